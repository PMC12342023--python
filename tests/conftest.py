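import numpy as np
import pandas as pd
import pytest

from dynanet.dataset import MediatorDataset


def make_dataset(rows, **kwargs) -> MediatorDataset:
    """Build a MediatorDataset from (subject, subgroup, time, mediator,
    value) tuples."""
    frame = pd.DataFrame(
        rows, columns=["subject", "subgroup", "time", "mediator", "value"]
    )
    return MediatorDataset(frame, **kwargs)


def random_dataset(rng, n_mediators=5, n_subjects=12, n_times=4, subgroup="G",
                   missing_rate=0.0):
    """Unstructured lognormal dataset for oracle-equivalence checks."""
    meds = [f"M{i}" for i in range(n_mediators)]
    rows = []
    for s in range(n_subjects):
        for t in range(n_times):
            for m in meds:
                if missing_rate and rng.random() < missing_rate:
                    v = np.nan
                else:
                    v = float(np.exp(rng.normal(3.0, 0.6)))
                rows.append((f"s{s:02d}", subgroup, float(t), m, v))
    return make_dataset(rows, mediators=meds)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
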
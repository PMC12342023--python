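"""Long-format mediator concentration datasets.

Every downstream stage (correlation networks, dynamic Bayesian network
inference, biomarker statistics) consumes the :class:`MediatorDataset`
container defined here.  The canonical coordinates are

* ``subject`` — opaque subject/culture identifier,
* ``subgroup`` — outcome or experimental-arm label (``"S"``, ``"NS"``,
  ``"WT_APAP"``, ...),
* ``time`` — numeric time position (days for serum panels, hours for
  culture supernatants); display labels are kept separately,
* ``mediator`` — canonical analyte name,
* ``value`` — non-negative concentration (pg/mL; µM for nitrite+nitrate),
  ``NaN`` when missing,
* ``censored`` — flag for below-detection-limit cells after the chosen
  substitution policy was applied.

Missing values are represented explicitly and handled downstream by
pairwise deletion (each correlation or regression family uses its own
complete cases), which preserves maximal data in small cohorts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataIntegrityError, PanelLookupError, SchemaError

CANONICAL_COLUMNS = ("subject", "subgroup", "time", "mediator", "value", "censored")

#: cell contents treated as "below detection limit" when parsing CSVs
DEFAULT_CENSOR_CODES = ("nd", "bdl", "<lod", "blod", "oor<")


@dataclass(frozen=True)
class Measurement:
    """A single concentration measurement."""

    subject: str
    subgroup: str
    time: float
    mediator: str
    value: float  # NaN when missing
    censored: bool = False


class MediatorDataset:
    """Validated long-format repository of mediator measurements.

    Parameters
    ----------
    frame:
        Long-format DataFrame with the canonical columns (``censored``
        optional).  Copied and sorted on construction.
    mediators, subgroups:
        Optional explicit registries; default to the values observed in the
        data (mediators in order of first appearance).  The mediator
        registry defines panel size ``n`` for complexity calculations, so
        analytes that never form an edge still count.
    time_labels:
        Optional mapping from numeric time to display label (e.g.
        ``{0: "d0"}``).
    subject_meta:
        Optional per-subject covariates (e.g. age in years) as a DataFrame
        indexed by subject id.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        mediators: Sequence[str] | None = None,
        subgroups: Sequence[str] | None = None,
        time_labels: Mapping[float, str] | None = None,
        subject_meta: pd.DataFrame | None = None,
    ):
        frame = frame.copy()
        missing = [c for c in CANONICAL_COLUMNS[:5] if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        if "censored" not in frame.columns:
            frame["censored"] = False
        frame["subject"] = frame["subject"].astype(str)
        frame["subgroup"] = frame["subgroup"].astype(str)
        frame["mediator"] = frame["mediator"].astype(str)
        frame["time"] = pd.to_numeric(frame["time"], errors="raise").astype(float)
        frame["value"] = pd.to_numeric(frame["value"], errors="raise").astype(float)
        frame["censored"] = frame["censored"].astype(bool)

        neg = frame["value"] < 0
        if neg.any():
            rows = frame.index[neg].tolist()[:5]
            raise DataIntegrityError(f"negative concentrations at rows {rows}")

        dup = frame.duplicated(subset=["subject", "time", "mediator"], keep=False)
        if dup.any():
            offending = frame.loc[dup, ["subject", "time", "mediator"]]
            rows = offending.index.tolist()
            raise DataIntegrityError(
                "duplicate (subject, time, mediator) keys at rows "
                f"{rows[:10]}: {offending.head(4).to_dict('records')}"
            )

        self._frame = frame.sort_values(
            ["subgroup", "subject", "time", "mediator"], kind="mergesort"
        ).reset_index(drop=True)

        observed_meds = list(dict.fromkeys(frame["mediator"]))
        self.mediators: list[str] = list(mediators) if mediators is not None else observed_meds
        unknown = set(observed_meds) - set(self.mediators)
        if unknown:
            raise DataIntegrityError(f"mediators not in registry: {sorted(unknown)}")

        observed_groups = list(dict.fromkeys(frame["subgroup"]))
        self.subgroups: list[str] = (
            list(subgroups) if subgroups is not None else sorted(observed_groups)
        )
        unknown = set(observed_groups) - set(self.subgroups)
        if unknown:
            raise DataIntegrityError(f"subgroups not in registry: {sorted(unknown)}")

        self.time_grid: list[float] = sorted(frame["time"].unique())
        self.time_labels = dict(time_labels) if time_labels else {}
        self.subject_meta = subject_meta

    # ------------------------------------------------------------------ #
    # construction / serialization

    @classmethod
    def from_long_csv(
        cls,
        path,
        schema: Mapping[str, str] | None = None,
        censor_policy: str = "half_lod",
        lod: float | Mapping[str, float] | None = None,
        censor_codes: Iterable[str] = DEFAULT_CENSOR_CODES,
        **kwargs,
    ) -> "MediatorDataset":
        """Load a long-format CSV.

        ``schema`` maps canonical column names to the file's column names,
        e.g. ``{"subject": "patient_id"}``.  Cells matching a censor code
        (case-insensitive) are below-detection-limit: under policy
        ``"half_lod"`` they are replaced by LOD/2 (``lod`` scalar or
        per-mediator mapping, required), under ``"drop"`` they become
        missing.  Either way the ``censored`` flag is retained.
        """
        raw = pd.read_csv(path, dtype=str)
        schema = dict(schema or {})
        rename = {}
        for canonical in CANONICAL_COLUMNS[:5]:
            src = schema.get(canonical, canonical)
            if src not in raw.columns:
                raise SchemaError(
                    f"column {src!r} (for {canonical!r}) not found in {path}; "
                    f"available: {list(raw.columns)}"
                )
            rename[src] = canonical
        raw = raw.rename(columns=rename)

        codes = {c.lower() for c in censor_codes}
        if censor_policy not in ("half_lod", "drop"):
            raise SchemaError(f"unknown censor policy {censor_policy!r}")

        values = np.empty(len(raw), dtype=float)
        censored = np.zeros(len(raw), dtype=bool)
        for i, cell in enumerate(raw["value"]):
            text = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
            if text == "" :
                values[i] = np.nan
                continue
            if text.lower() in codes:
                censored[i] = True
                if censor_policy == "drop":
                    values[i] = np.nan
                else:
                    med = raw["mediator"].iloc[i]
                    limit = lod.get(med) if isinstance(lod, Mapping) else lod
                    if limit is None:
                        raise SchemaError(
                            f"censored cell {text!r} at row {i} but no LOD given "
                            f"for mediator {med!r}"
                        )
                    values[i] = float(limit) / 2.0
                continue
            try:
                values[i] = float(text)
            except ValueError as exc:
                raise SchemaError(f"non-numeric value {text!r} at row {i}") from exc

        frame = raw[["subject", "subgroup", "time", "mediator"]].copy()
        frame["value"] = values
        frame["censored"] = censored
        return cls(frame, **kwargs)

    @classmethod
    def from_wide_csv(
        cls,
        path,
        id_columns: Sequence[str] = ("subject", "subgroup", "time"),
        **kwargs,
    ) -> "MediatorDataset":
        """Load a wide CSV (one column per mediator) by pivoting to the
        canonical long format; every non-id column is a mediator."""
        raw = pd.read_csv(path)
        missing = [c for c in id_columns if c not in raw.columns]
        if missing:
            raise SchemaError(f"missing id column(s) {missing} in {path}")
        long = raw.melt(
            id_vars=list(id_columns), var_name="mediator", value_name="value"
        )
        long = long.rename(
            columns=dict(zip(id_columns, ("subject", "subgroup", "time")))
        )
        return cls(long, **kwargs)

    def to_long_csv(self, path) -> None:
        """Write the canonical long CSV (round-trips through ``from_long_csv``)."""
        out = self._frame[list(CANONICAL_COLUMNS)].copy()
        out.to_csv(path, index=False)

    def summary(self) -> dict:
        """Counts per subgroup × time, plus registry sizes."""
        counts = (
            self._frame.dropna(subset=["value"])
            .groupby(["subgroup", "time"])
            .size()
        )
        return {
            "n_mediators": len(self.mediators),
            "subgroups": {
                g: int(self._frame.loc[self._frame["subgroup"] == g, "subject"].nunique())
                for g in self.subgroups
            },
            "time_grid": self.time_grid,
            "observations": {
                f"{g}@{t:g}": int(counts.get((g, t), 0))
                for g in self.subgroups
                for t in self.time_grid
            },
        }

    def summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)

    # ------------------------------------------------------------------ #
    # accessors

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def measurements(self) -> list[Measurement]:
        return [
            Measurement(r.subject, r.subgroup, r.time, r.mediator, r.value, r.censored)
            for r in self._frame.itertuples(index=False)
        ]

    @property
    def intervals(self) -> list[tuple[float, float]]:
        """Consecutive, non-overlapping intervals over the time grid."""
        return list(zip(self.time_grid[:-1], self.time_grid[1:]))

    def interval_label(self, interval: tuple[float, float]) -> str:
        a, b = interval
        la = self.time_labels.get(a, f"{a:g}")
        lb = self.time_labels.get(b, f"{b:g}")
        return f"{la}-{lb}"

    def _check_subgroup(self, subgroup: str) -> None:
        if subgroup not in self.subgroups:
            raise PanelLookupError(
                f"unknown subgroup {subgroup!r}; available: {self.subgroups}"
            )

    def wide(self, subgroup: str) -> pd.DataFrame:
        """Observation matrix for a subgroup: rows (subject, time), columns
        the full mediator registry; missing cells are NaN."""
        self._check_subgroup(subgroup)
        sub = self._frame[self._frame["subgroup"] == subgroup]
        wide = sub.pivot(index=["subject", "time"], columns="mediator", values="value")
        return wide.reindex(columns=self.mediators)

    def window_slice(self, subgroup: str, interval: tuple[float, float]) -> pd.DataFrame:
        """All samples of ``subgroup`` at the two boundary time points of
        ``interval``, stacked (rows = subject × boundary-time).  Rows with
        every mediator missing are dropped."""
        self._check_subgroup(subgroup)
        interval = (float(interval[0]), float(interval[1]))
        if interval not in self.intervals:
            raise PanelLookupError(
                f"interval {interval} not in scheme {self.intervals}"
            )
        wide = self.wide(subgroup)
        if wide.empty:
            return wide
        mask = wide.index.get_level_values("time").isin(interval)
        out = wide[mask]
        return out.dropna(how="all")

    def zscore_by_mediator(
        self, subgroup: str, log_transform: bool = False
    ) -> tuple[pd.DataFrame, list[str]]:
        """Per-mediator z-scores over a subgroup (mean 0, sample SD 1 over
        non-missing entries; ddof=1).  Mediators with fewer than two
        observed values or zero variance are excluded with a warning; the
        excluded names are returned alongside the matrix.

        ``log_transform`` takes natural logs first (non-positive values
        become missing), appropriate for right-skewed concentration data
        ahead of Gaussian modeling."""
        wide = self.wide(subgroup)
        if log_transform:
            wide = wide.where(wide > 0)
            wide = np.log(wide)
        excluded: list[str] = []
        cols = {}
        for m in self.mediators:
            col = wide[m]
            obs = col.dropna()
            if len(obs) < 2 or float(obs.std(ddof=1)) == 0.0:
                excluded.append(m)
                continue
            cols[m] = (col - obs.mean()) / obs.std(ddof=1)
        if excluded:
            warnings.warn(
                f"excluded zero-variance/underobserved mediators in {subgroup!r}: "
                f"{excluded}",
                UserWarning,
                stacklevel=2,
            )
        return pd.DataFrame(cols, index=wide.index), excluded


# ---------------------------------------------------------------------- #
# spec-level function surface

def load_long_csv(path, schema: Mapping[str, str] | None = None, **kwargs) -> MediatorDataset:
    """Parse and validate a long-format mediator CSV."""
    return MediatorDataset.from_long_csv(path, schema=schema, **kwargs)


def window_slice(ds: MediatorDataset, subgroup: str, interval) -> pd.DataFrame:
    return ds.window_slice(subgroup, interval)


def zscore_by_mediator(ds: MediatorDataset, subgroup: str) -> pd.DataFrame:
    z, _ = ds.zscore_by_mediator(subgroup)
    return z


@dataclass
class IntervalScheme:
    """Ordered consecutive (t_start, t_end) pairs over a time grid."""

    intervals: list[tuple[float, float]] = field(default_factory=list)

    @classmethod
    def from_grid(cls, grid: Sequence[float]) -> "IntervalScheme":
        grid = sorted(grid)
        return cls(list(zip(grid[:-1], grid[1:])))

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self):
        return len(self.intervals)
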
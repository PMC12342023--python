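"""Dynamic Network Analysis (DyNA).

Signed Pearson-correlation networks over consecutive time intervals: two
mediators are connected in an interval when the absolute Pearson
correlation of their concentrations within that window reaches the
stringency threshold (default 0.85, inclusive).  Positive correlations are
"parallel" trajectories, negative ones "anti-parallel".  Per-interval
network complexity is the degree sum divided by (n − 1) — i.e. 2E/(n − 1)
for a panel of n mediators — and the total number of connections is the
edge count summed over all intervals.

Two windowing modes are provided (the field uses both readings):

* ``levels`` (default) — pool the samples at the two boundary time points
  across subjects; each (subject, time) sample is one observation.
* ``differences`` — correlate per-subject changes across the interval
  (value at t_end − value at t_start), requiring both samples.

Correlations use pairwise-complete observations; a pair with fewer than
``min_pairs`` complete observations or zero variance is *undefined* (never
an edge, and reported as excluded rather than as "no correlation").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dataset import MediatorDataset
from .exceptions import ConfigError, PanelLookupError


@dataclass(frozen=True)
class SignedEdge:
    """Thresholded correlation between an unordered mediator pair."""

    mediator_a: str
    mediator_b: str
    r: float
    n_pairs: int

    @property
    def sign(self) -> str:
        return "positive" if self.r >= 0 else "negative"


@dataclass
class DynamicNetworkSet:
    """Per-interval signed undirected graphs over a fixed mediator panel."""

    intervals: list[tuple[float, float]]
    graphs: list[nx.Graph]
    mediators: list[str]
    threshold: float
    mode: str
    #: per interval: mediator -> reason string for exclusion from pairing
    excluded: list[dict] = field(default_factory=list)

    def edges(self, interval_index: int) -> list[SignedEdge]:
        g = self.graphs[interval_index]
        return [
            SignedEdge(a, b, d["r"], d["n_pairs"]) for a, b, d in g.edges(data=True)
        ]

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for k, (t0, t1) in enumerate(self.intervals):
            for e in self.edges(k):
                rows.append(
                    {
                        "interval": f"{t0:g}-{t1:g}",
                        "mediator_a": e.mediator_a,
                        "mediator_b": e.mediator_b,
                        "r": e.r,
                        "sign": e.sign,
                        "n_pairs": e.n_pairs,
                    }
                )
        return pd.DataFrame(
            rows, columns=["interval", "mediator_a", "mediator_b", "r", "sign", "n_pairs"]
        )


@dataclass
class ComplexityProfile:
    """Per-interval complexity 2E/(n−1) and the total connection count."""

    intervals: list[tuple[float, float]]
    complexity: list[float]
    edge_counts: list[int]

    @property
    def total_connections(self) -> int:
        return int(sum(self.edge_counts))

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interval": [f"{a:g}-{b:g}" for a, b in self.intervals],
                "edges": self.edge_counts,
                "complexity": self.complexity,
            }
        )


# ---------------------------------------------------------------------- #
# operations

def interval_correlations(
    ds: MediatorDataset,
    subgroup: str,
    interval: tuple[float, float],
    mode: str = "levels",
    min_pairs: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations within one interval window.

    Returns ``(r, n_pairs)`` as mediator × mediator DataFrames; undefined
    pairs (too few complete pairs, zero variance) are NaN in ``r``.
    """
    if mode not in ("levels", "differences"):
        raise ConfigError(f"mode must be 'levels' or 'differences', got {mode!r}")
    if mode == "levels":
        obs = ds.window_slice(subgroup, interval)
    else:
        interval = (float(interval[0]), float(interval[1]))
        if interval not in ds.intervals:
            raise PanelLookupError(f"interval {interval} not in scheme {ds.intervals}")
        wide = ds.wide(subgroup)
        if wide.empty:
            obs = wide
        else:
            t0 = wide.xs(interval[0], level="time")
            t1 = wide.xs(interval[1], level="time")
            common = t0.index.intersection(t1.index)
            obs = (t1.loc[common] - t0.loc[common]).dropna(how="all")

    meds = ds.mediators
    if obs.empty:
        nan = pd.DataFrame(np.nan, index=meds, columns=meds)
        return nan, pd.DataFrame(0, index=meds, columns=meds)

    obs = obs.reindex(columns=meds)
    notna = obs.notna().astype(float)
    n_pairs = pd.DataFrame(
        notna.T.values @ notna.values, index=meds, columns=meds
    ).astype(int)
    r = obs.corr(method="pearson", min_periods=max(int(min_pairs), 2))
    r = r.reindex(index=meds, columns=meds)
    r = r.mask(n_pairs < int(min_pairs))
    np.fill_diagonal(r.values, np.nan)
    return r, n_pairs


def build_networks(
    correlations: Sequence[tuple[pd.DataFrame, pd.DataFrame]],
    intervals: Sequence[tuple[float, float]],
    mediators: Sequence[str],
    threshold: float = 0.85,
    mode: str = "levels",
) -> DynamicNetworkSet:
    """Threshold per-interval correlation matrices into signed graphs.

    An edge exists iff |r| ≥ threshold (inclusive, exactly as stated for
    the stringency rule); NaN correlations never form edges.
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigError(f"threshold must be in (0, 1], got {threshold}")
    meds = list(mediators)
    graphs = []
    excluded = []
    for (r, n_pairs) in correlations:
        g = nx.Graph()
        g.add_nodes_from(meds)
        undef = {}
        for i, a in enumerate(meds):
            col_def = r[a].drop(index=a).notna()
            if not col_def.any():
                counts = n_pairs[a].drop(index=a)
                undef[a] = (
                    "zero variance or too few complete pairs"
                    if counts.max() > 0
                    else "no observations"
                )
        for i, a in enumerate(meds):
            for b in meds[i + 1 :]:
                rv = r.at[a, b]
                if pd.notna(rv) and abs(rv) >= threshold:
                    g.add_edge(a, b, r=float(rv), n_pairs=int(n_pairs.at[a, b]))
        graphs.append(g)
        excluded.append(undef)
    return DynamicNetworkSet(
        intervals=list(intervals),
        graphs=graphs,
        mediators=meds,
        threshold=threshold,
        mode=mode,
        excluded=excluded,
    )


def complexity(nets: DynamicNetworkSet, n_mediators: int | None = None) -> ComplexityProfile:
    """Per-interval complexity = (Σ node degrees)/(n−1) = 2E/(n−1).

    ``n_mediators`` is the analyzed panel size n, counting mediators that
    have no connections (defaults to the panel the networks were built on).
    """
    n = int(n_mediators) if n_mediators is not None else len(nets.mediators)
    if n < 2:
        raise ConfigError("complexity needs a panel of at least 2 mediators")
    counts = [g.number_of_edges() for g in nets.graphs]
    return ComplexityProfile(
        intervals=list(nets.intervals),
        complexity=[2.0 * e / (n - 1) for e in counts],
        edge_counts=counts,
    )


def mediator_connectivity(nets: DynamicNetworkSet, mediator: str) -> dict:
    """Per-interval degree, partner lists with signs, and the total."""
    if mediator not in nets.mediators:
        raise PanelLookupError(
            f"unknown mediator {mediator!r}; panel: {nets.mediators}"
        )
    degrees, partners = [], []
    for g in nets.graphs:
        nbrs = {
            b: "positive" if g.edges[mediator, b]["r"] >= 0 else "negative"
            for b in g.neighbors(mediator)
        }
        degrees.append(len(nbrs))
        partners.append(nbrs)
    return {
        "mediator": mediator,
        "degree": degrees,
        "partners": partners,
        "total": int(sum(degrees)),
    }


def connectivity_table(nets: DynamicNetworkSet) -> pd.DataFrame:
    """Degrees of every mediator per interval plus the totals."""
    rows = {}
    for m in nets.mediators:
        c = mediator_connectivity(nets, m)
        rows[m] = c["degree"] + [c["total"]]
    cols = [f"{a:g}-{b:g}" for a, b in nets.intervals] + ["total"]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    out.index.name = "mediator"
    return out


# ---------------------------------------------------------------------- #
# estimator

class DynamicNetworkAnalysis(BaseEstimator):
    """Interval-wise signed correlation-network analysis.

    Parameters
    ----------
    threshold:
        Stringency on |Pearson r| for an edge, in (0, 1]; inclusive.
    mode:
        ``"levels"`` pools boundary-time samples, ``"differences"``
        correlates per-subject changes across the interval.
    min_pairs:
        Minimum complete pairs for a correlation to be defined.

    Attributes (after :meth:`fit`)
    ------------------------------
    networks_ : DynamicNetworkSet
    complexity_ : ComplexityProfile
    total_connections_ : int
    correlations_ : list of (r, n_pairs) DataFrames, one per interval
    subgroup_ : the subgroup analyzed
    """

    def __init__(self, threshold: float = 0.85, mode: str = "levels", min_pairs: int = 4):
        self.threshold = threshold
        self.mode = mode
        self.min_pairs = min_pairs

    def fit(self, ds: MediatorDataset, subgroup: str | None = None):
        if subgroup is None:
            raise ConfigError(
                f"subgroup is required; available: {ds.subgroups}"
            )
        if not 0.0 < self.threshold <= 1.0:
            raise ConfigError(f"threshold must be in (0, 1], got {self.threshold}")
        intervals = ds.intervals
        corrs = [
            interval_correlations(ds, subgroup, iv, self.mode, self.min_pairs)
            for iv in intervals
        ]
        self.correlations_ = corrs
        self.networks_ = build_networks(
            corrs, intervals, ds.mediators, self.threshold, self.mode
        )
        self.complexity_ = complexity(self.networks_, len(ds.mediators))
        self.total_connections_ = self.complexity_.total_connections
        self.subgroup_ = subgroup
        return self

    def connectivity(self, mediator: str) -> dict:
        return mediator_connectivity(self.networks_, mediator)

    def connectivity_table(self) -> pd.DataFrame:
        return connectivity_table(self.networks_)

    def write_outputs(self, outdir, prefix: str = "") -> None:
        """Edge list, complexity and connectivity CSVs plus one GraphML per
        interval."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.networks_.edge_table().to_csv(outdir / f"{prefix}edges.csv", index=False)
        self.complexity_.table().to_csv(outdir / f"{prefix}complexity.csv", index=False)
        self.connectivity_table().to_csv(outdir / f"{prefix}connectivity.csv")
        for k, g in enumerate(self.networks_.graphs):
            g = g.copy()
            for node in g.nodes:
                g.nodes[node]["degree"] = g.degree(node)
            for a, b in g.edges:
                g.edges[a, b]["sign"] = (
                    "positive" if g.edges[a, b]["r"] >= 0 else "negative"
                )
            t0, t1 = self.networks_.intervals[k]
            nx.write_graphml(g, outdir / f"{prefix}network_{t0:g}-{t1:g}.graphml")
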
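"""Synthetic multi-subject mediator time-series with known ground truth.

The generator emulates the structure of longitudinal inflammatory-mediator
panels: positive, right-skewed concentrations (lognormal observation
model), subgroup fold-change effects, first-order autoregressive
self-feedback with optional changepoints, directed cross-mediator
couplings, interval-local planted correlations, and
missing-completely-at-random dropout.

Latent log-scale model per subject, mediator i, time index t:

    x[t+1, i] = a_i(t) * x[t, i] + sum_j b_ij * x[t, j] + eps,   eps ~ N(0, s_ar^2)

with a_i(t) switching at a per-mediator changepoint.  Interval-local
correlations are induced by latent "channels": every mediator involved in
a planted edge exchanges a fixed share s_m = max incident |r| of its
variance for a channel component present at *all* time points, and the
channels of a planted pair are cross-correlated only at the two boundary
times of the target interval (correlation r/√(s_a·s_b), solved per time
point by eigendecomposition of the channel correlation matrix).  This
keeps each mediator's marginal variance flat across time — so planted
correlations are exactly r inside their window, zero is leaked into
neighbouring windows, and thresholded network recovery is calibrated.
Observed value:

    exp( baseline + log fold-change + age term + subject offset + x + channel + noise )

Targets are exact in population only when a mediator is not re-used by a
planted edge in an *adjacent* interval (the shared boundary time would
need two different channel correlations); the constructor warns in that
case.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import panels
from .dataset import MediatorDataset
from .exceptions import ConfigError, InfeasibleStructureError


@dataclass(frozen=True)
class PlantedEdge:
    """Target Pearson correlation for one mediator pair in one interval.

    ``interval`` is the 0-based index into the consecutive-interval scheme;
    ``subgroup=None`` plants the edge in every subgroup.
    """

    mediator_a: str
    mediator_b: str
    interval: int
    r: float
    subgroup: str | None = None


@dataclass(frozen=True)
class Coupling:
    """Directed lag-1 influence parent → child with coefficient b."""

    parent: str
    child: str
    coefficient: float
    subgroup: str | None = None


@dataclass
class SyntheticSpec:
    """Full parameterization of the generative model."""

    mediators: Sequence[str]
    subgroup_sizes: Mapping[str, int]
    time_grid: Sequence[float]
    baseline_log_mean: Mapping[str, float] | float = 5.0
    baseline_log_sd: float = 0.3
    group_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    planted_edges: Sequence[PlantedEdge] = field(default_factory=tuple)
    ar_self: Mapping[str, float] = field(default_factory=dict)
    cross_couplings: Sequence[Coupling] = field(default_factory=tuple)
    changepoints: Mapping[str, tuple[int, float]] = field(default_factory=dict)
    ar_noise_sd: float = 0.5
    noise_log_sd: float = 0.2
    missing_rate: float = 0.0
    age_effects: Mapping[str, float] = field(default_factory=dict)
    age_range: tuple[float, float] = (0.5, 17.0)
    seed: int = 0
    tags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        meds = set(self.mediators)
        for e in self.planted_edges:
            if not abs(e.r) < 1.0:
                raise ConfigError(f"planted |r| must be < 1, got {e.r}")
            if e.mediator_a == e.mediator_b:
                raise ConfigError("planted self-pair is not allowed")
            if not {e.mediator_a, e.mediator_b} <= meds:
                raise ConfigError(f"planted edge uses unknown mediator: {e}")
            if not 0 <= e.interval < len(self.time_grid) - 1:
                raise ConfigError(f"planted edge interval out of range: {e}")
        for m, a in self.ar_self.items():
            if not abs(a) < 1.0:
                raise ConfigError(f"|AR coefficient| must be < 1 ({m}: {a})")
        for m, (idx, a) in self.changepoints.items():
            if not abs(a) < 1.0:
                raise ConfigError(f"|AR coefficient| must be < 1 ({m}: {a})")
            if not 0 < idx < len(self.time_grid):
                raise ConfigError(f"changepoint index out of range ({m}: {idx})")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError("missing_rate must be in [0, 1]")
        # adjacent-interval reuse makes planted targets approximate
        by_group: dict[str | None, dict[int, set[str]]] = {}
        for e in self.planted_edges:
            by_group.setdefault(e.subgroup, {}).setdefault(e.interval, set()).update(
                (e.mediator_a, e.mediator_b)
            )
        for g, per_int in by_group.items():
            for k in per_int:
                overlap = per_int[k] & per_int.get(k + 1, set())
                if overlap:
                    warnings.warn(
                        f"mediators {sorted(overlap)} planted in adjacent intervals "
                        f"{k},{k+1} (subgroup {g}); realized correlations will fall "
                        "below target at the shared boundary time",
                        UserWarning,
                        stacklevel=2,
                    )

    def baseline_of(self, mediator: str) -> float:
        if isinstance(self.baseline_log_mean, Mapping):
            return float(self.baseline_log_mean.get(mediator, 5.0))
        return float(self.baseline_log_mean)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mediators"] = list(self.mediators)
        d["time_grid"] = list(self.time_grid)
        d["subgroup_sizes"] = dict(self.subgroup_sizes)
        d["group_effects"] = [[a, g, f] for (a, g), f in self.group_effects.items()]
        return d


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery scoring."""

    #: (subgroup, interval index) -> list of (mediator_a, mediator_b, sign)
    edges_by_interval: dict
    #: subgroup -> child -> sorted list of true lag-1 parents (incl. self)
    parent_sets: dict
    #: mediators with nonzero AR self-coefficient
    self_loops: list
    #: mediator -> (time index, new AR coefficient)
    changepoints: dict
    #: (mediator, subgroup) -> fold change
    fold_changes: dict

    def planted_pairs(self, subgroup: str, interval: int) -> set[frozenset]:
        out = set()
        for (g, k), edges in self.edges_by_interval.items():
            if k == interval and (g is None or g == subgroup):
                out.update(frozenset((a, b)) for a, b, _ in edges)
        return out

    def to_json(self, path) -> None:
        payload = {
            "edges_by_interval": [
                {"subgroup": g, "interval": k, "edges": [list(e) for e in edges]}
                for (g, k), edges in self.edges_by_interval.items()
            ],
            "parent_sets": {
                g: {c: sorted(ps) for c, ps in by_child.items()}
                for g, by_child in self.parent_sets.items()
            },
            "self_loops": self.self_loops,
            "changepoints": {m: list(cp) for m, cp in self.changepoints.items()},
            "fold_changes": [[m, g, f] for (m, g), f in self.fold_changes.items()],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------- #
# generation

def _ar_variances(spec: SyntheticSpec, mediator: str) -> np.ndarray:
    """Analytic variance of the AR component at each time index, starting
    from the stationary distribution of the initial coefficient."""
    T = len(spec.time_grid)
    a0 = float(spec.ar_self.get(mediator, 0.0))
    s2 = spec.ar_noise_sd ** 2
    v = np.empty(T)
    v[0] = s2 / (1.0 - a0 ** 2)
    cp = spec.changepoints.get(mediator)
    for t in range(T - 1):
        a = a0 if (cp is None or t < cp[0]) else cp[1]
        v[t + 1] = a * a * v[t] + s2
    return v


def _latent_corr_for_observed(r: float, va: float, vb: float) -> float:
    """Latent (log-scale) correlation that yields observed-scale Pearson r
    between two lognormal variables with log-variances va, vb.

    Inverts corr(e^X, e^Y) = (e^{rho·sa·sb} − 1)/√((e^{va}−1)(e^{vb}−1)).
    Raises when the target is outside the attainable lognormal range."""
    span = math.sqrt(math.expm1(va) * math.expm1(vb))
    arg = 1.0 + r * span
    if arg <= 0.0:
        raise InfeasibleStructureError(
            f"observed-scale correlation {r:.3f} is unattainable for lognormal "
            f"noise with log-variances ({va:.3f}, {vb:.3f}); reduce |r| or the "
            "noise scales"
        )
    rho = math.log(arg) / math.sqrt(va * vb)
    if abs(rho) > 1.0:
        raise InfeasibleStructureError(
            f"observed-scale correlation {r:.3f} needs latent correlation "
            f"{rho:.3f} (outside [-1, 1]) at log-variances ({va:.3f}, {vb:.3f})"
        )
    return rho


class _ChannelPlan:
    """Latent channel loadings for one subgroup.

    ``meds`` are the mediators carrying a channel, ``share[m]`` the
    variance share s_m handed to the channel, and ``loadings[t]`` the
    factor L_t with channel correlation C_t = L_t·L_tᵀ at time index t.
    Planted targets are observed-scale Pearson correlations; they are
    converted to latent correlations first (lognormal attenuation).
    """

    def __init__(self, spec: SyntheticSpec, subgroup: str, tau: Mapping[str, np.ndarray]):
        edges = [
            e for e in spec.planted_edges if e.subgroup in (None, subgroup)
        ]
        self.meds: list[str] = sorted(
            {m for e in edges for m in (e.mediator_a, e.mediator_b)}
        )
        idx = {m: i for i, m in enumerate(self.meds)}
        p = len(self.meds)
        T = len(spec.time_grid)
        # latent correlation per edge and boundary time
        rho_lat: dict[tuple[int, int], dict[frozenset, float]] = {}
        self.share = {m: 0.0 for m in self.meds}
        for e in edges:
            for t in (e.interval, e.interval + 1):
                rho = _latent_corr_for_observed(
                    e.r, tau[e.mediator_a][t], tau[e.mediator_b][t]
                )
                rho_lat.setdefault((t,), {})[
                    frozenset((e.mediator_a, e.mediator_b))
                ] = rho
                self.share[e.mediator_a] = max(self.share[e.mediator_a], abs(rho))
                self.share[e.mediator_b] = max(self.share[e.mediator_b], abs(rho))
        for m in self.meds:
            if spec.age_effects.get(m, 0.0) != 0.0:
                warnings.warn(
                    f"mediator {m!r} has both an age effect and planted edges; "
                    "its realized window correlations will fall slightly below "
                    "target",
                    UserWarning,
                    stacklevel=3,
                )
        self.loadings: dict[int, np.ndarray] = {}
        for t in range(T):
            per_pair = rho_lat.get((t,))
            if not per_pair:
                continue
            C = np.eye(p)
            for pair, rho in per_pair.items():
                a, b = sorted(pair)
                i, j = idx[a], idx[b]
                C[i, j] = C[j, i] = rho / math.sqrt(self.share[a] * self.share[b])
            eigval, eigvec = np.linalg.eigh(C)
            if eigval.min() < -1e-8:
                raise InfeasibleStructureError(
                    f"planted correlations touching time index {t} (subgroup "
                    f"{subgroup!r}) admit no positive semi-definite covariance "
                    f"(min eigenvalue {eigval.min():.3g}); reduce |r| or plant "
                    "cliques instead of hubs"
                )
            self.loadings[t] = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))

    @property
    def empty(self) -> bool:
        return not self.meds


def generate(spec: SyntheticSpec) -> tuple[MediatorDataset, GroundTruth]:
    """Sample a dataset and its ground truth.  Deterministic given
    ``spec.seed``; infeasible planted structures raise before sampling."""
    rng = np.random.default_rng(spec.seed)
    meds = list(spec.mediators)
    n = len(meds)
    med_idx = {m: i for i, m in enumerate(meds)}
    grid = [float(t) for t in spec.time_grid]
    T = len(grid)

    # per-time variance of the components a channel can substitute for
    tau = {
        m: _ar_variances(spec, m) + spec.baseline_log_sd ** 2 + spec.noise_log_sd ** 2
        for m in meds
    }

    # resolve channel plans up front: feasibility is checked for every
    # subgroup before any sampling happens
    plans = {g: _ChannelPlan(spec, g, tau) for g in spec.subgroup_sizes}

    a_base = np.array([spec.ar_self.get(m, 0.0) for m in meds])
    cp_idx = np.full(n, T + 1)
    cp_coef = a_base.copy()
    for m, (tidx, newa) in spec.changepoints.items():
        cp_idx[med_idx[m]] = tidx
        cp_coef[med_idx[m]] = newa

    rows = []
    ages: dict[str, float] = {}
    age_mid = 0.5 * (spec.age_range[0] + spec.age_range[1])
    for g, size in spec.subgroup_sizes.items():
        B = np.zeros((n, n))
        for c in spec.cross_couplings:
            if c.subgroup in (None, g):
                B[med_idx[c.child], med_idx[c.parent]] = c.coefficient
        fold = np.array(
            [np.log(spec.group_effects.get((m, g), 1.0)) for m in meds]
        )
        base = np.array([spec.baseline_of(m) for m in meds])
        slopes = np.array([spec.age_effects.get(m, 0.0) for m in meds])

        plan = plans[g]
        chan_cols = [med_idx[m] for m in plan.meds]
        # idiosyncratic components of channel mediators shrink by 1 - s_m so
        # the marginal variance is unchanged by the channel
        idio_scale = np.ones(n)
        chan_sd = np.zeros((T, n))
        for m in plan.meds:
            i = med_idx[m]
            idio_scale[i] = np.sqrt(1.0 - plan.share[m])
            chan_sd[:, i] = np.sqrt(plan.share[m] * tau[m])

        for s_i in range(size):
            subject = f"{g}-{s_i + 1:02d}"
            age = float(rng.uniform(*spec.age_range))
            ages[subject] = age
            offset = rng.normal(0.0, spec.baseline_log_sd, size=n)

            x = np.empty((T, n))
            a0_sd = spec.ar_noise_sd / np.sqrt(1.0 - a_base ** 2)
            x[0] = rng.normal(0.0, 1.0, size=n) * a0_sd
            for t in range(T - 1):
                a_t = np.where(t < cp_idx, a_base, cp_coef)
                x[t + 1] = a_t * x[t] + B @ x[t] + rng.normal(
                    0.0, spec.ar_noise_sd, size=n
                )

            chan = np.zeros((T, n))
            if not plan.empty:
                p = len(plan.meds)
                for t in range(T):
                    L = plan.loadings.get(t)
                    z = rng.standard_normal(p)
                    u = (L @ z) if L is not None else z
                    chan[t, chan_cols] = chan_sd[t, chan_cols] * u

            noise = rng.normal(0.0, spec.noise_log_sd, size=(T, n))
            logval = (
                base[None, :]
                + fold[None, :]
                + slopes[None, :] * (age - age_mid)
                + (offset[None, :] + x + noise) * idio_scale[None, :]
                + chan
            )
            value = np.exp(logval)
            if spec.missing_rate > 0:
                mask = rng.random(size=(T, n)) < spec.missing_rate
                value = np.where(mask, np.nan, value)

            for t in range(T):
                for i, m in enumerate(meds):
                    rows.append((subject, g, grid[t], m, value[t, i], False))

    frame = pd.DataFrame(
        rows, columns=["subject", "subgroup", "time", "mediator", "value", "censored"]
    )
    meta = pd.DataFrame({"age": pd.Series(ages)})
    meta.index.name = "subject"
    ds = MediatorDataset(
        frame,
        mediators=meds,
        subgroups=list(spec.subgroup_sizes),
        subject_meta=meta,
    )

    truth = GroundTruth(
        edges_by_interval=_truth_edges(spec),
        parent_sets=_truth_parents(spec),
        self_loops=sorted(m for m, a in spec.ar_self.items() if a != 0.0),
        changepoints=dict(spec.changepoints),
        fold_changes={
            (m, g): f for (m, g), f in spec.group_effects.items() if f != 1.0
        },
    )
    return ds, truth


def _truth_edges(spec: SyntheticSpec) -> dict:
    out: dict = {}
    for e in spec.planted_edges:
        key = (e.subgroup, e.interval)
        out.setdefault(key, []).append(
            (e.mediator_a, e.mediator_b, "positive" if e.r >= 0 else "negative")
        )
    return out


def _truth_parents(spec: SyntheticSpec) -> dict:
    out: dict = {}
    for g in spec.subgroup_sizes:
        by_child: dict[str, set[str]] = {}
        for m, a in spec.ar_self.items():
            if a != 0.0:
                by_child.setdefault(m, set()).add(m)
        for c in spec.cross_couplings:
            if c.subgroup in (None, g) and c.coefficient != 0.0:
                by_child.setdefault(c.child, set()).add(c.parent)
        out[g] = {child: sorted(ps) for child, ps in by_child.items()}
    return out


# ---------------------------------------------------------------------- #
# presets emulating the two study designs (stylized shapes, not fitted to
# any published concentration ranges; see the methods note)

def palf_preset(seed: int = 0) -> SyntheticSpec:
    """Serum-panel preset: 28 mediators, survivors (S, n=14) vs
    non-survivors (NS, n=7), daily samples d0–d7.

    Planted structure: GDF-15 strongly up and MIG down in NS; HMGB1 high in
    both subgroups; AR self-feedback on HMGB1 and GDF-15; denser planted
    interval correlations in NS than in S; an HMGB1→MIG→GDF-15 coupling
    chain present only in S; mild negative age trends on two mediators.
    """
    P = panels.HUMAN_PANEL
    baselines = {m: 5.0 for m in P}
    baselines.update({"HMGB1": 7.6, "GDF-15": 6.5, "NO2+NO3": 3.4, "IL-6": 5.8})
    r = 0.95
    ns_edges = [
        ("IL-6", "IL-8", 0), ("TNF-a", "IL-1b", 0),
        ("MCP-1", "IL-13", 1), ("IP-10", "IL-17A", 1),
        ("IL-6", "TNF-a", 2), ("IL-15", "IL-8", 2),
        ("IFN-g", "IL-12p70", 3), ("MCP-1", "Eotaxin", 3),
        ("IL-6", "IL-10", 4), ("TNF-a", "MIP-1a", 4),
        ("IL-8", "IP-10", 5),
        ("IL-15", "IL-6", 6),
    ]
    s_edges = [
        ("IL-6", "TNF-a", 0),
        ("IL-10", "IL-1RA", 2),
        ("IL-8", "MCP-1", 4),
        ("GM-CSF", "IL-7", 5),
        ("IFN-g", "IP-10", 6),
    ]
    planted = [PlantedEdge(a, b, k, r, "NS") for a, b, k in ns_edges]
    planted += [PlantedEdge(a, b, k, r, "S") for a, b, k in s_edges]
    return SyntheticSpec(
        mediators=P,
        subgroup_sizes={"S": 14, "NS": 7},
        time_grid=list(range(8)),
        baseline_log_mean=baselines,
        baseline_log_sd=0.35,
        group_effects={
            ("GDF-15", "NS"): 4.0,
            ("MIG", "NS"): 0.4,
            ("IL-6", "NS"): 2.5,
            ("sIL-2Ra", "NS"): 2.2,
        },
        planted_edges=planted,
        ar_self={"HMGB1": 0.7, "GDF-15": 0.7},
        cross_couplings=(
            Coupling("HMGB1", "MIG", 0.8, "S"),
            Coupling("MIG", "GDF-15", -0.7, "S"),
        ),
        changepoints={"IL-1RA": (4, 0.6)},
        ar_noise_sd=0.5,
        noise_log_sd=0.25,
        missing_rate=0.03,
        age_effects={"sIL-2Ra": -0.06, "MIP-1b": -0.04},
        seed=seed,
        tags={"preset": "palf", "note": "stylized shape; effect sizes synthetic"},
    )


def hepatocyte_preset(seed: int = 0) -> SyntheticSpec:
    """Hepatocyte-supernatant preset: 23 mediators, genotype × treatment
    arms (wild-type vs hepatocyte-specific HMGB1 knockout; control vs
    10 mM APAP), sampled at 1, 3, 6, 24, 48 h with 3–5 cultures per arm.

    KO arms carry near-zero HMGB1 and attenuated GDF-15; APAP in wild type
    raises GDF-15 and plants denser interval correlations than any other
    arm."""
    P = panels.MOUSE_PANEL
    baselines = {m: 4.5 for m in P}
    baselines.update({"HMGB1": 7.0, "GDF-15": 5.8, "NO2+NO3": 3.0})
    r = 0.95
    wt_apap = [
        ("IL-6", "TNF-a", 0), ("KC", "MCP-1", 0),
        ("IL-12p40", "IL-10", 1), ("MIP-1a", "IP-10", 1),
        ("TNF-a", "KC", 2), ("IL-1b", "IL-6", 2),
        ("MCP-1", "VEGF", 3), ("IL-17", "IL-10", 3),
    ]
    wt_ctrl = [("IL-6", "KC", 1), ("MCP-1", "VEGF", 2), ("TNF-a", "IP-10", 3)]
    ko_apap = [("IL-6", "TNF-a", 1)]
    planted = (
        [PlantedEdge(a, b, k, r, "WT_APAP") for a, b, k in wt_apap]
        + [PlantedEdge(a, b, k, r, "WT_control") for a, b, k in wt_ctrl]
        + [PlantedEdge(a, b, k, r, "KO_APAP") for a, b, k in ko_apap]
    )
    effects = {
        ("HMGB1", "KO_control"): 0.02,
        ("HMGB1", "KO_APAP"): 0.02,
        ("HMGB1", "WT_APAP"): 3.0,
        ("GDF-15", "WT_APAP"): 3.0,
        ("GDF-15", "KO_APAP"): 1.2,
        ("IL-6", "WT_APAP"): 2.0,
        ("KC", "WT_APAP"): 2.0,
    }
    return SyntheticSpec(
        mediators=P,
        subgroup_sizes={"WT_control": 3, "WT_APAP": 3, "KO_control": 4, "KO_APAP": 5},
        time_grid=[1.0, 3.0, 6.0, 24.0, 48.0],
        baseline_log_mean=baselines,
        baseline_log_sd=0.3,
        group_effects=effects,
        planted_edges=planted,
        ar_self={"HMGB1": 0.6, "GDF-15": 0.6},
        ar_noise_sd=0.5,
        noise_log_sd=0.25,
        missing_rate=0.0,
        age_effects={},
        age_range=(8.0, 12.0),  # weeks; recorded but unused by analyses
        seed=seed,
        tags={"preset": "hepatocyte", "note": "stylized shape; effect sizes synthetic"},
    )
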
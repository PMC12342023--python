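"""Dynamic Bayesian network (DyBN) inference over mediator time series.

A first-order DBN: each mediator at time t+1 is a Gaussian function of a
small set of lag-1 parents (possibly including itself — a self-feedback
loop).  Families are scored with the BGe (Bayesian Gaussian with score
equivalence) marginal likelihood under a Normal–Wishart prior, made
inhomogeneous by node-specific changepoints at which the Gaussian
parameters (not the structure) may switch.  A Metropolis–Hastings sampler
explores parent sets (add/remove/swap) and changepoints
(birth/death/relocate); edge posteriors are sample frequencies, and the
consensus graph keeps edges above a posterior threshold.  Central
(high-feedback) nodes are those with a self-loop plus at least one
connection to another mediator.

Because a lag-1 DBN has no acyclicity constraint, the posterior factorises
over child families and the move set never couples children; the sampler
therefore runs one chain per child, which is the same Markov chain
restricted to its independent component.

BGe marginal likelihood of N complete d-dimensional rows Y under
μ | W ~ N(0, (α_μ W)⁻¹), W ~ Wishart(ν, T₀⁻¹):

    p(Y) = π^(−Nd/2) (α_μ/(α_μ+N))^(d/2) |T₀|^(ν/2) / |T_N|^((ν+N)/2)
           · Γ_d((ν+N)/2) / Γ_d(ν/2)

with T_N = T₀ + S + (α_μ N/(α_μ+N)) ȳȳᵀ and S the centered scatter.  The
family score is the Geiger–Heckerman decomposition
score(child | parents) = log p(family block) − log p(parent block), with
the degrees of freedom for a block of size l set to l + dof_extra and a
scalar-diagonal T₀ — a choice under which the decomposition telescopes and
Markov-equivalent structures score identically.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import multigammaln
from sklearn.base import BaseEstimator

from .dataset import MediatorDataset
from .exceptions import ConfigError, DynanetError

__all__ = [
    "BgeHyperparams",
    "ChangepointConfig",
    "TransitionTable",
    "DybnPosterior",
    "ConsensusGraph",
    "build_transitions",
    "bge_log_marginal",
    "bge_family_score",
    "network_log_score",
    "mcmc_sample",
    "exact_posterior",
    "consensus",
    "DynamicBayesianNetwork",
]


@dataclass(frozen=True)
class BgeHyperparams:
    """Normal–Wishart prior settings for the BGe score.

    ``alpha_mu`` scales the prior precision of the mean; a block of size l
    uses Wishart degrees of freedom ``l + dof_extra`` and prior scale
    matrix ``t0_scale · I``.  Defaults are weak-prior conventions for
    z-scored data.
    """

    alpha_mu: float = 1.0
    dof_extra: float = 2.0
    t0_scale: float = 0.5

    def __post_init__(self):
        if self.alpha_mu <= 0:
            raise ConfigError("alpha_mu must be > 0")
        if self.dof_extra < 1.0:
            raise ConfigError("dof_extra must be >= 1 (alpha_w >= d)")
        if self.t0_scale <= 0:
            raise ConfigError("t0_scale must be > 0 (T0 positive definite)")


@dataclass(frozen=True)
class ChangepointConfig:
    """Node-specific changepoint settings.

    ``k_max`` caps the number of changepoints per node, ``min_segment`` is
    the minimum segment length in time steps (transitions), and the
    changepoint count carries a truncated Poisson(``lambda_cp``) prior with
    positions uniform over valid configurations of that count.
    """

    k_max: int = 1
    min_segment: int = 2
    lambda_cp: float = 1.0

    def __post_init__(self):
        if self.k_max < 0:
            raise ConfigError("k_max must be >= 0")
        if self.min_segment < 2:
            raise ConfigError("min_segment must be >= 2 transitions")
        if self.lambda_cp <= 0:
            raise ConfigError("lambda_cp must be > 0")


@dataclass
class TransitionTable:
    """Pooled (x_t, x_{t+1}) pairs over consecutive observed time points.

    ``x`` holds the normalized mediator vectors at the start of each
    transition, ``y`` at the end; ``start_index`` is the position of the
    start time on the dataset's time grid.  Gaps in a subject's series
    break the chain (strict-consecutive policy); per-family missing values
    are dropped at scoring time.
    """

    mediators: list[str]
    x: np.ndarray
    y: np.ndarray
    start_index: np.ndarray
    subjects: np.ndarray
    n_steps: int  # number of possible start indices (len(time_grid) - 1)

    @property
    def n_transitions(self) -> int:
        return self.x.shape[0]


def build_transitions(
    ds: MediatorDataset, subgroup: str, log_transform: bool = True
) -> TransitionTable:
    """Normalize a subgroup (log then per-mediator z-score by default —
    concentrations are right-skewed and the score is Gaussian) and pool
    strict-consecutive transitions across its subjects."""
    z, excluded = ds.zscore_by_mediator(subgroup, log_transform=log_transform)
    meds = [m for m in ds.mediators if m not in excluded]
    z = z[meds]
    z = z.dropna(how="all")  # a fully-missing sample is an unobserved time
    grid = ds.time_grid
    pos = {t: i for i, t in enumerate(grid)}
    xs, ys, starts, subs = [], [], [], []
    for subject, block in z.groupby(level="subject", sort=True):
        block = block.droplevel("subject").sort_index()
        tidx = [pos[t] for t in block.index]
        for row, u in enumerate(tidx[:-1]):
            if tidx[row + 1] == u + 1:
                xs.append(block.iloc[row].to_numpy())
                ys.append(block.iloc[row + 1].to_numpy())
                starts.append(u)
                subs.append(subject)
    if not xs:
        raise DynanetError(f"no transitions for subgroup {subgroup!r}")
    table = TransitionTable(
        mediators=meds,
        x=np.asarray(xs, dtype=float),
        y=np.asarray(ys, dtype=float),
        start_index=np.asarray(starts, dtype=int),
        subjects=np.asarray(subs, dtype=object),
        n_steps=len(grid) - 1,
    )
    if table.n_transitions < len(meds) + 2:
        warnings.warn(
            f"only {table.n_transitions} transitions for {len(meds)} mediators; "
            "posterior will be prior-dominated",
            UserWarning,
            stacklevel=2,
        )
    return table


# ---------------------------------------------------------------------- #
# BGe score

def bge_log_marginal(
    data: np.ndarray, alpha_mu: float, nu: float, t0_scale: float
) -> float:
    """Closed-form log marginal likelihood of complete rows ``data``
    (N × d) under the Normal–Wishart prior described in the module
    docstring.  Empty data scores exactly 0 (empty-product likelihood)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    N, d = data.shape
    if N == 0 or d == 0:
        return 0.0
    if nu <= d - 1:
        raise ConfigError(f"Wishart dof {nu} must exceed d-1 = {d - 1}")
    ybar = data.mean(axis=0)
    centered = data - ybar
    S = centered.T @ centered
    TN = (
        t0_scale * np.eye(d)
        + S
        + (alpha_mu * N / (alpha_mu + N)) * np.outer(ybar, ybar)
    )
    sign, logdet = np.linalg.slogdet(TN)
    if sign <= 0:
        cond = np.linalg.cond(TN)
        raise DynanetError(
            f"singular posterior scale matrix (condition number {cond:.3g})"
        )
    return (
        -0.5 * N * d * math.log(math.pi)
        + 0.5 * d * (math.log(alpha_mu) - math.log(alpha_mu + N))
        + multigammaln(0.5 * (nu + N), d)
        - multigammaln(0.5 * nu, d)
        + 0.5 * nu * d * math.log(t0_scale)
        - 0.5 * (nu + N) * logdet
    )


def _log_ml_from_moments(
    N: int, s: np.ndarray, O: np.ndarray, alpha_mu: float, nu: float, t0_scale: float
) -> float:
    """Same quantity as :func:`bge_log_marginal` from sufficient statistics
    (count, sum vector, raw outer-product sum)."""
    d = s.shape[0]
    if N == 0:
        return 0.0
    ybar = s / N
    S = O - N * np.outer(ybar, ybar)
    TN = t0_scale * np.eye(d) + S + (alpha_mu * N / (alpha_mu + N)) * np.outer(ybar, ybar)
    sign, logdet = np.linalg.slogdet(TN)
    if sign <= 0:
        raise DynanetError("singular posterior scale matrix")
    return (
        -0.5 * N * d * math.log(math.pi)
        + 0.5 * d * (math.log(alpha_mu) - math.log(alpha_mu + N))
        + multigammaln(0.5 * (nu + N), d)
        - multigammaln(0.5 * nu, d)
        + 0.5 * nu * d * math.log(t0_scale)
        - 0.5 * (nu + N) * logdet
    )


class _FamilyScorer:
    """Cached BGe family scores over a transition table.

    With complete data the per-start-index sufficient statistics of the
    joint (x_t, x_{t+1}) vector are precomputed once, so any family score
    over any contiguous segment is a small matrix operation; with missing
    values the family's complete cases are selected on demand.  Scores are
    memoized by (child, parents, segment)."""

    def __init__(self, table: TransitionTable, hyper: BgeHyperparams):
        self.table = table
        self.hyper = hyper
        self.n = len(table.mediators)
        self._cache: dict = {}
        self._complete = not (
            np.isnan(table.x).any() or np.isnan(table.y).any()
        )
        if self._complete:
            joint = np.hstack([table.x, table.y])
            self._counts = np.zeros(table.n_steps, dtype=int)
            self._sums = np.zeros((table.n_steps, 2 * self.n))
            self._outers = np.zeros((table.n_steps, 2 * self.n, 2 * self.n))
            for u in range(table.n_steps):
                rows = joint[table.start_index == u]
                self._counts[u] = rows.shape[0]
                if rows.shape[0]:
                    self._sums[u] = rows.sum(axis=0)
                    self._outers[u] = rows.T @ rows

    def score(
        self, child: int, parents: tuple[int, ...], lo: int, hi: int
    ) -> float:
        """log p(child | parents) over transitions with start index in
        [lo, hi)."""
        key = (child, parents, lo, hi)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        h = self.hyper
        l_fam = len(parents) + 1
        if self._complete:
            cols = list(parents) + [self.n + child]
            N = int(self._counts[lo:hi].sum())
            s = self._sums[lo:hi].sum(axis=0)
            O = self._outers[lo:hi].sum(axis=0)
            fam = _log_ml_from_moments(
                N, s[cols], O[np.ix_(cols, cols)], h.alpha_mu, l_fam + h.dof_extra,
                h.t0_scale,
            )
            if parents:
                pc = list(parents)
                fam -= _log_ml_from_moments(
                    N, s[pc], O[np.ix_(pc, pc)], h.alpha_mu,
                    len(parents) + h.dof_extra, h.t0_scale,
                )
        else:
            in_seg = (self.table.start_index >= lo) & (self.table.start_index < hi)
            cols = np.column_stack(
                [self.table.x[in_seg][:, list(parents)], self.table.y[in_seg, child]]
            )
            ok = ~np.isnan(cols).any(axis=1)
            block = cols[ok]
            fam = bge_log_marginal(block, h.alpha_mu, l_fam + h.dof_extra, h.t0_scale)
            if parents:
                fam -= bge_log_marginal(
                    block[:, :-1], h.alpha_mu, len(parents) + h.dof_extra, h.t0_scale
                )
        self._cache[key] = fam
        return fam


def bge_family_score(
    table: TransitionTable,
    child: str,
    parents: Sequence[str],
    segment: tuple[int, int] | None = None,
    hyper: BgeHyperparams | None = None,
) -> float:
    """Log marginal-likelihood contribution of one child family over one
    segment (start-index range; ``None`` = the whole series)."""
    hyper = hyper or BgeHyperparams()
    idx = {m: i for i, m in enumerate(table.mediators)}
    lo, hi = segment if segment is not None else (0, table.n_steps)
    scorer = _FamilyScorer(table, hyper)
    return scorer.score(idx[child], tuple(sorted(idx[p] for p in parents)), lo, hi)


# ---------------------------------------------------------------------- #
# changepoint bookkeeping

def _valid_positions(n_steps: int, cfg: ChangepointConfig) -> list[int]:
    return list(range(cfg.min_segment, n_steps - cfg.min_segment + 1))


def _valid_configs(n_steps: int, cfg: ChangepointConfig) -> dict[int, list[tuple[int, ...]]]:
    """All admissible changepoint tuples grouped by count."""
    positions = _valid_positions(n_steps, cfg)
    out: dict[int, list[tuple[int, ...]]] = {0: [()]}
    for k in range(1, cfg.k_max + 1):
        configs = [
            c
            for c in itertools.combinations(positions, k)
            if all(b - a >= cfg.min_segment for a, b in zip(c, c[1:]))
        ]
        if not configs:
            break
        out[k] = configs
    return out


def _cp_log_prior(cps: tuple[int, ...], configs: dict, cfg: ChangepointConfig) -> float:
    ks = sorted(configs)
    lam = cfg.lambda_cp
    log_pois = {k: k * math.log(lam) - lam - math.lgamma(k + 1) for k in ks}
    norm = math.log(sum(math.exp(v) for v in log_pois.values()))
    k = len(cps)
    return log_pois[k] - norm - math.log(len(configs[k]))


def _segments(cps: tuple[int, ...], n_steps: int) -> list[tuple[int, int]]:
    bounds = [0, *cps, n_steps]
    return list(zip(bounds[:-1], bounds[1:]))


# ---------------------------------------------------------------------- #
# network score

def network_log_score(
    structure: Mapping[str, Sequence[str]],
    changepoints: Mapping[str, Sequence[int]],
    table: TransitionTable,
    hyper: BgeHyperparams | None = None,
    cpconfig: ChangepointConfig | None = None,
    fan_in: int = 3,
) -> float:
    """Total log score of a structure + segmentation: BGe family scores
    summed over nodes and segments, plus the uniform-structure and
    truncated-Poisson changepoint priors."""
    hyper = hyper or BgeHyperparams()
    cpconfig = cpconfig or ChangepointConfig()
    idx = {m: i for i, m in enumerate(table.mediators)}
    scorer = _FamilyScorer(table, hyper)
    configs = _valid_configs(table.n_steps, cpconfig)
    n_sets = sum(
        math.comb(len(table.mediators), k) for k in range(fan_in + 1)
    )
    total = 0.0
    for child in table.mediators:
        parents = tuple(sorted(idx[p] for p in structure.get(child, ())))
        if len(parents) > fan_in:
            raise ConfigError(f"family of {child!r} exceeds fan-in {fan_in}")
        cps = tuple(sorted(changepoints.get(child, ())))
        if cps and cps not in set(configs.get(len(cps), ())):
            raise ConfigError(f"invalid segmentation for {child!r}: {cps}")
        for lo, hi in _segments(cps, table.n_steps):
            total += scorer.score(idx[child], parents, lo, hi)
        total += _cp_log_prior(cps, configs, cpconfig) - math.log(n_sets)
    return total


# ---------------------------------------------------------------------- #
# posterior containers

@dataclass
class DybnPosterior:
    """Posterior edge probabilities and sampler by-products."""

    mediators: list[str]
    edge_posterior: pd.DataFrame  # index = child, columns = parent
    changepoint_samples: dict  # child -> list of changepoint tuples
    acceptance: dict  # child -> acceptance rate
    log_score_trace: dict  # child -> thinned log-posterior values
    config: dict
    seed: int | None
    excluded: list = field(default_factory=list)

    @property
    def self_loop(self) -> pd.Series:
        return pd.Series(
            np.diag(self.edge_posterior.values), index=self.mediators, name="self_loop"
        )


@dataclass
class ConsensusGraph:
    """Thresholded posterior digraph with self-feedback annotation."""

    graph: nx.DiGraph
    threshold: float
    self_feedback: list
    central: list

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"parent": a, "child": b, "posterior": d["posterior"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["parent", "child", "posterior"])


def consensus(posterior: DybnPosterior, threshold: float = 0.5) -> ConsensusGraph:
    """Directed edges with posterior ≥ threshold; nodes whose self-loop
    passes are self-feedback, and 'central' if additionally connected to at
    least one other mediator."""
    if not 0.0 < threshold < 1.0:
        raise ConfigError(f"consensus threshold must be in (0, 1), got {threshold}")
    g = nx.DiGraph()
    g.add_nodes_from(posterior.mediators)
    P = posterior.edge_posterior
    for child in posterior.mediators:
        for parent in posterior.mediators:
            p = float(P.at[child, parent])
            if p >= threshold:
                g.add_edge(parent, child, posterior=p)
    self_fb = [m for m in posterior.mediators if g.has_edge(m, m)]
    central = [
        m
        for m in self_fb
        if any(b != m for _, b in g.out_edges(m)) or any(a != m for a, _ in g.in_edges(m))
    ]
    return ConsensusGraph(graph=g, threshold=threshold, self_feedback=self_fb, central=central)


# ---------------------------------------------------------------------- #
# samplers

def _structure_neighbourhood(
    parents: tuple[int, ...], n: int, fan_in: int
) -> list[tuple[int, ...]]:
    """Parent sets reachable by one add/remove/swap move."""
    pset = set(parents)
    others = [j for j in range(n) if j not in pset]
    out = []
    if len(parents) < fan_in:
        for j in others:
            out.append(tuple(sorted(pset | {j})))
    for j in parents:
        out.append(tuple(sorted(pset - {j})))
    for j in parents:
        for k in others:
            out.append(tuple(sorted((pset - {j}) | {k})))
    return out


def _cp_neighbourhood(
    cps: tuple[int, ...], configs: dict, k_max: int
) -> list[tuple[int, ...]]:
    """Changepoint tuples reachable by one birth/death/relocate move."""
    valid = {k: set(v) for k, v in configs.items()}
    out = []
    k = len(cps)
    if k < k_max and (k + 1) in valid:  # birth
        cset = set(cps)
        for c in valid[k + 1]:
            if cset <= set(c):
                out.append(c)
    for i in range(k):  # death
        out.append(tuple(p for j, p in enumerate(cps) if j != i))
    if k:  # relocate one
        for i in range(k):
            rest = set(p for j, p in enumerate(cps) if j != i)
            for c in valid.get(k, ()):
                diff = set(c) - rest
                if rest <= set(c) and len(diff) == 1 and c != cps:
                    out.append(c)
    return out


def _run_child_chain(
    scorer: _FamilyScorer,
    child: int,
    configs: dict,
    cpconfig: ChangepointConfig,
    fan_in: int,
    iterations: int,
    burn_in: int,
    thinning: int,
    rng: np.random.Generator,
):
    n = scorer.n
    n_steps = scorer.table.n_steps

    def log_post(parents, cps):
        val = _cp_log_prior(cps, configs, cpconfig)
        for lo, hi in _segments(cps, n_steps):
            val += scorer.score(child, parents, lo, hi)
        return val

    parents: tuple[int, ...] = ()
    cps: tuple[int, ...] = ()
    current = log_post(parents, cps)
    cp_space = cpconfig.k_max > 0 and len(configs) > 1

    parent_hits = np.zeros(n)
    cp_samples = []
    trace = []
    n_kept = 0
    accepted = 0
    for it in range(iterations):
        move_cp = cp_space and rng.random() < 0.5
        if move_cp:
            nbrs = _cp_neighbourhood(cps, configs, cpconfig.k_max)
            if not nbrs:
                move_cp = False
        if not move_cp:
            nbrs = _structure_neighbourhood(parents, n, fan_in)
        prop = nbrs[rng.integers(len(nbrs))]
        if move_cp:
            new_parents, new_cps = parents, prop
            back = _cp_neighbourhood(new_cps, configs, cpconfig.k_max)
        else:
            new_parents, new_cps = prop, cps
            back = _structure_neighbourhood(new_parents, n, fan_in)
        proposed = log_post(new_parents, new_cps)
        log_alpha = proposed - current + math.log(len(nbrs)) - math.log(len(back))
        if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
            parents, cps, current = new_parents, new_cps, proposed
            accepted += 1
        if it >= burn_in and (it - burn_in) % thinning == 0:
            n_kept += 1
            for j in parents:
                parent_hits[j] += 1
            cp_samples.append(cps)
            trace.append(current)
    return parent_hits / max(n_kept, 1), cp_samples, accepted / iterations, trace


def mcmc_sample(
    table: TransitionTable,
    hyper: BgeHyperparams | None = None,
    cpconfig: ChangepointConfig | None = None,
    iterations: int = 20000,
    burn_in: int = 5000,
    thinning: int = 10,
    fan_in: int = 3,
    seed: int | None = None,
) -> DybnPosterior:
    """Metropolis–Hastings over (parent sets, changepoints) for every
    child; deterministic given ``seed``."""
    hyper = hyper or BgeHyperparams()
    cpconfig = cpconfig or ChangepointConfig()
    if burn_in < 0 or iterations <= burn_in:
        raise ConfigError("need iterations > burn_in >= 0")
    if thinning < 1:
        raise ConfigError("thinning must be >= 1")
    if fan_in < 1:
        raise ConfigError("fan_in must be >= 1")
    scorer = _FamilyScorer(table, hyper)
    configs = _valid_configs(table.n_steps, cpconfig)
    meds = table.mediators
    n = len(meds)
    P = np.zeros((n, n))
    cp_samples, acceptance, traces = {}, {}, {}
    for c in range(n):
        rng = np.random.default_rng(
            np.random.SeedSequence([0 if seed is None else int(seed), c])
        )
        probs, cp_s, acc, trace = _run_child_chain(
            scorer, c, configs, cpconfig, fan_in, iterations, burn_in, thinning, rng
        )
        P[c] = probs
        cp_samples[meds[c]] = cp_s
        acceptance[meds[c]] = acc
        traces[meds[c]] = trace
        if acc < 0.01:
            warnings.warn(
                f"acceptance rate {acc:.3f} for child {meds[c]!r} is below 1%",
                UserWarning,
                stacklevel=2,
            )
    return DybnPosterior(
        mediators=meds,
        edge_posterior=pd.DataFrame(P, index=meds, columns=meds),
        changepoint_samples=cp_samples,
        acceptance=acceptance,
        log_score_trace=traces,
        config={
            "hyper": {
                "alpha_mu": hyper.alpha_mu,
                "dof_extra": hyper.dof_extra,
                "t0_scale": hyper.t0_scale,
            },
            "changepoints": {
                "k_max": cpconfig.k_max,
                "min_segment": cpconfig.min_segment,
                "lambda_cp": cpconfig.lambda_cp,
            },
            "mcmc": {
                "iterations": iterations,
                "burn_in": burn_in,
                "thinning": thinning,
                "fan_in": fan_in,
            },
        },
        seed=seed,
    )


def exact_posterior(
    table: TransitionTable,
    hyper: BgeHyperparams | None = None,
    cpconfig: ChangepointConfig | None = None,
    fan_in: int = 3,
) -> pd.DataFrame:
    """Edge posteriors by exhaustive enumeration of parent sets and
    changepoint configurations (feasible for small panels)."""
    hyper = hyper or BgeHyperparams()
    cpconfig = cpconfig or ChangepointConfig()
    scorer = _FamilyScorer(table, hyper)
    configs = _valid_configs(table.n_steps, cpconfig)
    meds = table.mediators
    n = len(meds)
    all_sets = [
        tuple(sorted(c))
        for k in range(fan_in + 1)
        for c in itertools.combinations(range(n), k)
    ]
    all_cps = [c for k in sorted(configs) for c in configs[k]]
    P = np.zeros((n, n))
    for child in range(n):
        logws, members = [], []
        for parents in all_sets:
            for cps in all_cps:
                w = _cp_log_prior(cps, configs, cpconfig)
                for lo, hi in _segments(cps, table.n_steps):
                    w += scorer.score(child, parents, lo, hi)
                logws.append(w)
                members.append(parents)
        logws = np.asarray(logws)
        w = np.exp(logws - logws.max())
        w /= w.sum()
        for weight, parents in zip(w, members):
            for j in parents:
                P[child, j] += weight
    return pd.DataFrame(P, index=meds, columns=meds)


# ---------------------------------------------------------------------- #
# estimator

class DynamicBayesianNetwork(BaseEstimator):
    """Changepoint DyBN inference with BGe scoring.

    Parameters mirror :func:`mcmc_sample`, :class:`BgeHyperparams` and
    :class:`ChangepointConfig`; ``edge_threshold`` sets the consensus rule
    and ``random_state`` seeds the sampler.

    Attributes (after :meth:`fit`)
    ------------------------------
    posterior_ : DybnPosterior
    edge_posterior_ : DataFrame (child × parent)
    consensus_ : ConsensusGraph
    self_feedback_, central_ : node lists
    transitions_ : TransitionTable
    excluded_ : mediators dropped for zero variance
    """

    def __init__(
        self,
        iterations: int = 20000,
        burn_in: int = 5000,
        thinning: int = 10,
        fan_in: int = 3,
        k_max: int = 1,
        min_segment: int = 2,
        lambda_cp: float = 1.0,
        alpha_mu: float = 1.0,
        dof_extra: float = 2.0,
        t0_scale: float = 0.5,
        edge_threshold: float = 0.5,
        random_state: int | None = None,
    ):
        self.iterations = iterations
        self.burn_in = burn_in
        self.thinning = thinning
        self.fan_in = fan_in
        self.k_max = k_max
        self.min_segment = min_segment
        self.lambda_cp = lambda_cp
        self.alpha_mu = alpha_mu
        self.dof_extra = dof_extra
        self.t0_scale = t0_scale
        self.edge_threshold = edge_threshold
        self.random_state = random_state

    def fit(self, ds: MediatorDataset, subgroup: str | None = None):
        if subgroup is None:
            raise ConfigError(f"subgroup is required; available: {ds.subgroups}")
        table = build_transitions(ds, subgroup)
        hyper = BgeHyperparams(self.alpha_mu, self.dof_extra, self.t0_scale)
        cpc = ChangepointConfig(self.k_max, self.min_segment, self.lambda_cp)
        post = mcmc_sample(
            table,
            hyper,
            cpc,
            iterations=self.iterations,
            burn_in=self.burn_in,
            thinning=self.thinning,
            fan_in=self.fan_in,
            seed=self.random_state,
        )
        post.excluded = [m for m in ds.mediators if m not in table.mediators]
        self.transitions_ = table
        self.posterior_ = post
        self.edge_posterior_ = post.edge_posterior
        self.consensus_ = consensus(post, self.edge_threshold)
        self.self_feedback_ = self.consensus_.self_feedback
        self.central_ = self.consensus_.central
        self.subgroup_ = subgroup
        self.excluded_ = post.excluded
        return self

    def write_outputs(self, outdir, prefix: str = "") -> None:
        import json
        import pathlib

        import yaml

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.edge_posterior_.round(6).to_csv(outdir / f"{prefix}posterior.csv")
        self.consensus_.edge_table().round(6).to_csv(
            outdir / f"{prefix}consensus_edges.csv", index=False
        )
        with open(outdir / f"{prefix}self_feedback.txt", "w") as fh:
            for m in self.self_feedback_:
                tag = "central" if m in self.central_ else "self-only"
                fh.write(f"{m}\t{tag}\n")
        diag = {
            "acceptance": self.posterior_.acceptance,
            "n_transitions": int(self.transitions_.n_transitions),
            "excluded_mediators": self.excluded_,
            "log_score_last": {
                m: (tr[-1] if tr else None)
                for m, tr in self.posterior_.log_score_trace.items()
            },
            "changepoint_rate": {
                m: float(np.mean([len(c) > 0 for c in s])) if s else 0.0
                for m, s in self.posterior_.changepoint_samples.items()
            },
        }
        with open(outdir / f"{prefix}diagnostics.json", "w") as fh:
            json.dump(diag, fh, indent=2)
        with open(outdir / f"{prefix}config.yaml", "w") as fh:
            yaml.safe_dump(
                {**self.posterior_.config, "seed": self.posterior_.seed}, fh
            )
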
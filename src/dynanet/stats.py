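"""Outcome-biomarker statistics.

Univariate comparisons used to screen mediators against outcome: the
Mann-Whitney rank-sum test, Spearman rank correlation (e.g. mediator level
vs age), ROC/AUC with an automatically chosen optimal cutoff (Youden J),
and volcano classification (fold change ≥ 2.0 at P < 0.05 by default).

Conventions:

* Mann-Whitney uses midranks for ties; the p-value is exact when the
  smaller group has ≤ 8 observations and there are no ties, otherwise the
  normal approximation with tie correction is used.  Two-sided throughout.
* Spearman rho is Pearson on midranks; p comes from the exact permutation
  null for n ≤ 10 and from the t approximation above that.
* AUC equals the normalized Mann-Whitney U statistic (ties counted ½);
  orientation is chosen automatically so AUC ≥ 0.5 and recorded.
* Volcano fold changes are ratios of geometric means (concentration data
  are positive and right-skewed), thresholds inclusive.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .dataset import MediatorDataset
from .exceptions import ConfigError

__all__ = [
    "StatResult",
    "RocResult",
    "VolcanoResult",
    "mann_whitney",
    "spearman",
    "roc_auc",
    "volcano",
]


@dataclass(frozen=True)
class StatResult:
    """Statistic value + two-sided p-value with method metadata."""

    method: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    tie_corrected: bool = False
    exact: bool = False


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    optimal_cutoff: float
    youden_j: float
    positive_group: str


@dataclass
class VolcanoResult:
    """Per-mediator log2 fold change (B over A), p-value and class."""

    table: pd.DataFrame  # columns: mediator, log2_fc, p_value, class
    fc_threshold: float
    alpha: float
    group_a: str
    group_b: str
    excluded: dict  # mediator -> reason

    def classes(self) -> pd.Series:
        return self.table.set_index("mediator")["class"]


# ---------------------------------------------------------------------- #

def _as_clean_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ConfigError(f"sample {name} is empty")
    return arr


def mann_whitney(x, y) -> StatResult:
    """Two-sided Mann-Whitney rank-sum test.

    Returns the U statistic of the first sample (midrank tie handling);
    exact p for min(n1, n2) ≤ 8 without ties, otherwise the tie-corrected
    normal approximation.
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (not has_ties) and min(x.size, y.size) <= 8
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    return StatResult(
        method="mann-whitney",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=(x.size, y.size),
        tie_corrected=has_ties and not use_exact,
        exact=use_exact,
    )


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Exact two-sided permutation p for Spearman rho (enumerates all n!
    orderings of one rank vector; midranks allowed)."""
    n = rx.size
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    count = 0
    total = 0
    chunk = []
    target = abs(rho) - 1e-12
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            rhos = (ry[np.asarray(chunk)] @ rx) / denom
            count += int((np.abs(rhos) >= target).sum())
            total += len(chunk)
            chunk = []
    if chunk:
        rhos = (ry[np.asarray(chunk)] @ rx) / denom
        count += int((np.abs(rhos) >= target).sum())
        total += len(chunk)
    return count / total


def spearman(x, y) -> StatResult:
    """Spearman rank correlation of paired samples (NaN pairs dropped).

    rho is Pearson on midranks; p is exact by permutation for n ≤ 10 and
    the t approximation otherwise.  Two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigError("spearman needs paired samples of equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ConfigError(f"spearman needs >= 3 complete pairs, got {n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.unique(rx).size == 1 or np.unique(ry).size == 1:
        raise ConfigError("spearman undefined for a constant sample")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        p = _exact_spearman_p(rx, ry, rho)
        exact = True
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(sps.t.sf(abs(t), n - 2))
        exact = False
    return StatResult(
        method="spearman",
        statistic=rho,
        p_value=min(p, 1.0),
        n=(n,),
        tie_corrected=np.unique(rx).size < n or np.unique(ry).size < n,
        exact=exact,
    )


def roc_auc(values, labels, positive=None) -> RocResult:
    """ROC curve and AUC for a continuous marker against binary labels.

    AUC is the trapezoid over all thresholds and equals U/(n1·n2) with ties
    as ½.  ``positive`` names the label treated as the positive class; by
    default orientation is chosen so AUC ≥ 0.5 (and recorded).  The optimal
    cutoff maximizes Youden's J = TPR − FPR, ties resolved to the lowest
    cutoff value.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = ~np.isnan(values)
    values, labels = values[ok], labels[ok]
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ConfigError(f"need exactly two label classes, got {list(classes)}")

    def _curve(pos):
        y = (labels == pos).astype(int)
        fpr, tpr, thr = roc_curve(y, values, drop_intermediate=False)
        return fpr, tpr, thr, float(np.trapezoid(tpr, fpr))

    if positive is None:
        fpr, tpr, thr, auc = _curve(classes[0])
        pos = classes[0]
        if auc < 0.5:
            fpr, tpr, thr, auc = _curve(classes[1])
            pos = classes[1]
    else:
        fpr, tpr, thr, auc = _curve(positive)
        pos = positive

    j = tpr - fpr
    best = j.max()
    # among J-maximizing thresholds pick the lowest finite cutoff
    candidates = thr[j >= best - 1e-12]
    finite = candidates[np.isfinite(candidates)]
    cutoff = float(finite.min()) if finite.size else float("nan")
    return RocResult(
        auc=float(auc),
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        optimal_cutoff=cutoff,
        youden_j=float(best),
        positive_group=str(pos),
    )


def volcano(
    ds: MediatorDataset,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> VolcanoResult:
    """Volcano classification of every mediator, B over A.

    Fold change is the ratio of geometric means over all pooled positive
    values (all subjects, all time points); the p-value is the rank-sum
    test on the same pooled samples.  ``up`` requires FC ≥ threshold and
    p < alpha (inclusive FC boundary), ``down`` FC ≤ 1/threshold and
    p < alpha.  No multiple-testing correction is applied.
    """
    if fc_threshold <= 1.0:
        raise ConfigError("fc_threshold must exceed 1")
    for g in (group_a, group_b):
        if g not in ds.subgroups:
            raise ConfigError(f"unknown subgroup {g!r}; available {ds.subgroups}")
    frame = ds.frame
    rows = []
    excluded = {}
    for m in ds.mediators:
        sub = frame[frame["mediator"] == m]
        a = sub.loc[sub["subgroup"] == group_a, "value"].dropna()
        b = sub.loc[sub["subgroup"] == group_b, "value"].dropna()
        if a.empty or b.empty:
            excluded[m] = f"no observations in {'both' if a.empty and b.empty else (group_a if a.empty else group_b)}"
            continue
        a_pos, b_pos = a[a > 0], b[b > 0]
        if a_pos.empty or b_pos.empty:
            excluded[m] = "no positive values for geometric mean"
            continue
        log2fc = float(np.log2(b_pos).mean() - np.log2(a_pos).mean())
        p = mann_whitney(b, a).p_value
        # inclusive threshold compared in log space (1e-9 guard so that an
        # exact 2-fold ratio is not lost to rounding)
        log2_thr = math.log2(fc_threshold)
        if p < alpha and log2fc >= log2_thr - 1e-9:
            cls = "up"
        elif p < alpha and log2fc <= -log2_thr + 1e-9:
            cls = "down"
        else:
            cls = "not-significant"
        rows.append({"mediator": m, "log2_fc": log2fc, "p_value": p, "class": cls})
    table = (
        pd.DataFrame(rows, columns=["mediator", "log2_fc", "p_value", "class"])
        .sort_values("p_value", kind="mergesort")
        .reset_index(drop=True)
    )
    return VolcanoResult(
        table=table,
        fc_threshold=fc_threshold,
        alpha=alpha,
        group_a=group_a,
        group_b=group_b,
        excluded=excluded,
    )


def spearman_vs_covariate(ds: MediatorDataset, covariate: str = "age") -> pd.DataFrame:
    """Spearman correlation of each mediator (pooled over time) against a
    per-subject covariate from ``ds.subject_meta``; one row per mediator."""
    if ds.subject_meta is None or covariate not in ds.subject_meta.columns:
        raise ConfigError(f"dataset has no subject covariate {covariate!r}")
    cov = ds.subject_meta[covariate]
    rows = []
    for m in ds.mediators:
        sub = ds.frame[ds.frame["mediator"] == m].dropna(subset=["value"])
        x = cov.reindex(sub["subject"]).to_numpy()
        y = sub["value"].to_numpy()
        ok = ~np.isnan(x)
        if ok.sum() < 3:
            continue
        res = spearman(x[ok], y[ok])
        rows.append(
            {"mediator": m, "rho": res.statistic, "p_value": res.p_value, "n": res.n[0]}
        )
    return pd.DataFrame(rows, columns=["mediator", "rho", "p_value", "n"])
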
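"""Differential feature analysis.

Welch's unequal-variance t-test with Satterthwaite degrees of freedom,
Benjamini-Hochberg step-up FDR adjustment, log2 fold changes with a
zero-intensity floor, volcano significance calls (adjusted p <= 0.01 and
|log2FC| >= 0.3 by default), multi-condition overlap (Venn) summaries, and
one-way ANOVA with Tukey's HSD post hoc test for three-group modulation
experiments.

Technical replicates are collapsed to their biological-replicate means
before testing so that n equals the number of biological replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .preprocess import FeatureMatrix

logger = logging.getLogger("lipidfinger")

DEFAULT_ALPHA = 0.01
DEFAULT_FC_MIN = 0.3


def welch_t(x, y, axis: int = -1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch's two-sided t-test: returns (t, Satterthwaite df, p).

    Accepts 1-D samples or stacked 2-D arrays (features along the other
    axis). Zero variance in both groups gives t=0, p=1 for equal means and
    p -> 0 (warned) for unequal means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.shape[axis], y.shape[axis]
    if nx < 2 or ny < 2:
        raise ValidationError("each group needs at least 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in input")
    mx, my = x.mean(axis=axis), y.mean(axis=axis)
    vx, vy = x.var(axis=axis, ddof=1), y.var(axis=axis, ddof=1)
    sx, sy = vx / nx, vy / ny
    denom = np.sqrt(sx + sy)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / denom
        df = (sx + sy) ** 2 / (sx**2 / (nx - 1) + sy**2 / (ny - 1))
    zero_var = denom == 0
    if np.any(zero_var):
        equal = zero_var & (mx == my)
        unequal = zero_var & (mx != my)
        t = np.where(equal, 0.0, t)
        df = np.where(zero_var, nx + ny - 2, df)
        if np.any(unequal):
            logger.warning("zero variance with unequal means: p-value degenerates to 0")
            t = np.where(unequal, np.sign(mx - my) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    if t.ndim == 0:
        return float(t), float(df), float(p)
    return t, df, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    p_adj(i) = min_{j >= i} (m/j) p(j) over the ascending ordering, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def log2_fold_change(treated, control, eps: float | None = None):
    """log2((mean_treated + eps) / (mean_control + eps)).

    ``eps`` defaults to half the smallest positive value across both groups
    (a floor against zero means). Both means zero gives 0 with a warning.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    mt = treated.mean(axis=-1) if treated.ndim > 0 else treated
    mc = control.mean(axis=-1) if control.ndim > 0 else control
    if eps is None:
        pos = np.concatenate([treated.ravel(), control.ravel()])
        pos = pos[pos > 0]
        eps = 0.5 * float(pos.min()) if pos.size else 1.0
    both_zero = (np.asarray(mt) == 0) & (np.asarray(mc) == 0)
    if np.any(both_zero):
        logger.warning("both group means zero for %d feature(s); log2FC set to 0",
                       int(np.sum(both_zero)))
    lfc = np.log2((mt + eps) / (mc + eps))
    lfc = np.where(both_zero, 0.0, lfc)
    return float(lfc) if lfc.ndim == 0 else lfc


def classify_volcano(
    results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    fc_min: float = DEFAULT_FC_MIN,
) -> pd.DataFrame:
    """Flag rows significant when p_adj <= alpha and |log2fc| >= fc_min."""
    out = results.copy()
    out["significant"] = (out["p_adj"] <= alpha) & (out["log2fc"].abs() >= fc_min)
    return out


def differential_analysis(
    fm: FeatureMatrix,
    treated: str,
    control: str,
    collapse_technical: bool = True,
    alpha: float = DEFAULT_ALPHA,
    fc_min: float = DEFAULT_FC_MIN,
) -> pd.DataFrame:
    """Per-feature Welch test + BH + log2FC between two groups of a matrix.

    Returns a DataFrame with columns feature_mz, log2fc, t, df, p, p_adj,
    significant.
    """
    if collapse_technical:
        fm = fm.collapse_technical()
    x = fm.group_values(treated)
    y = fm.group_values(control)
    if x.shape[1] < 2 or y.shape[1] < 2:
        raise ValidationError("need >= 2 replicates per group")
    # variance-stabilize before testing: intensities are multiplicative
    pos = np.concatenate([x.ravel(), y.ravel()])
    pos = pos[pos > 0]
    eps = 0.5 * float(pos.min()) if pos.size else 1.0
    t, df, p = welch_t(np.log2(x + eps), np.log2(y + eps), axis=1)
    table = pd.DataFrame(
        {
            "feature_mz": fm.feature_mz,
            "log2fc": log2_fold_change(x, y),
            "t": t,
            "df": df,
            "p": p,
            "p_adj": bh_adjust(p),
        }
    )
    return classify_volcano(table, alpha=alpha, fc_min=fc_min)


@dataclass
class OverlapResult:
    """Region counts of significant-feature sets across conditions."""

    sets: dict[str, frozenset]
    regions: dict[tuple[str, ...], int] = field(default_factory=dict)
    union_size: int = 0
    intersection_size: int = 0
    shared_fraction_percent: float = 0.0


def venn_overlap(sets: Mapping[str, Sequence]) -> OverlapResult:
    """Exact region counts for >= 2 condition sets of feature identifiers.

    Features come from one shared picked list, so identifiers (indices or
    representative m/z) match exactly. ``regions`` maps each non-empty
    combination of conditions to the count of features in exactly those
    conditions. The shared fraction |intersection|/|union| is reported as a
    percentage rounded half-even to 1 decimal.
    """
    if len(sets) < 2:
        raise ValidationError("need at least 2 conditions")
    frozen = {k: frozenset(v) for k, v in sets.items()}
    names = list(frozen)
    union = frozenset().union(*frozen.values())
    inter = frozenset.intersection(*frozen.values())
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = frozenset.intersection(*(frozen[c] for c in combo))
            outside = frozenset().union(
                *(frozen[c] for c in names if c not in combo), frozenset()
            )
            regions[combo] = len(inside - outside)
    shared = 100.0 * len(inter) / len(union) if union else 0.0
    result = OverlapResult(
        sets=frozen,
        regions=regions,
        union_size=len(union),
        intersection_size=len(inter),
        shared_fraction_percent=float(np.round(shared, 1)),
    )
    return result


def anova_tukey(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA F test plus Tukey HSD pairwise comparisons.

    Returns (F, p, pairs) where pairs has columns group_a, group_b,
    mean_diff, p_adj, significant (p_adj <= alpha).
    """
    if len(groups) < 3:
        raise ValidationError("need at least 3 groups")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    for name, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValidationError(f"group {name!r} needs at least 2 values")
    f_stat, p_value = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i, j in combinations(range(len(names)), 2):
        p_adj = float(hsd.pvalue[i, j])
        rows.append(
            dict(
                group_a=names[i],
                group_b=names[j],
                mean_diff=float(arrays[i].mean() - arrays[j].mean()),
                p_adj=p_adj,
                significant=p_adj <= alpha,
            )
        )
    return float(f_stat), float(p_value), pd.DataFrame(rows)
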
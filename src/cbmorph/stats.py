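"""Group-level inference for morphometric features.

One-way ANOVA, Dunnett comparisons against a control group (multiplicity
adjustment by seeded Monte-Carlo simulation of the max-|t| null),
Bonferroni-adjusted selected pairwise t-tests, and empirical ROC curves
with the conventional AUC accuracy bands
(no value < 0.6 <= poor < 0.7 <= fair < 0.8 <= good < 0.9 <= excellent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InvalidArgumentError, InvalidInputError

__all__ = [
    "one_way_anova",
    "DunnettResult",
    "dunnett_vs_control",
    "bonferroni_pairs",
    "ROCResult",
    "roc_curve",
    "classify_auc",
]


def _as_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise InvalidArgumentError("need at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise InvalidArgumentError("every group needs at least 2 values")
    if any(not np.isfinite(g).all() for g in gs):
        raise InvalidInputError("groups contain non-finite values")
    return gs


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, p).

    Degenerate cases: zero within-group variance with equal means gives
    (0, 1); zero within-group variance with unequal means gives (inf, 0).
    """
    gs = _as_groups(groups)
    k = len(gs)
    ns = np.array([g.size for g in gs])
    N = int(ns.sum())
    grand = float(np.concatenate(gs).mean())
    ssb = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, gs)))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    dfb, dfw = k - 1, N - k
    if ssw == 0.0:
        return (0.0, 1.0) if ssb == 0.0 else (float("inf"), 0.0)
    F = (ssb / dfb) / (ssw / dfw)
    return F, float(sps.f.sf(F, dfb, dfw))


@dataclass(frozen=True)
class DunnettResult:
    comparisons: list[int]  # indices of the non-control groups, in order
    t_stats: np.ndarray
    p_raw: np.ndarray  # unadjusted two-sided pooled t-test p values
    p_adjusted: np.ndarray  # family-wise adjusted (max-|t| Monte-Carlo)
    reject: np.ndarray  # p_adjusted < alpha
    alpha: float


def dunnett_vs_control(
    groups,
    control_index: int = 0,
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int = 0,
) -> DunnettResult:
    """Two-sided Dunnett comparisons of each group against the control.

    t statistics use the variance pooled over *all* groups.  The adjusted
    p value of comparison i is P(max_j |T_j| >= |t_i|) under the joint
    null, estimated from ``n_mc`` seeded Monte-Carlo draws of the group
    means and pooled variance, then clipped from below by the unadjusted
    t p-value so adjusted >= raw holds exactly.
    """
    if n_mc < 1000:
        raise InvalidArgumentError("n_mc must be >= 1000 for a usable estimate")
    gs = _as_groups(groups)
    k = len(gs)
    if not (0 <= control_index < k):
        raise InvalidArgumentError("control_index out of range")
    ns = np.array([g.size for g in gs])
    N, dfw = int(ns.sum()), int(ns.sum()) - k
    s2 = sum(((g - g.mean()) ** 2).sum() for g in gs) / dfw
    others = [i for i in range(k) if i != control_index]
    nc = ns[control_index]
    mc_mean = gs[control_index].mean()
    se = np.sqrt(s2 * (1.0 / ns[others] + 1.0 / nc))
    t_obs = np.array([(gs[i].mean() - mc_mean) for i in others]) / se
    p_raw = 2.0 * sps.t.sf(np.abs(t_obs), dfw)

    rng = np.random.default_rng(seed)
    sim_means = rng.standard_normal((n_mc, k)) / np.sqrt(ns)
    sim_s2 = rng.chisquare(dfw, size=n_mc) / dfw
    se_unit = np.sqrt(1.0 / ns[others] + 1.0 / nc)
    sim_t = (sim_means[:, others] - sim_means[:, [control_index]]) / (
        np.sqrt(sim_s2)[:, None] * se_unit
    )
    max_abs = np.abs(sim_t).max(axis=1)
    p_adj = np.array([(max_abs >= abs(t)).mean() for t in t_obs])
    p_adj = np.minimum(1.0, np.maximum(p_adj, p_raw))
    return DunnettResult(
        comparisons=others,
        t_stats=t_obs,
        p_raw=p_raw,
        p_adjusted=p_adj,
        reject=p_adj < alpha,
        alpha=alpha,
    )


def bonferroni_pairs(groups, pairs) -> np.ndarray:
    """Pooled-variance two-sided t-tests for selected pairs, Bonferroni adjusted.

    Adjustment is min(1, m * p) with m the number of selected pairs.
    """
    gs = _as_groups(groups)
    m = len(pairs)
    if m < 1:
        raise InvalidArgumentError("need at least one pair")
    out = np.empty(m)
    for idx, (a, b) in enumerate(pairs):
        if not (0 <= a < len(gs) and 0 <= b < len(gs) and a != b):
            raise InvalidArgumentError(f"invalid pair ({a}, {b})")
        p = sps.ttest_ind(gs[a], gs[b], equal_var=True).pvalue
        out[idx] = min(1.0, m * float(p))
    return out


@dataclass(frozen=True)
class ROCResult:
    operating_points: list[tuple[float, float]]  # (sensitivity, 1 - specificity)
    auc: float
    band: str


def roc_curve(positive_scores, negative_scores, direction: str = "greater_is_positive") -> ROCResult:
    """Empirical ROC over all distinct thresholds; AUC by trapezoidal rule.

    The trapezoidal AUC equals the Mann-Whitney statistic with ties
    credited one half.  ``direction`` states whether larger scores signal
    the positive class.
    """
    pos = np.asarray(positive_scores, dtype=float).ravel()
    neg = np.asarray(negative_scores, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise InvalidInputError("both classes need at least one score")
    if direction not in ("greater_is_positive", "lesser_is_positive"):
        raise InvalidArgumentError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == "greater_is_positive" else -1.0
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = sign * np.concatenate([pos, neg])
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    points = [(float(t), float(f)) for t, f in zip(tpr, fpr)]
    return ROCResult(operating_points=points, auc=auc, band=classify_auc(auc))


def classify_auc(auc: float) -> str:
    """Accuracy band of an AUC: left-closed, right-open intervals.

    < 0.6 no_value; [0.6, 0.7) poor; [0.7, 0.8) fair; [0.8, 0.9) good;
    >= 0.9 excellent.
    """
    if not (0.0 <= auc <= 1.0):
        raise InvalidInputError(f"AUC must lie in [0, 1], got {auc}")
    if auc < 0.6:
        return "no_value"
    if auc < 0.7:
        return "poor"
    if auc < 0.8:
        return "fair"
    if auc < 0.9:
        return "good"
    return "excellent"


#: ordering of bands for comparisons (higher = better discriminability)
BAND_ORDER = {"no_value": 0, "poor": 1, "fair": 2, "good": 3, "excellent": 4}
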
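"""Nonparametric statistics for slide-level cytology evaluation.

Implements the statistical protocol used throughout the pipeline: one-sided
Mann-Whitney tests under pre-specified alternatives, Cliff's delta effect
sizes, Benjamini-Hochberg q-values within analysis families, empirical ROC
curves with stratified-bootstrap percentile bands, Wilson score intervals for
human operating points, matched-operating-point bootstrap comparisons, and
LOWESS age trends with bootstrap confidence bands.

Conventions fixed here (and relied on elsewhere):

* The Mann-Whitney statistic ``U_ref`` counts *reference* wins, with ties
  contributing 1/2.  Cliff's delta is the pairwise dominance statistic
  ``delta = [#(comp > ref) - #(comp < ref)] / (n_ref * n_comp)``,
  equivalently ``1 - 2 U_ref / (n_ref n_comp)``; ``delta > 0`` means the
  comparator tends to be larger.
* ROC uses the ``score >= t`` positivity convention; tied positive/negative
  scores contribute 1/2 to the AUC, so ``AUC = P(s+ > s-) + P(s+ = s-)/2``
  and ``AUC = (delta + 1)/2`` for comparator = positives.
* Bootstrap bands are pointwise percentile intervals of curves linearly
  interpolated onto a uniform false-positive-rate grid; resampling is
  stratified by class and is a pure function of (data, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "GroupComparison",
    "RocResult",
    "OperatingPoint",
    "MatchedComparison",
    "mann_whitney_one_sided",
    "cliffs_delta",
    "bh_adjust",
    "empirical_roc",
    "bootstrap_roc_band",
    "compare_at_matched_operating_point",
    "wilson_interval",
    "lowess_trend",
]

#: Default uniform FPR grid: 1,001 nodes on [0, 1].
DEFAULT_FPR_GRID = np.linspace(0.0, 1.0, 1001)

#: Largest product n_ref * n_comp for which the exact Mann-Whitney null
#: distribution is enumerated (tie-free samples only).
EXACT_MW_LIMIT = 400


@dataclass
class GroupComparison:
    """One reference-vs-comparator test: U statistic, p, effect size."""

    n_ref: int
    n_comp: int
    u_ref: float  # reference wins, ties counted 1/2
    p: float  # one-sided, alternative comparator > reference
    delta: float  # Cliff's delta, > 0 when comparator larger
    q: float | None = None  # set after family-wise BH adjustment


@dataclass
class RocResult:
    """Empirical ROC curve, optionally with a stratified-bootstrap band."""

    fpr: np.ndarray  # raw curve nodes (not the uniform grid)
    tpr: np.ndarray
    auc: float
    grid: np.ndarray | None = None  # uniform FPR grid used for the band
    tpr_grid: np.ndarray | None = None  # point curve interpolated on grid
    band_lower: np.ndarray | None = None
    band_upper: np.ndarray | None = None
    auc_ci: tuple[float, float] | None = None
    boot_auc: np.ndarray | None = field(default=None, repr=False)
    n_resamples: int | None = None
    level: float = 0.95


@dataclass
class OperatingPoint:
    """A (sensitivity, specificity) point with Wilson 95% intervals."""

    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    definition: str = ""


@dataclass
class MatchedComparison:
    """Bootstrap comparison of an ROC curve against a fixed operating point."""

    matching: str  # "specificity" or "sensitivity"
    delta: float  # ΔTPR (matched specificity) or ΔFPR (matched sensitivity)
    p: float  # two-sided: 2 * smaller bootstrap tail, capped at 1
    ai_value: float
    human_value: float
    extrapolated: bool = False


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} sample is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} sample contains non-finite values")
    return arr


def _u_comp(ref: np.ndarray, comp: np.ndarray) -> float:
    """Comparator wins (ties 1/2) via midranks; exact for float-representable data."""
    pooled = np.concatenate([comp, ref])
    ranks = sps.rankdata(pooled)
    rank_sum = ranks[: comp.size].sum()
    return float(rank_sum - comp.size * (comp.size + 1) / 2.0)


def mann_whitney_one_sided(ref, comp) -> GroupComparison:
    """One-sided Mann-Whitney test of the alternative comparator > reference.

    ``u_ref`` counts reference wins with ties as 1/2.  The p-value is exact
    (full enumeration of the null permutation distribution) when
    ``n_ref * n_comp <= 400`` and the pooled sample is tie-free; otherwise a
    tie-corrected normal approximation with continuity correction is used.
    """
    ref = _as_sample(ref, "reference")
    comp = _as_sample(comp, "comparator")
    n_ref, n_comp = ref.size, comp.size
    u_comp = _u_comp(ref, comp)
    u_ref = n_ref * n_comp - u_comp
    tie_free = np.unique(np.concatenate([ref, comp])).size == n_ref + n_comp
    method = "exact" if (n_ref * n_comp <= EXACT_MW_LIMIT and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(comp, ref, alternative="greater", method=method)
    delta = 1.0 - 2.0 * u_ref / (n_ref * n_comp)
    return GroupComparison(
        n_ref=n_ref, n_comp=n_comp, u_ref=u_ref, p=float(res.pvalue), delta=delta
    )


def cliffs_delta(ref, comp) -> float:
    """Cliff's delta: P(comp > ref) - P(comp < ref) over all cross pairs.

    Positive values indicate the comparator tends to be larger.  Computed
    through midranks, which reproduces the pairwise count exactly.
    """
    ref = _as_sample(ref, "reference")
    comp = _as_sample(comp, "comparator")
    return float(2.0 * _u_comp(ref, comp) / (ref.size * comp.size) - 1.0)


def bh_adjust(pvalues, family=None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, applied within each family.

    ``family`` is an optional sequence of hashable labels, one per p-value;
    the adjustment is carried out independently inside each label group
    (one analysis family = one figure/table comparison set).
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.empty_like(p)
    if family is None:
        groups = {None: np.arange(p.size)}
    else:
        fam = np.asarray(family)
        if fam.size != p.size:
            raise ValueError("family must have one label per p-value")
        groups = {g: np.flatnonzero(fam == g) for g in np.unique(fam)}
    for idx in groups.values():
        q[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return q


def _binary_labels(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype.kind in "b":
        return lab.astype(bool)
    if lab.dtype.kind in "iuf":
        return lab.astype(float) > 0
    return np.isin(lab, ("positive", "pos", "1", "True", "true"))


def _roc_points(scores: np.ndarray, positive: np.ndarray):
    """Raw ROC nodes under the ``score >= t`` convention, plus tie-aware AUC."""
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], positive[order]
    # one node per distinct threshold value
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(~y)[distinct]
    n_pos, n_neg = int(positive.sum()), int((~positive).sum())
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    u_comp = _u_comp(scores[~positive], scores[positive])  # positives as comparator
    auc = u_comp / (n_pos * n_neg)
    return fpr, tpr, float(auc)


def empirical_roc(scores, labels) -> RocResult:
    """Empirical ROC curve and AUC for binary slide labels.

    Predicted positive when ``score >= t``; tied scores across classes
    contribute 1/2 per pair, so the AUC equals the Mann-Whitney pair
    statistic P(score+ > score-) + P(=)/2.
    """
    scores = _as_sample(scores, "scores")
    positive = _binary_labels(labels)
    if positive.size != scores.size:
        raise ValueError("scores and labels differ in length")
    if positive.all() or not positive.any():
        raise ValueError("AUC undefined: need at least one positive and one negative")
    fpr, tpr, auc = _roc_points(scores, positive)
    return RocResult(fpr=fpr, tpr=tpr, auc=auc)


def _interp_on_grid(fpr: np.ndarray, tpr: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.interp(grid, fpr, tpr)


def bootstrap_roc_band(
    scores,
    labels,
    n_resamples: int = 2000,
    grid: np.ndarray | None = None,
    seed=None,
    level: float = 0.95,
) -> RocResult:
    """ROC curve with stratified-bootstrap percentile confidence bands.

    Positives and negatives are resampled separately with replacement
    (stratification guarantees both classes in every resample); each
    resample's curve is linearly interpolated onto a uniform FPR grid and
    the band is the pointwise percentile interval.  The percentile interval
    of the resampled AUCs is reported as ``auc_ci``.
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    scores = _as_sample(scores, "scores")
    positive = _binary_labels(labels)
    if positive.all() or not positive.any():
        raise ValueError("AUC undefined: need at least one positive and one negative")
    grid = DEFAULT_FPR_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    pos_scores, neg_scores = scores[positive], scores[~positive]
    n_pos, n_neg = pos_scores.size, neg_scores.size

    fpr, tpr, auc = _roc_points(scores, positive)
    tpr_grid = _interp_on_grid(fpr, tpr, grid)

    boot_curves = np.empty((n_resamples, grid.size))
    boot_auc = np.empty(n_resamples)
    ones = np.ones(n_pos, dtype=bool)
    zeros = np.zeros(n_neg, dtype=bool)
    y = np.concatenate([ones, zeros])
    for b in range(n_resamples):
        sp = pos_scores[rng.integers(0, n_pos, n_pos)]
        sn = neg_scores[rng.integers(0, n_neg, n_neg)]
        f, t, a = _roc_points(np.concatenate([sp, sn]), y)
        boot_curves[b] = _interp_on_grid(f, t, grid)
        boot_auc[b] = a
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(boot_curves, [alpha, 1.0 - alpha], axis=0)
    auc_lo, auc_hi = np.quantile(boot_auc, [alpha, 1.0 - alpha])
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        grid=grid,
        tpr_grid=tpr_grid,
        band_lower=lower,
        band_upper=upper,
        auc_ci=(float(auc_lo), float(auc_hi)),
        boot_auc=boot_auc,
        n_resamples=n_resamples,
        level=level,
    )


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Closed-form Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    return float(lo), float(hi)


def human_operating_point(calls, labels, definition: str = "") -> OperatingPoint:
    """Sensitivity/specificity of a binary triage rule with Wilson intervals.

    ``calls`` are the rule's per-slide positive/negative decisions and
    ``labels`` the reference standard (e.g. HPV status).
    """
    pred = _binary_labels(calls)
    truth = _binary_labels(labels)
    if pred.size != truth.size:
        raise ValueError("calls and labels differ in length")
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    tp = int((pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    return OperatingPoint(
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
        sens_ci=wilson_interval(tp, n_pos),
        spec_ci=wilson_interval(tn, n_neg),
        definition=definition,
    )


def _tpr_at_specificity(fpr, tpr, spec: float) -> float:
    return float(np.interp(1.0 - spec, fpr, tpr))


def _fpr_at_sensitivity(fpr, tpr, sens: float) -> tuple[float, bool]:
    """Smallest FPR achieving TPR >= sens by inverse interpolation."""
    if sens > tpr[-1]:  # curve never reaches the requested sensitivity
        return 1.0, True
    idx = int(np.searchsorted(tpr, sens, side="left"))
    if tpr[idx] == sens or idx == 0:
        # step curves can have several nodes at this TPR; take the smallest FPR
        at = np.flatnonzero(tpr == tpr[idx])
        return float(fpr[at[0]] if tpr[idx] == sens else fpr[idx]), False
    f0, f1 = fpr[idx - 1], fpr[idx]
    t0, t1 = tpr[idx - 1], tpr[idx]
    if t1 == t0:
        return float(f0), False
    return float(f0 + (sens - t0) * (f1 - f0) / (t1 - t0)), False


def compare_at_matched_operating_point(
    scores,
    labels,
    human_calls,
    matching: str = "specificity",
    n_resamples: int = 2000,
    seed=None,
    fixed_human_point: bool = False,
) -> MatchedComparison:
    """Bootstrap comparison of an ROC score against a human triage rule.

    At matched specificity the statistic is ΔTPR = TPR_curve - TPR_human read
    from the interpolated curve at the human specificity; at matched
    sensitivity it is ΔFPR = FPR_curve - FPR_human by inverse interpolation.
    Each stratified resample of slides recomputes both the curve and the
    human point (unless ``fixed_human_point``); the two-sided p-value is
    twice the smaller tail probability of the bootstrap delta distribution
    around zero, capped at 1.
    """
    if matching not in ("specificity", "sensitivity"):
        raise ValueError("matching must be 'specificity' or 'sensitivity'")
    scores = _as_sample(scores, "scores")
    positive = _binary_labels(labels)
    calls = _binary_labels(human_calls)
    if not (scores.size == positive.size == calls.size):
        raise ValueError("scores, labels and human_calls must be aligned per slide")

    def point_delta(sc, pos, cl):
        fpr, tpr, _ = _roc_points(sc, pos)
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        sens_h = (cl & pos).sum() / n_pos
        spec_h = (~cl & ~pos).sum() / n_neg
        if matching == "specificity":
            ai = _tpr_at_specificity(fpr, tpr, spec_h)
            return ai - sens_h, ai, sens_h, False
        ai, extrap = _fpr_at_sensitivity(fpr, tpr, sens_h)
        return ai - (1.0 - spec_h), ai, 1.0 - spec_h, extrap

    delta0, ai0, human0, extrap = point_delta(scores, positive, calls)

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(positive)
    neg_idx = np.flatnonzero(~positive)
    deltas = np.empty(n_resamples)
    for b in range(n_resamples):
        take = np.concatenate(
            [
                pos_idx[rng.integers(0, pos_idx.size, pos_idx.size)],
                neg_idx[rng.integers(0, neg_idx.size, neg_idx.size)],
            ]
        )
        cl = calls if fixed_human_point else calls[take]
        if fixed_human_point:
            fpr, tpr, _ = _roc_points(scores[take], positive[take])
            n_pos = pos_idx.size
            n_neg = neg_idx.size
            sens_h = (calls & positive).sum() / n_pos
            spec_h = (~calls & ~positive).sum() / n_neg
            if matching == "specificity":
                deltas[b] = _tpr_at_specificity(fpr, tpr, spec_h) - sens_h
            else:
                deltas[b] = _fpr_at_sensitivity(fpr, tpr, sens_h)[0] - (1.0 - spec_h)
        else:
            deltas[b] = point_delta(scores[take], positive[take], cl)[0]
    below = float(np.mean(deltas < 0)) + 0.5 * float(np.mean(deltas == 0))
    above = 1.0 - below
    p = min(1.0, 2.0 * min(below, above))
    return MatchedComparison(
        matching=matching,
        delta=float(delta0),
        p=p,
        ai_value=float(ai0),
        human_value=float(human0),
        extrapolated=extrap,
    )


def lowess_trend(
    x,
    y,
    log_y: bool = False,
    frac: float = 0.5,
    n_boot: int = 100,
    seed=None,
    level: float = 0.95,
):
    """LOWESS trend of y against x with a percentile bootstrap band.

    With ``log_y`` the smoother runs on log-transformed values (all y must be
    positive; zero-count slides are excluded upstream) and the returned curve
    and band are back-transformed to the original scale.  Returns
    ``(x_sorted, fitted, lower, upper)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 10:
        raise ValueError("need at least 10 points for a LOWESS trend")
    if log_y:
        if np.any(y <= 0):
            raise ValueError("log_y requires strictly positive y")
        yt = np.log(y)
    else:
        yt = y
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    fit = sm_lowess(yt[order], xs, frac=frac, xvals=xs)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, xs.size))
    for b in range(n_boot):
        take = rng.integers(0, x.size, x.size)
        boots[b] = sm_lowess(yt[take], x[take], frac=frac, xvals=xs)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.nanquantile(boots, [alpha, 1.0 - alpha], axis=0)
    if log_y:
        fit, lower, upper = np.exp(fit), np.exp(lower), np.exp(upper)
    return xs, fit, lower, upper
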
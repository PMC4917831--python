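"""Diagnostic statistics for relating parallelism scores to perfusion status.

Implements the study-level statistical layer: two-group comparisons
(pooled-variance t test), 2x2 association (Pearson chi-squared, optional
Fisher exact), ROC analysis with DeLong confidence intervals, the Youden
"best balance" cutoff, sensitivities at fixed specificities, likelihood
ratios, a two-mean normal-approximation sample-size calculation, and the
decimal-to-logMAR visual-acuity conversion.

Convention for the parallelism marker: the ischemic macula is the positive
class, and *low* scores indicate positivity (ischemic eyes lose the
oriented nerve-fiber texture and score lower).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve

__all__ = [
    "EyeRecord",
    "ContingencyTable2x2",
    "RocAnalysis",
    "chi2_association",
    "fisher_exact_association",
    "unpaired_t_test",
    "roc_analysis",
    "likelihood_ratios",
    "sample_size_two_means",
    "decimal_va_to_logmar",
]

PATTERN_LABELS = ("flame", "non_flame")
PERFUSION_LABELS = ("nonischemic", "ischemic", "undeterminable")


@dataclass
class EyeRecord:
    """One eye's labels, covariates and parallelism score.

    Eyes with undeterminable perfusion (dense hemorrhage blocking the
    angiographic view) are carried in the record set but excluded from
    every analysis.
    """

    eye_id: str
    pattern_label: str
    perfusion_label: str
    p_mean: float = math.nan
    age_years: float = math.nan
    logmar_va: float = math.nan
    foveal_thickness_um: float = math.nan
    symptom_months: float = math.nan

    def __post_init__(self) -> None:
        if self.pattern_label not in PATTERN_LABELS:
            raise ValueError(f"unknown pattern label {self.pattern_label!r}")
        if self.perfusion_label not in PERFUSION_LABELS:
            raise ValueError(f"unknown perfusion label {self.perfusion_label!r}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table; rows index hemorrhage pattern, columns perfusion status."""

    a: int  # row 0, col 0
    b: int  # row 0, col 1
    c: int  # row 1, col 0
    d: int  # row 1, col 1

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class RocAnalysis:
    """Cohort-level ROC summary for one continuous marker."""

    auroc: float
    ci95: tuple[float, float]
    p_vs_half: float
    cutoff: float
    sensitivity_pct: float
    specificity_pct: float
    lr_pos: float | None  # None when specificity is 100% (undefined)
    lr_neg: float | None
    sens_at_spec90_pct: float
    sens_at_spec95_pct: float
    positive_means_low_score: bool
    n_positive: int = 0
    n_negative: int = 0
    curve_fpr: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    curve_tpr: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def chi2_association(tab: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-squared test on a 2x2 table, 1 df, no continuity correction."""
    arr = tab.as_array()
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate table: a zero marginal leaves nothing to test")
    stat, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    assert dof == 1
    return float(stat), float(p)


def fisher_exact_association(tab: ContingencyTable2x2) -> tuple[float, float]:
    """Fisher's exact test (two-sided) on the same 2x2 table."""
    odds, p = sps.fisher_exact(tab.as_array(), alternative="two-sided")
    return float(odds), float(p)


def unpaired_t_test(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float, tuple[float, float], tuple[float, float]]:
    """Two-sided Student t test with pooled variance.

    Returns (t, p, (mean_x, mean_y), (sd_x, sd_y)); sample SDs use n-1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return (
        float(t),
        float(p),
        (float(x.mean()), float(y.mean())),
        (float(x.std(ddof=1)), float(y.std(ddof=1))),
    )


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUROC and its DeLong variance via midrank placements."""
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    rk_all = sps.rankdata(allv)  # midranks
    rk_pos = sps.rankdata(pos)
    rk_neg = sps.rankdata(neg)
    # Placement of each positive among negatives, and vice versa.
    v10 = (rk_all[:m] - rk_pos) / n
    v01 = 1.0 - (rk_all[m:] - rk_neg) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def roc_analysis(
    scores: np.ndarray,
    labels: np.ndarray,
    positive_means_low_score: bool = True,
) -> RocAnalysis:
    """Empirical ROC analysis of a continuous marker.

    ``labels`` is a binary vector (1 / True = positive class).  When
    ``positive_means_low_score`` the decision rule is ``score <= cutoff``;
    otherwise ``score >= cutoff``.  AUROC is computed with the
    Mann-Whitney identity (midrank tie handling); the 95% CI and the p
    value against AUROC = 0.5 use DeLong's variance; the cutoff maximizes
    Youden's J (ties resolved toward higher specificity); sensitivities at
    90%/95% specificity are the best achievable empirical sensitivities at
    or above those specificity floors.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for an ROC analysis")

    s = -scores if positive_means_low_score else scores
    auc, var = _delong_variance(s[y], s[~y])
    se = math.sqrt(max(var, 0.0))
    if se > 0:
        z = (auc - 0.5) / se
        p_vs_half = 2.0 * sps.norm.sf(abs(z))
        ci = (max(0.0, auc - 1.959963984540054 * se), min(1.0, auc + 1.959963984540054 * se))
    else:  # degenerate (perfect separation): variance estimate collapses
        p_vs_half = 0.0 if auc != 0.5 else 1.0
        ci = (auc, auc)

    # Operating points: every observed score is a candidate threshold for
    # the rule "positive when s >= t" (on the oriented scale s).
    cand = np.unique(s)
    s_pos = np.sort(s[y])
    s_neg = np.sort(s[~y])
    sens_arr = 1.0 - np.searchsorted(s_pos, cand, side="left") / n_pos
    spec_arr = np.searchsorted(s_neg, cand, side="left") / n_neg
    j = sens_arr + spec_arr - 1.0
    # Max J; among ties prefer higher specificity.
    order = np.lexsort((-spec_arr, -j))
    best = int(order[0])
    cutoff_internal = float(cand[best])
    cutoff = -cutoff_internal if positive_means_low_score else cutoff_internal
    sens = float(sens_arr[best]) * 100.0
    spec = float(spec_arr[best]) * 100.0
    lr_pos, lr_neg = likelihood_ratios(sens, spec)

    def sens_at_spec(spec_floor_pct: float) -> float:
        ok = spec_arr * 100.0 >= spec_floor_pct
        return float(sens_arr[ok].max()) * 100.0 if ok.any() else 0.0

    fpr, tpr, _ = roc_curve(y.astype(int), s, drop_intermediate=False)

    return RocAnalysis(
        auroc=auc,
        ci95=ci,
        p_vs_half=float(p_vs_half),
        cutoff=float(cutoff),
        sensitivity_pct=sens,
        specificity_pct=spec,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        sens_at_spec90_pct=sens_at_spec(90.0),
        sens_at_spec95_pct=sens_at_spec(95.0),
        positive_means_low_score=positive_means_low_score,
        n_positive=n_pos,
        n_negative=n_neg,
        curve_fpr=fpr,
        curve_tpr=tpr,
    )


def likelihood_ratios(
    sensitivity_pct: float, specificity_pct: float
) -> tuple[float | None, float | None]:
    """Positive and negative likelihood ratios from percent sens/spec.

    +LR = sens / (1 - spec), undefined (None) at 100% specificity;
    -LR = (1 - sens) / spec, undefined (None) at 0% specificity.
    """
    if not (0 <= sensitivity_pct <= 100 and 0 <= specificity_pct <= 100):
        raise ValueError("sensitivity and specificity must be in [0, 100]")
    sens = sensitivity_pct / 100.0
    spec = specificity_pct / 100.0
    lr_pos = None if spec == 1.0 else sens / (1.0 - spec)
    lr_neg = None if spec == 0.0 else (1.0 - sens) / spec
    return lr_pos, lr_neg


def sample_size_two_means(
    m1: float,
    s1: float,
    m2: float,
    s2: float,
    alpha: float = 0.05,
    beta: float = 0.20,
    allocation_ratio: float = 1.0,
) -> tuple[int, int, int]:
    """Two-sided normal-approximation sample size for comparing two means.

    With allocation ratio k = n1/n2 and pooled variance
    sigma^2 = (s1^2 + s2^2) / 2:

        n2 = (1 + 1/k) (z_{1-alpha/2} + z_{1-beta})^2 sigma^2 / (m1 - m2)^2
        n1 = k * n2

    both rounded up.  Returns (n1, n2, total).
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    if not (0 < alpha < 1 and 0 < beta < 1):
        raise ValueError("alpha and beta must lie in (0, 1)")
    if allocation_ratio <= 0:
        raise ValueError("allocation ratio must be positive")
    delta = m1 - m2
    if delta == 0:
        raise ValueError("equal means: no sample size is large enough")
    zsum = sps.norm.ppf(1.0 - alpha / 2.0) + sps.norm.ppf(1.0 - beta)
    sigma2 = 0.5 * (s1 * s1 + s2 * s2)
    k = allocation_ratio
    n2_raw = (1.0 + 1.0 / k) * zsum * zsum * sigma2 / (delta * delta)
    n1 = math.ceil(k * n2_raw)
    n2 = math.ceil(n2_raw)
    return n1, n2, n1 + n2


def decimal_va_to_logmar(va: float) -> float:
    """Convert decimal visual acuity (Landolt chart) to logMAR = -log10(VA)."""
    if va <= 0:
        raise ValueError("decimal visual acuity must be positive")
    return -math.log10(va)
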
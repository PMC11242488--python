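"""Diagnostic test accuracy statistics for index-vs-reference FFR comparisons.

Implements the full evaluation battery used to validate an angiographic FFR
index against pressure-wire FFR: dichotomous classification at the 0.80
cut-off, sensitivity/specificity/accuracy/predictive values/likelihood
ratios with 95% CIs (Clopper-Pearson exact for proportions, log-method for
likelihood ratios), Pearson correlation, Bland-Altman limits of agreement,
the Mann-Whitney ROC AUC with DeLong variance, and DeLong's paired test for
comparing two correlated AUCs on the same cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DomainError

__all__ = [
    "ConfusionCounts",
    "PairedMeasurements",
    "MetricCI",
    "DiagnosticReport",
    "BlandAltmanResult",
    "RocResult",
    "DeLongResult",
    "classify",
    "diagnostic_metrics",
    "pearson_correlation",
    "bland_altman",
    "roc_auc",
    "delong_paired_test",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table with the reference (wire FFR) as truth."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if self.total == 0:
            raise DomainError("confusion table must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PairedMeasurements:
    """Per-case paired index (angiographic) and reference (wire) FFR values."""

    index_values: np.ndarray
    reference_values: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.index_values, dtype=float)
        y = np.asarray(self.reference_values, dtype=float)
        object.__setattr__(self, "index_values", x)
        object.__setattr__(self, "reference_values", y)
        if x.shape != y.shape or x.ndim != 1:
            raise DomainError("paired arrays must be 1-D and of equal length")
        if len(x) < 2:
            raise DomainError("need at least 2 paired cases")
        for arr, name in ((x, "index"), (y, "reference")):
            if np.any(arr <= 0) or np.any(arr > 1):
                raise DomainError(f"{name} FFR values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.index_values)


def classify(paired: PairedMeasurements, threshold: float = 0.80) -> ConfusionCounts:
    """Tabulate the confusion table at an inclusive cut-off.

    A value <= ``threshold`` is positive (hemodynamically critical) for
    both the index and the reference; the reference defines truth.
    """
    idx_pos = paired.index_values <= threshold
    ref_pos = paired.reference_values <= threshold
    return ConfusionCounts(
        tp=int(np.sum(idx_pos & ref_pos)),
        fp=int(np.sum(idx_pos & ~ref_pos)),
        tn=int(np.sum(~idx_pos & ~ref_pos)),
        fn=int(np.sum(~idx_pos & ref_pos)),
    )


@dataclass(frozen=True)
class MetricCI:
    """Point estimate with a two-sided confidence interval; NaN = undefined."""

    value: float
    low: float
    high: float

    @property
    def percent(self) -> float:
        return self.value * 100.0


def _clopper_pearson(k: int, n: int, conf: float) -> MetricCI:
    if n == 0:
        return MetricCI(float("nan"), float("nan"), float("nan"))
    alpha = 1.0 - conf
    low = sps.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    high = sps.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return MetricCI(k / n, float(low), float(high))


def _lr_ci(lr: float, a: int, m: int, b: int, n: int, conf: float) -> MetricCI:
    """Log-method CI for a likelihood ratio built from proportions a/m and b/n."""
    if not np.isfinite(lr) or lr <= 0 or a == 0 or b == 0:
        return MetricCI(lr, float("nan"), float("nan"))
    z = sps.norm.ppf(0.5 + conf / 2)
    se = np.sqrt(1.0 / a - 1.0 / m + 1.0 / b - 1.0 / n)
    return MetricCI(lr, float(lr * np.exp(-z * se)), float(lr * np.exp(z * se)))


@dataclass(frozen=True)
class DiagnosticReport:
    """All dichotomous diagnostic metrics (proportions in [0, 1])."""

    counts: ConfusionCounts
    threshold: float
    sensitivity: MetricCI
    specificity: MetricCI
    accuracy: MetricCI
    ppv: MetricCI
    npv: MetricCI
    prevalence: MetricCI
    lr_plus: MetricCI
    lr_minus: MetricCI

    def rows(self) -> list[tuple[str, MetricCI, bool]]:
        """(name, estimate, is_proportion) rows in the standard table order."""
        return [
            ("Disease prevalence", self.prevalence, True),
            ("Sensitivity", self.sensitivity, True),
            ("Specificity", self.specificity, True),
            ("Accuracy", self.accuracy, True),
            ("Positive predictive value", self.ppv, True),
            ("Negative predictive value", self.npv, True),
            ("Positive likelihood ratio", self.lr_plus, False),
            ("Negative likelihood ratio", self.lr_minus, False),
        ]

    def format(self) -> str:
        lines = [f"Diagnostic performance at cut-off <= {self.threshold:g}",
                 f"  TP={self.counts.tp} FP={self.counts.fp} "
                 f"TN={self.counts.tn} FN={self.counts.fn}"]
        for name, m, is_prop in self.rows():
            if is_prop:
                lines.append(
                    f"  {name}: {m.value * 100:.1f} "
                    f"({m.low * 100:.1f}-{m.high * 100:.1f})%"
                )
            else:
                lines.append(f"  {name}: {m.value:.2f} ({m.low:.2f}-{m.high:.2f})")
        return "\n".join(lines)


def diagnostic_metrics(
    c: ConfusionCounts, confidence: float = 0.95, threshold: float = 0.80
) -> DiagnosticReport:
    """Standard diagnostic-accuracy metrics with exact proportion CIs.

    Zero-denominator metrics are reported as NaN rather than raising.
    """
    nan = MetricCI(float("nan"), float("nan"), float("nan"))
    pos, neg = c.tp + c.fn, c.tn + c.fp
    sens = _clopper_pearson(c.tp, pos, confidence) if pos else nan
    spec = _clopper_pearson(c.tn, neg, confidence) if neg else nan
    acc = _clopper_pearson(c.tp + c.tn, c.total, confidence)
    ppv = _clopper_pearson(c.tp, c.tp + c.fp, confidence) if c.tp + c.fp else nan
    npv = _clopper_pearson(c.tn, c.tn + c.fn, confidence) if c.tn + c.fn else nan
    prev = _clopper_pearson(pos, c.total, confidence)
    if pos and neg and spec.value < 1:
        lr_p = _lr_ci(sens.value / (1 - spec.value), c.tp, pos, c.fp, neg, confidence)
    else:
        lr_p = nan
    if pos and neg and spec.value > 0:
        lr_m = _lr_ci((1 - sens.value) / spec.value, c.fn, pos, c.tn, neg, confidence)
    else:
        lr_m = nan
    return DiagnosticReport(
        counts=c, threshold=threshold,
        sensitivity=sens, specificity=spec, accuracy=acc,
        ppv=ppv, npv=npv, prevalence=prev, lr_plus=lr_p, lr_minus=lr_m,
    )


def pearson_correlation(paired: PairedMeasurements) -> tuple[float, float]:
    """Product-moment r between index and reference, with the two-sided
    t-distribution p-value (n-2 df)."""
    x, y = paired.index_values, paired.reference_values
    if len(x) < 3:
        raise DomainError("Pearson correlation needs at least 3 cases")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("correlation undefined for zero-variance data")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float


def bland_altman(paired: PairedMeasurements) -> BlandAltmanResult:
    """Agreement analysis of index - reference differences.

    Limits of agreement are ``bias +/- 1.96 * SD`` with the sample (n-1) SD.
    """
    diffs = paired.index_values - paired.reference_values
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltmanResult(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd)


# ---------------------------------------------------------------------------
# ROC AUC via midranks + DeLong structural components


def _oriented(scores: np.ndarray, positive_direction: str) -> np.ndarray:
    if positive_direction == "low":
        return -scores  # lower FFR indicates disease
    if positive_direction == "high":
        return scores.copy()
    raise DomainError("positive_direction must be 'low' or 'high'")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and structural components V10 (per positive), V01 (per negative)."""
    x = scores[labels]
    y = scores[~labels]
    m, n = len(x), len(y)
    all_r = sps.rankdata(np.concatenate([x, y]))
    x_r = sps.rankdata(x)
    y_r = sps.rankdata(y)
    auc = (np.sum(all_r[:m]) - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - x_r) / n
    v01 = 1.0 - (all_r[m:] - y_r) / m
    return float(auc), v10, v01


def _validate_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() == 0 or (~labels).sum() == 0:
        raise DomainError("ROC needs both diseased and non-diseased cases")
    return labels


@dataclass(frozen=True)
class RocResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    positive_direction: str = "low",
    confidence: float = 0.95,
) -> RocResult:
    """Mann-Whitney ROC AUC (ties count 1/2) with a DeLong-variance CI.

    ``positive_direction='low'`` means lower scores indicate disease (the
    FFR convention); set 'high' for severity scores like percent stenosis.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _validate_labels(np.asarray(labels))
    auc, v10, v01 = _delong_components(_oriented(scores, positive_direction), labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = float(np.sqrt(var))
    z = sps.norm.ppf(0.5 + confidence / 2)
    return RocResult(
        auc=auc,
        se=se,
        ci_low=float(max(0.0, auc - z * se)),
        ci_high=float(min(1.0, auc + z * se)),
    )


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    delta: float
    se: float
    z: float
    p: float


def delong_paired_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
    positive_direction_a: str = "low",
    positive_direction_b: str = "low",
) -> DeLongResult:
    """DeLong's nonparametric test for two correlated ROC AUCs.

    Both score sets must be measured on the same cases.  The covariance of
    the paired AUCs is estimated from the structural components; the
    two-sided p-value comes from the normal distribution.  With degenerate
    (zero) variance, identical AUCs yield p = 1.0, otherwise a warning is
    emitted and p is NaN with the AUC difference still reported.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise DomainError("paired score sets must have equal length")
    labels = _validate_labels(np.asarray(labels))
    auc_a, v10_a, v01_a = _delong_components(_oriented(a, positive_direction_a), labels)
    auc_b, v10_b, v01_b = _delong_components(_oriented(b, positive_direction_b), labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b])) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    delta = auc_a - auc_b
    if var <= 1e-15:
        if abs(delta) < 1e-12:
            return DeLongResult(auc_a, auc_b, delta, 0.0, 0.0, 1.0)
        warnings.warn("degenerate DeLong variance; p undefined", stacklevel=2)
        return DeLongResult(auc_a, auc_b, delta, 0.0, float("nan"), float("nan"))
    se = float(np.sqrt(var))
    z = delta / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, delta, se, float(z), p)
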
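"""Diagnostic-accuracy statistics for patient-level cancer detection.

Sensitivity, specificity and accuracy with 95% Wilson score intervals,
the Youden index J = sens + spec - 1 with an interval obtained by
combining the Wilson bounds of its two terms, and a trapezoidal ROC/AUC
over threshold operating points.

The Youden interval policy (summing Wilson bounds) is not a standard
interval; it is the package's reporting convention for threshold sweeps,
chosen because it combines the two per-proportion intervals without any
resampling.  A seeded bootstrap alternative is provided for users who
want a conventional interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "DiagnosticSummary",
    "wilson_ci",
    "summarize_diagnostics",
    "youden_with_ci",
    "youden_ci_bootstrap",
    "roc_auc",
    "round_percent",
]


def round_percent(x: float, ndigits: int = 2) -> float:
    """Round half-up, applied only at reporting time (never internally)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Patient-level confusion counts."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.positives + self.negatives


def wilson_ci(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Returns ``(lower, upper)`` as proportions in [0, 1].  The critical
    value is the exact two-sided normal quantile for the requested
    confidence level (1.959964 at 95%).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError(f"need 0 <= successes <= trials, got {successes}/{trials}")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    n = float(trials)
    p = successes / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2.0 * n)) / denom
    half = z * np.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n)) / denom
    lo, hi = center - half, center + half
    return max(lo, 0.0), min(hi, 1.0)


@dataclass
class _ProportionReport:
    value_pct: float
    ci_pct: tuple[float, float]
    successes: int
    trials: int


@dataclass
class DiagnosticSummary:
    """Per-threshold summary: proportions as percentages with Wilson CIs."""

    counts: ConfusionCounts
    sensitivity: _ProportionReport
    specificity: _ProportionReport
    accuracy: _ProportionReport
    youden_pct: float
    youden_ci_pct: tuple[float, float]

    def to_dict(self) -> dict:
        def rep(r: _ProportionReport) -> dict:
            return {
                "percent": r.value_pct,
                "ci95_percent": list(r.ci_pct),
                "successes": r.successes,
                "trials": r.trials,
            }

        return {
            "counts": {
                "tp": self.counts.tp,
                "fn": self.counts.fn,
                "tn": self.counts.tn,
                "fp": self.counts.fp,
            },
            "sensitivity": rep(self.sensitivity),
            "specificity": rep(self.specificity),
            "accuracy": rep(self.accuracy),
            "youden_percent": self.youden_pct,
            "youden_ci95_percent": list(self.youden_ci_pct),
        }


def _proportion_report(successes: int, trials: int, confidence: float) -> _ProportionReport:
    lo, hi = wilson_ci(successes, trials, confidence)
    return _ProportionReport(
        value_pct=round_percent(100.0 * successes / trials),
        ci_pct=(round_percent(100.0 * lo), round_percent(100.0 * hi)),
        successes=successes,
        trials=trials,
    )


def summarize_diagnostics(
    counts: ConfusionCounts, confidence: float = 0.95
) -> DiagnosticSummary:
    """Sensitivity, specificity, accuracy and Youden J with 95% CIs.

    Proportions are reported as percentages rounded half-up to two
    decimals; all interval arithmetic uses unrounded values.
    """
    if counts.positives < 1 or counts.negatives < 1:
        raise ValueError("need at least one positive and one negative patient")
    sens = _proportion_report(counts.tp, counts.positives, confidence)
    spec = _proportion_report(counts.tn, counts.negatives, confidence)
    acc = _proportion_report(counts.tp + counts.tn, counts.total, confidence)
    j, j_ci = youden_with_ci(counts, confidence)
    return DiagnosticSummary(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        youden_pct=j,
        youden_ci_pct=j_ci,
    )


def youden_with_ci(
    counts: ConfusionCounts, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Youden J (percent) with the combined-Wilson-bound interval.

    J = sens + spec - 1 on unrounded proportions; the interval sums the
    unrounded Wilson bounds of sensitivity and specificity and subtracts
    100, rounding only the final numbers.
    """
    if counts.positives < 1 or counts.negatives < 1:
        raise ValueError("need at least one positive and one negative patient")
    sens = counts.tp / counts.positives
    spec = counts.tn / counts.negatives
    s_lo, s_hi = wilson_ci(counts.tp, counts.positives, confidence)
    p_lo, p_hi = wilson_ci(counts.tn, counts.negatives, confidence)
    j = round_percent(100.0 * (sens + spec - 1.0))
    lo = round_percent(100.0 * (s_lo + p_lo - 1.0))
    hi = round_percent(100.0 * (s_hi + p_hi - 1.0))
    return j, (lo, hi)


def youden_ci_bootstrap(
    counts: ConfusionCounts,
    confidence: float = 0.95,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap Youden interval (conventional alternative)."""
    rng = np.random.default_rng(seed)
    tp = rng.binomial(counts.positives, counts.tp / counts.positives, size=n_boot)
    tn = rng.binomial(counts.negatives, counts.tn / counts.negatives, size=n_boot)
    j = tp / counts.positives + tn / counts.negatives - 1.0
    alpha = 1.0 - confidence
    lo, hi = np.quantile(j, [alpha / 2.0, 1.0 - alpha / 2.0])
    return round_percent(100.0 * lo), round_percent(100.0 * hi)


def roc_auc(
    operating_points: list[tuple[float, float]] | np.ndarray,
) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC from (sensitivity, specificity) pairs.

    Points are mapped to (FPR, TPR) = (1 - spec, sens), the trivial
    endpoints (0, 0) and (1, 1) are appended, points are sorted by FPR
    (then TPR) and integrated with the trapezoid rule.
    """
    pts = np.asarray(operating_points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 1:
        raise ValueError("need at least one operating point")
    if np.any(pts < 0) or np.any(pts > 1):
        raise ValueError("operating points must lie in [0, 1]")
    fpr = 1.0 - pts[:, 1]
    tpr = pts[:, 0]
    roc = np.vstack([[0.0, 0.0], np.column_stack([fpr, tpr]), [1.0, 1.0]])
    order = np.lexsort((roc[:, 1], roc[:, 0]))
    roc = roc[order]
    auc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    return roc, auc
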
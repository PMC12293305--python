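"""Method-agreement statistics for paired displacement measurements.

The two measurement procedures are compared on the cases where both ran:
Shapiro-Wilk on the paired differences, a two-sided paired t-test, and a
Cohen's d effect size standardised by the SD of the paired differences
(matching the paired design; a pooled-SD variant is exposed as an option).
Effect-size bands follow the usual anchors 0.20 / 0.50 / 0.80, read as
half-open intervals [0.2, 0.5) small, [0.5, 0.8) moderate, >= 0.8 large;
|d| < 0.2 is likewise reported as small. Two sites (cusp tip, root apex)
are tested without multiplicity correction; the report notes this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import ValidationError
from .overlay_pipeline import DisplacementResult

__all__ = [
    "ComparisonReport",
    "PairedMeasurements",
    "cohens_d_paired",
    "compare_methods",
    "effect_label",
    "paired_t",
    "shapiro_wilk",
]

ALPHA = 0.05
NO_CORRECTION_NOTE = (
    "two paired tests (tip, apex) performed without multiple-testing correction"
)


@dataclass
class PairedMeasurements:
    """Per-case values from two methods, paired by case id (overlap only)."""

    case_ids: list[str]
    method_a_values: np.ndarray
    method_b_values: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.method_a_values, dtype=np.float64).ravel()
        b = np.asarray(self.method_b_values, dtype=np.float64).ravel()
        ids = [str(c) for c in self.case_ids]
        if not (len(ids) == len(a) == len(b)):
            raise ValidationError("case_ids and value lists must have equal length")
        if len(ids) < 2:
            raise ValidationError("paired comparison needs at least 2 cases")
        if len(set(ids)) != len(ids):
            raise ValidationError("case ids must be unique")
        self.case_ids = ids
        self.method_a_values = a
        self.method_b_values = b

    @property
    def n(self) -> int:
        return len(self.case_ids)

    @property
    def differences(self) -> np.ndarray:
        return self.method_a_values - self.method_b_values


@dataclass
class ComparisonReport:
    """Paired-comparison summary mirroring an N / mean +- SD / p / d layout."""

    site: str
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    shapiro_statistic: Optional[float]
    shapiro_p: Optional[float]
    t_statistic: Optional[float]
    p_value: Optional[float]
    cohens_d: Optional[float]
    effect_label: Optional[str]
    exact_agreement: bool = False
    alpha: float = ALPHA
    notes: list[str] = field(default_factory=lambda: [NO_CORRECTION_NOTE])

    @property
    def significant(self) -> Optional[bool]:
        return None if self.p_value is None else bool(self.p_value < self.alpha)


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (statistic, p)."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if len(x) < 3:
        raise ValidationError(f"Shapiro-Wilk needs n >= 3, got {len(x)}")
    if len(x) > 5000:
        raise ValidationError("Shapiro-Wilk supported up to n = 5000")
    if np.ptp(x) == 0:
        raise ValidationError("Shapiro-Wilk undefined for a zero-variance sample")
    stat, p = sps.shapiro(x)
    return float(stat), float(p)


def paired_t(paired: PairedMeasurements) -> tuple[float, float]:
    """Two-sided paired t-test on the differences.

    t = mean(d) / (sd(d)/sqrt(n)) with df = n - 1; sd uses the n-1
    denominator.
    """
    d = paired.differences
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ValidationError(
            "paired t undefined: differences have zero variance "
            "(methods agree exactly)"
        )
    n = paired.n
    t = float(np.mean(d)) / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 1))
    return t, p


def effect_label(d: float) -> str:
    """Band |d| into small / moderate / large."""
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "moderate"
    return "small"


def cohens_d_paired(
    paired: PairedMeasurements, standardizer: str = "differences"
) -> tuple[float, str]:
    """Cohen's d for a paired design.

    ``standardizer="differences"`` (default): d = mean(diff) / sd(diff).
    ``standardizer="pooled"``: mean(diff) divided by the pooled SD of the two
    samples — exposed because the convention is not universal.
    """
    d = paired.differences
    if standardizer == "differences":
        sd = float(np.std(d, ddof=1))
    elif standardizer == "pooled":
        sa = float(np.std(paired.method_a_values, ddof=1))
        sb = float(np.std(paired.method_b_values, ddof=1))
        sd = math.sqrt((sa**2 + sb**2) / 2.0)
    else:
        raise ValidationError(f"unknown standardizer {standardizer!r}")
    if sd == 0:
        raise ValidationError("Cohen's d undefined: zero-variance standardizer")
    value = float(np.mean(d)) / sd
    return value, effect_label(value)


def build_paired(
    results: Sequence[DisplacementResult], site: str
) -> PairedMeasurements:
    """Pair CBCT (method A) and intraoral-scan (method B) values by case id."""
    if site not in ("tip", "apex"):
        raise ValidationError(f"site must be tip/apex, got {site!r}")
    attr = f"{site}_displacement"
    by_case: dict[str, dict[str, float]] = {}
    for r in results:
        by_case.setdefault(r.case_id, {})[r.method] = getattr(r, attr)
    overlap = [cid for cid, m in by_case.items() if {"cbct", "stl"} <= m.keys()]
    if len(overlap) < 2:
        raise ValidationError(
            f"only {len(overlap)} case(s) measured by both methods; need >= 2"
        )
    return PairedMeasurements(
        overlap,
        [by_case[c]["cbct"] for c in overlap],
        [by_case[c]["stl"] for c in overlap],
    )


def compare_methods(
    results: Sequence[DisplacementResult],
    site: str,
    standardizer: str = "differences",
) -> ComparisonReport:
    """Full paired comparison of the two methods at one site.

    Only cases measured by both methods enter. When the methods agree
    exactly on every case, t / p / d are undefined; the report flags exact
    agreement instead of failing.
    """
    paired = build_paired(results, site)
    a, b = paired.method_a_values, paired.method_b_values
    descr = dict(
        site=site,
        n=paired.n,
        mean_a=float(np.mean(a)),
        sd_a=float(np.std(a, ddof=1)),
        mean_b=float(np.mean(b)),
        sd_b=float(np.std(b, ddof=1)),
    )
    diffs = paired.differences
    if float(np.std(diffs, ddof=1)) == 0:
        return ComparisonReport(
            **descr,
            shapiro_statistic=None,
            shapiro_p=None,
            t_statistic=None,
            p_value=None,
            cohens_d=None,
            effect_label=None,
            exact_agreement=True,
        )
    if paired.n >= 3:
        sw_stat, sw_p = shapiro_wilk(diffs)
    else:
        sw_stat = sw_p = None
    t, p = paired_t(paired)
    d, label = cohens_d_paired(paired, standardizer=standardizer)
    return ComparisonReport(
        **descr,
        shapiro_statistic=sw_stat,
        shapiro_p=sw_p,
        t_statistic=t,
        p_value=p,
        cohens_d=d,
        effect_label=label,
    )
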
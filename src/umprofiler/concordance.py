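"""Performance-evaluation statistics: coverage QC, robust outliers,
regression, Bland-Altman agreement and 2x2 concordance metrics."""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CoverageRecord",
    "ConcordanceTable",
    "AgreementResult",
    "KappaBand",
    "BlandAltmanResult",
    "coverage_stats",
    "rout_outliers",
    "linear_fit",
    "bland_altman",
    "agreement",
    "validation_concordance",
    "percent_concordance",
]


@dataclass(frozen=True)
class CoverageRecord:
    patient_id: str
    mean_depth: float
    total_reads: int
    on_target_pct: float
    uniformity_pct: float

    @property
    def reads_per_depth(self) -> float:
        return self.total_reads / self.mean_depth if self.mean_depth else math.nan


def coverage_stats(
    per_amplicon_reads: Mapping[str, Sequence[int]],
    target_lengths: Sequence[int],
    on_target_pct: Optional[Mapping[str, float]] = None,
) -> list[CoverageRecord]:
    """Per-patient coverage summaries from per-amplicon read counts.

    Each amplicon's read count is its depth over its target; mean depth is
    the length-weighted average, and uniformity is the percent of target
    bases covered at >= 0.2x the mean depth (amplicon-panel convention).
    On-target percentages, if known upstream, are passed through.
    """
    lengths = np.asarray(target_lengths, dtype=float)
    if lengths.size == 0 or np.any(lengths <= 0):
        raise ValueError("target lengths must be positive and non-empty")
    total_len = lengths.sum()
    records = []
    for patient_id, reads in per_amplicon_reads.items():
        depth = np.asarray(reads, dtype=float)
        if depth.shape != lengths.shape:
            raise ValueError(
                f"{patient_id}: {depth.size} amplicon counts vs "
                f"{lengths.size} target lengths"
            )
        if np.any(depth < 0):
            raise ValueError(f"{patient_id}: negative read count")
        mean_depth = float((depth * lengths).sum() / total_len)
        covered = lengths[depth >= 0.2 * mean_depth].sum() if mean_depth > 0 else total_len
        records.append(
            CoverageRecord(
                patient_id=patient_id,
                mean_depth=mean_depth,
                total_reads=int(depth.sum()),
                on_target_pct=float((on_target_pct or {}).get(patient_id, 100.0)),
                uniformity_pct=float(100.0 * covered / total_len),
            )
        )
    return records


def rout_outliers(values: Sequence[float], q_pct: float = 1.0) -> set[int]:
    """FDR-controlled robust outlier detection for a location sample.

    Residuals are taken from the median, scaled by the normal-consistent
    MAD (a robust standard deviation), converted to two-sided t-tail
    probabilities on n-1 degrees of freedom, and tested from the most
    extreme point inward at false-discovery rate ``q_pct`` percent.
    A sample with zero robust spread yields no outliers.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 values for robust outlier detection")
    if not 0 < q_pct < 100:
        raise ValueError("Q must be in (0, 100) percent")
    resid = x - np.median(x)
    rsdr = stats.median_abs_deviation(x, scale="normal")
    if rsdr == 0:
        return set()
    t = np.abs(resid) / rsdr
    pvals = 2.0 * stats.t.sf(t, df=n - 1)
    order = np.argsort(pvals)  # most extreme first
    q = q_pct / 100.0
    thresholds = q * (np.arange(1, n + 1)) / n
    below = pvals[order] <= thresholds
    if not below.any():
        return set()
    k = int(np.max(np.nonzero(below)[0])) + 1
    return set(int(i) for i in order[:k])


def linear_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float, float]:
    """Ordinary least squares fit; returns (slope, intercept, r, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


def bland_altman(pairs: Sequence[tuple[float, float]]) -> BlandAltmanResult:
    """Limits of agreement for paired measurements (differences A - B).

    Limits are mean difference +/- 1.96 times the sample (n-1) standard
    deviation of the differences.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    diffs = np.array([a - b for a, b in pairs], dtype=float)
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        sd_diff=sd,
        n=len(pairs),
    )


class KappaBand(str, enum.Enum):
    WEAK = "WEAK"
    MODERATE = "MODERATE"
    STRONG = "STRONG"


def _kappa_band(kappa: float) -> KappaBand:
    if kappa < 0.4:
        return KappaBand.WEAK
    if kappa <= 0.8:
        return KappaBand.MODERATE
    return KappaBand.STRONG


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 agreement counts between method A and method B.

    ``pos_pos`` = positive in both, ``pos_neg`` = A positive / B negative,
    ``neg_pos`` = A negative / B positive, ``neg_neg`` = negative in both.
    """

    pos_pos: int
    pos_neg: int
    neg_pos: int
    neg_neg: int

    def __post_init__(self) -> None:
        if min(self.pos_pos, self.pos_neg, self.neg_pos, self.neg_neg) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.pos_pos + self.pos_neg + self.neg_pos + self.neg_neg

    def transposed(self) -> "ConcordanceTable":
        return ConcordanceTable(self.pos_pos, self.neg_pos, self.pos_neg, self.neg_neg)


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    kappa_band: KappaBand
    sensitivity: Optional[float]  # percent, method B as reference
    specificity: Optional[float]  # percent, method B as reference
    sensitivity_a_ref: Optional[float]  # percent, method A as reference
    specificity_a_ref: Optional[float]


def agreement(table: ConcordanceTable) -> AgreementResult:
    """Cohen's kappa plus sensitivity/specificity in both directions.

    Kappa is chance-corrected observed agreement; when expected agreement
    is 1 (a degenerate margin on both methods) kappa is 1 by convention.
    Sensitivity and specificity treat method B as the reference; the
    ``*_a_ref`` fields flip the reference.  A metric whose reference class
    is empty is None (undefined), never zero.
    """
    n = table.total
    if n == 0:
        raise ValueError("empty concordance table")
    a, b, c, d = table.pos_pos, table.pos_neg, table.neg_pos, table.neg_neg
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)

    def ratio(num: int, den: int) -> Optional[float]:
        return 100.0 * num / den if den > 0 else None

    return AgreementResult(
        kappa=kappa,
        kappa_band=_kappa_band(kappa),
        sensitivity=ratio(a, a + c),
        specificity=ratio(d, d + b),
        sensitivity_a_ref=ratio(a, a + b),
        specificity_a_ref=ratio(d, d + c),
    )


def percent_concordance(
    concordant: int, total: int, decimals: int = 0, truncate: bool = False
) -> float:
    """Percent agreement at printed precision.

    ``truncate`` drops digits past the requested precision instead of
    rounding (e.g. 103/104 -> 99.0384... -> 99.03 at two decimals).
    """
    if total <= 0:
        raise ValueError("total comparisons must be positive")
    pct = 100.0 * concordant / total
    factor = 10 ** decimals
    if truncate:
        return math.floor(pct * factor) / factor
    return round(pct * factor) / factor


def validation_concordance(
    calls_a: Iterable[str],
    calls_b: Iterable[str],
    universe: int,
    decimals: int = 0,
    truncate: bool = False,
) -> float:
    """Percent of compared loci on which two call sets agree.

    A locus is concordant when it is in both call sets or in neither;
    ``universe`` is the number of loci compared.
    """
    set_a, set_b = set(calls_a), set(calls_b)
    if universe <= 0:
        raise ValueError("universe must be positive")
    discordant = len(set_a ^ set_b)
    if discordant > universe:
        raise ValueError("more discordant loci than compared loci")
    return percent_concordance(universe - discordant, universe, decimals, truncate)
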
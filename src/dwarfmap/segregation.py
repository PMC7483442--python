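"""Goodness-of-fit tests for phenotype segregation ratios.

For a single recessive gene in an F2, the dominant:recessive phenotype
classes are expected at 3:1; consistency is assessed with a Pearson χ²
(df = 1), optionally with the Yates continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as sps


@dataclass(frozen=True)
class SegregationCounts:
    n_dominant_class: int
    n_recessive_class: int
    ratio: tuple[float, float] = (3.0, 1.0)

    def __post_init__(self):
        if self.n_dominant_class < 0 or self.n_recessive_class < 0:
            raise ValueError("counts must be >= 0")
        if self.n_dominant_class + self.n_recessive_class == 0:
            raise ValueError("total count must be > 0")
        if min(self.ratio) <= 0:
            raise ValueError("expected ratio terms must be > 0")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square_ratio(counts: SegregationCounts, yates: bool = False) -> ChiSquareResult:
    """Pearson χ² of observed two-class counts against an expected ratio.

    With ``yates`` the absolute deviations are reduced by 0.5 (floored at 0)
    before squaring.  Returns (statistic, df=1, two-sided p).
    """
    total = counts.n_dominant_class + counts.n_recessive_class
    r = sum(counts.ratio)
    expected = [total * counts.ratio[0] / r, total * counts.ratio[1] / r]
    observed = [counts.n_dominant_class, counts.n_recessive_class]
    if yates:
        stat = sum(max(abs(o - e) - 0.5, 0.0) ** 2 / e for o, e in zip(observed, expected))
        p = float(sps.chi2.sf(stat, df=1))
    else:
        stat, p = sps.chisquare(observed, expected)
        stat, p = float(stat), float(p)
    return ChiSquareResult(statistic=stat, df=1, p_value=p)
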
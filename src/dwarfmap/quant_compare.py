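"""Two-group fold-change / significance screening for analyte tables.

Implements the screening rules used for hormone panels measured in
replicate (reported as mean ± SD, n) and for FPKM expression triplicates:
an analyte differs significantly when |log2(fold change)| >= 1 and the
two-sided t-test p-value is < 0.05.  Hormone tests default to the Welch
(unequal-variance) t computed from summary statistics; FPKM rows get an
explicitly labelled fold-change-only screen (no dispersion modelling or
FDR is attempted here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

QUANTIFIED = "quantified"
NOT_QUANTIFIED = {"n.d.", "n.q."}

#: pathway membership of gibberellin species (two parallel branches of the
#: GA biosynthetic/metabolic network in cucurbits)
GA53_PATHWAY = frozenset({"GA_53", "GA_44", "GA_19", "GA_20", "GA_1",
                          "GA_8", "GA_29", "GA_5", "GA_3", "GA_6"})
GA12_PATHWAY = frozenset({"GA_12", "GA_15", "GA_24", "GA_9", "GA_4",
                          "GA_34", "GA_51", "GA_7"})


@dataclass
class GroupMeasurement:
    """An analyte measured in two groups, as replicates or (mean, sd, n)."""

    analyte: str
    mean_a: float | None = None
    sd_a: float | None = None
    n_a: int | None = None
    mean_b: float | None = None
    sd_b: float | None = None
    n_b: int | None = None
    status_a: str = QUANTIFIED
    status_b: str = QUANTIFIED

    @classmethod
    def from_summary(cls, analyte, mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                     status_a=QUANTIFIED, status_b=QUANTIFIED) -> "GroupMeasurement":
        m = cls(analyte=analyte, mean_a=mean_a, sd_a=sd_a, n_a=n_a,
                mean_b=mean_b, sd_b=sd_b, n_b=n_b,
                status_a=status_a, status_b=status_b)
        m._validate()
        return m

    @classmethod
    def from_replicates(cls, analyte, values_a, values_b,
                        status_a=QUANTIFIED, status_b=QUANTIFIED) -> "GroupMeasurement":
        a = np.asarray(values_a, dtype=float)
        b = np.asarray(values_b, dtype=float)
        m = cls(analyte=analyte,
                mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=a.size,
                mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=b.size,
                status_a=status_a, status_b=status_b)
        m._validate()
        return m

    def _validate(self):
        for st in (self.status_a, self.status_b):
            if st != QUANTIFIED and st not in NOT_QUANTIFIED:
                raise ValueError(f"unknown status {st!r}")
        if self.quantified:
            if self.n_a < 2 or self.n_b < 2:
                raise ValueError("n >= 2 required in each group for a t-test")
            if self.sd_a < 0 or self.sd_b < 0 or self.mean_a < 0 or self.mean_b < 0:
                raise ValueError("means and SDs must be >= 0")

    @property
    def quantified(self) -> bool:
        return self.status_a == QUANTIFIED and self.status_b == QUANTIFIED


@dataclass(frozen=True)
class ComparisonResult:
    analyte: str
    log2fc: float
    t_stat: float
    df: float
    p_value: float
    call: str  # up_sig | up | down | down_sig | no_call


def log2_fold_change(mean_a: float, mean_b: float, pseudocount: float = 0.0) -> float:
    """log2((mean_b + pseudocount) / (mean_a + pseudocount)), b relative to a."""
    a = mean_a + pseudocount
    b = mean_b + pseudocount
    if a <= 0 or b <= 0:
        raise ValueError("fold change undefined for non-positive means; use a pseudocount")
    return math.log2(b / a)


def welch_t_from_summary(mean_a: float, sd_a: float, n_a: int,
                         mean_b: float, sd_b: float, n_b: int,
                         welch: bool = True) -> tuple[float, float, float]:
    """Two-sided t-test of group b vs a from summary statistics.

    Welch with Satterthwaite df by default; ``welch=False`` pools the
    variances.  Degenerate zero-variance inputs follow the conventions
    t = 0, p = 1 for equal means and |t| = inf, p = 0 otherwise.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("n >= 2 required in each group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("SDs must be >= 0")
    if sd_a == 0 and sd_b == 0:
        df = float(n_a + n_b - 2)
        if mean_a == mean_b:
            return 0.0, df, 1.0
        return math.copysign(math.inf, mean_b - mean_a), df, 0.0
    t, p = sps.ttest_ind_from_stats(mean_b, sd_b, n_b, mean_a, sd_a, n_a,
                                    equal_var=not welch)
    if welch:
        va, vb = sd_a ** 2 / n_a, sd_b ** 2 / n_b
        df = (va + vb) ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
    else:
        df = float(n_a + n_b - 2)
    return float(t), float(df), float(p)


def call_significance(m: GroupMeasurement, fold_thresh: float = 1.0,
                      p_thresh: float = 0.05, pseudocount: float = 0.0,
                      welch: bool = True) -> ComparisonResult:
    """Directional significance call for one analyte.

    ``no_call`` when either group is not detected/quantified; otherwise the
    direction follows the sign of the b-over-a log2 fold change and the
    ``_sig`` suffix requires both |log2FC| >= ``fold_thresh`` and
    p < ``p_thresh``.
    """
    if not m.quantified:
        return ComparisonResult(m.analyte, math.nan, math.nan, math.nan, math.nan, "no_call")
    lfc = log2_fold_change(m.mean_a, m.mean_b, pseudocount=pseudocount)
    t, df, p = welch_t_from_summary(m.mean_a, m.sd_a, m.n_a, m.mean_b, m.sd_b, m.n_b,
                                    welch=welch)
    direction = "up" if lfc >= 0 else "down"
    sig = abs(lfc) >= fold_thresh and p < p_thresh
    return ComparisonResult(m.analyte, lfc, t, df, p,
                            f"{direction}_sig" if sig else direction)


def compare_table(measurements: list[GroupMeasurement], fold_thresh: float = 1.0,
                  p_thresh: float = 0.05, welch: bool = True) -> pd.DataFrame:
    """call_significance over a panel, returned as a tidy frame."""
    rows = [call_significance(m, fold_thresh=fold_thresh, p_thresh=p_thresh, welch=welch)
            for m in measurements]
    return pd.DataFrame([r.__dict__ for r in rows])


def fpkm_screen(rows: pd.DataFrame, group_a_cols: list[str], group_b_cols: list[str],
                fold_thresh: float = 1.0, pseudocount: float = 0.001) -> pd.DataFrame:
    """Fold-change screen of replicate FPKM rows (group b relative to a).

    Means are taken over the replicate columns, the pseudocount guards
    all-zero rows, and ``fold_flag`` marks |log2FC| >= ``fold_thresh``.
    This is screening only — no dispersion estimate or FDR is computed, so
    the output carries an explicit ``note`` column saying so.
    """
    mean_a = rows[group_a_cols].mean(axis=1)
    mean_b = rows[group_b_cols].mean(axis=1)
    lfc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    out = rows.copy()
    out["log2fc"] = lfc
    out["direction"] = np.where(lfc >= 0, "up", "down")
    out["fold_flag"] = np.abs(lfc) >= fold_thresh
    out["note"] = "screening only - FDR not computed"
    return out


def classify_ga_pathway(analyte: str) -> str:
    """Assign a gibberellin to the GA53- or GA12-branch of the pathway."""
    if analyte in GA53_PATHWAY:
        return "GA53_pathway"
    if analyte in GA12_PATHWAY:
        return "GA12_pathway"
    return "unassigned"
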
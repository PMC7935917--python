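"""Genetics and phenotype tabulation for corolla-folding mutants.

Two small statistics back the genetic interpretation of the folded-corolla
trait: a Pearson chi-square goodness-of-fit test of an F2 segregation count
against a Mendelian expected ratio (3:1 for a monohybrid recessive trait),
and per-line proportion tables over the four folding severity classes
observed in cup-flower lines (normal, traced, half, cup).

The chi-square test uses the plain Pearson statistic with df=1 and no Yates
continuity correction; for the observed 33:8 segregation this gives
p = 0.4171, consistent with a recessive single-locus trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

__all__ = [
    "SegregationCounts",
    "FoldingClassCounts",
    "FOLDING_CLASSES",
    "segregation_chi_square",
    "phenotype_ratio_table",
]

FOLDING_CLASSES = ("normal", "traced", "half", "cup")


@dataclass(frozen=True)
class SegregationCounts:
    """Observed F2 counts and the Mendelian ratio tested against."""

    n_dominant: int
    n_recessive: int
    expected_ratio: tuple = (3.0, 1.0)

    def __post_init__(self):
        if self.n_dominant < 0 or self.n_recessive < 0:
            raise ParameterError("counts must be >= 0")
        if self.n_dominant + self.n_recessive == 0:
            raise ParameterError("total count must be > 0")
        r1, r2 = self.expected_ratio
        if not (r1 > 0 and r2 > 0):
            raise ParameterError("expected ratio components must be > 0")


@dataclass(frozen=True)
class FoldingClassCounts:
    """Per-line flower counts over the four folding classes."""

    line: str
    normal: int
    traced: int
    half: int
    cup: int

    def __post_init__(self):
        counts = (self.normal, self.traced, self.half, self.cup)
        if any(c < 0 for c in counts):
            raise ParameterError(f"line {self.line}: counts must be >= 0")

    @property
    def total(self) -> int:
        return self.normal + self.traced + self.half + self.cup


def segregation_chi_square(counts: SegregationCounts):
    """Pearson chi-square test of an observed segregation vs an expected ratio.

    Returns (chi2, df, p_value, observed_ratio).  Expected counts are
    total*(r1, r2)/(r1+r2); the p-value is the upper tail of chi-square with
    df=1; no continuity correction.  observed_ratio is
    n_dominant/n_recessive, or nan when n_recessive is 0.
    """
    obs = np.array([counts.n_dominant, counts.n_recessive], dtype=float)
    r = np.array(counts.expected_ratio, dtype=float)
    exp = obs.sum() * r / r.sum()
    chi2, p = stats.chisquare(obs, exp)
    ratio = (counts.n_dominant / counts.n_recessive
             if counts.n_recessive > 0 else float("nan"))
    return float(chi2), 1, float(p), ratio


def phenotype_ratio_table(lines) -> pd.DataFrame:
    """Per-line folding-class proportions, one row per line (order kept).

    Columns: line, n, then one proportion per class; proportions sum to 1
    per row.
    """
    rows = []
    for lc in lines:
        if lc.total == 0:
            raise ParameterError(f"line {lc.line}: zero total count")
        counts = np.array([lc.normal, lc.traced, lc.half, lc.cup], dtype=float)
        props = counts / counts.sum()
        rows.append({"line": lc.line, "n": lc.total,
                     **dict(zip(FOLDING_CLASSES, props))})
    return pd.DataFrame(rows, columns=["line", "n", *FOLDING_CLASSES])
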
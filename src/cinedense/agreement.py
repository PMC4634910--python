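"""Agreement statistics between two encoding conditions.

Implements the reproducibility toolkit used to compare peak strain/twist
measured with two encoding frequencies in the same subjects: Bland-Altman
bias and 95 % limits of agreement, a modified coefficient of variation, and
two-sided paired t-tests.

The modified CoV for a measure X observed in N subjects under conditions 1
and 2 is

    CoV = 100 * [ sum_i SD(x_i, y_i) / N ] / | sum_i ((x_i + y_i)/2) / N |,

where the two-value SD uses the n-1 form, ``SD(x, y) = |x - y| / sqrt(2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "AgreementResult",
    "bland_altman",
    "cov_modified",
    "paired_t",
    "compare_encodings",
    "agreement_table",
]


@dataclass
class AgreementResult:
    """Agreement between one measure under two encoding conditions."""

    label: str
    bias: float
    loa_half_width: float
    cov_percent: float
    p_value: float
    n: int

    def as_row(self) -> dict:
        return {
            "comparison": self.label,
            "bias": self.bias,
            "loa_half_width": self.loa_half_width,
            "cov_percent": self.cov_percent,
            "p_value": self.p_value,
            "n": self.n,
        }


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 paired observations")
    return x, y


def bland_altman(x, y) -> tuple[float, float]:
    """Bias and half-width of the 95 % limits of agreement for paired data.

    ``bias = mean(x - y)``; ``loa_half_width = 1.96 * SD(x - y)`` with the
    sample (n-1) standard deviation.
    """
    x, y = _paired(x, y)
    d = x - y
    return float(d.mean()), float(1.96 * d.std(ddof=1))


def cov_modified(x, y) -> float:
    """Modified coefficient of variation (%) across paired conditions.

    Mean within-pair two-value SD (``|x_i - y_i| / sqrt(2)``) divided by the
    absolute grand mean of the pair means.  Undefined (NaN, with ValueError)
    when the grand mean is zero.
    """
    x, y = _paired(x, y)
    numerator = np.mean(np.abs(x - y) / np.sqrt(2.0))
    denominator = np.abs(np.mean((x + y) / 2.0))
    if denominator == 0.0:
        raise ValueError("modified CoV undefined: grand mean of pair means is zero")
    return float(100.0 * numerator / denominator)


def paired_t(x, y) -> float:
    """Two-sided paired t-test p-value.

    Degenerate differences are handled by convention: all-zero differences
    give p = 1 (no evidence of any difference); zero-variance differences
    with nonzero mean give p = 0 (the t statistic diverges).
    """
    x, y = _paired(x, y)
    d = x - y
    if np.all(d == d[0]):
        return 1.0 if d[0] == 0.0 else 0.0
    return float(sp_stats.ttest_rel(x, y).pvalue)


def compare_encodings(x, y, label: str = "") -> AgreementResult:
    """All three agreement statistics for one paired comparison."""
    x, y = _paired(x, y)
    bias, loa = bland_altman(x, y)
    return AgreementResult(
        label=label,
        bias=bias,
        loa_half_width=loa,
        cov_percent=cov_modified(x, y),
        p_value=paired_t(x, y),
        n=x.size,
    )


def agreement_table(results: list[AgreementResult]) -> pd.DataFrame:
    """Delimited-table layout: comparison, bias, +/-LoA, CoV %, p, n."""
    return pd.DataFrame([r.as_row() for r in results])
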
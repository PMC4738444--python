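"""Genomic inflation (lambda), observed alpha, Q-Q coordinates and moments.

For a scan of 1-df statistics t, the genomic inflation factor is

    lambda = median(t^2) / median(chi^2_1)

For multi-df tests, each P-value is first mapped back to the 1-df chi-square
deviate with the same upper-tail probability, and the median deviate is divided
by the same denominator.  Two denominator conventions are supported: the
three-decimal value 0.455 commonly printed in the GWAS literature, and the
exact chi^2_1 median (~0.4549364), the default for new analyses.

A lambda computed on an interaction-term scan (lambda_3) is *not* comparable to
a main-effect lambda: product-term statistics within a scan share the repeating
SNP and are correlated, so lambda_3 varies under the null far more than a
main-effect lambda does.  For the same reason this module deliberately offers
no genomic-control correction of interaction statistics — dividing by lambda_3
would introduce bias rather than remove it.  Interpret lambda_3 against an
empirical null distribution instead (see :mod:`interscan.empirical_null`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CHISQ1_MEDIAN_EXACT",
    "CHISQ1_MEDIAN_PRINTED",
    "LambdaRecord",
    "QQSeries",
    "lambda_from_tstats",
    "lambda_from_pvalues",
    "observed_alpha",
    "qq_coordinates",
    "stat_moments",
]

#: Exact median of the 1-df chi-square distribution.
CHISQ1_MEDIAN_EXACT: float = float(stats.chi2.ppf(0.5, 1))
#: The three-decimal rounding of the same constant, as printed in GWAS practice.
CHISQ1_MEDIAN_PRINTED: float = 0.455

_P_FLOOR = 1e-300  # cap applied to P = 0 before inverting the chi-square CDF


def _denominator(mode: str) -> float:
    if mode == "exact_chisq1_median":
        return CHISQ1_MEDIAN_EXACT
    if mode == "printed_0455":
        return CHISQ1_MEDIAN_PRINTED
    raise ValueError(f"unknown denominator mode {mode!r}")


@dataclass
class LambdaRecord:
    """One scan's inflation factor with its provenance."""

    lambda_value: float
    source: str  # t_squared | chisq_from_p
    estimator: str
    model_id: str
    test_df: int
    repeating_snp_id: str
    repeating_maf: float
    phenotype_id: str
    n_tests: int
    observed_alpha: float
    n_skipped: int = 0
    denominator_mode: str = "exact_chisq1_median"
    extra: dict = field(default_factory=dict)


@dataclass
class QQSeries:
    expected_neglog10: np.ndarray
    observed_neglog10: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.expected_neglog10)


def lambda_from_tstats(t_values, denominator: str = "exact_chisq1_median") -> float:
    """Inflation factor from 1-df statistics: median(t^2) / chi^2_1 median."""
    t = np.asarray(t_values, dtype=float)
    t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("no finite test statistics supplied")
    return float(np.median(t**2) / _denominator(denominator))


def lambda_from_pvalues(p_values, denominator: str = "exact_chisq1_median") -> float:
    """Inflation factor from P-values of tests of any df.

    Each P is mapped to the 1-df chi-square deviate with that upper-tail
    probability; the median deviate is divided by the chi^2_1 median.  P = 0 is
    capped at 1e-300 with a warning (the deviate is then finite but extreme).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no P-values supplied")
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("P-values must lie in [0, 1]")
    if np.any(p == 0.0):
        warnings.warn("P-values of exactly 0 capped at 1e-300", RuntimeWarning, stacklevel=2)
        p = np.maximum(p, _P_FLOOR)
    deviates = stats.chi2.isf(p, 1)
    return float(np.median(deviates) / _denominator(denominator))


def observed_alpha(p_values, level: float = 0.05) -> float:
    """Fraction of tests with P strictly below ``level``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no P-values supplied")
    return float(np.mean(p < level))


def qq_coordinates(p_values) -> QQSeries:
    """Observed vs expected -log10(P) coordinates for a Q-Q plot.

    Expected quantiles use the (i - 0.5)/m convention for rank i among m tests.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        raise ValueError("no P-values supplied")
    observed = np.sort(-np.log10(np.maximum(p, _P_FLOOR)))
    ranks = np.arange(m, 0, -1)  # largest P first
    expected = np.sort(-np.log10((ranks - 0.5) / m))
    return QQSeries(expected_neglog10=expected, observed_neglog10=observed)


def stat_moments(t_values) -> dict:
    """Sample moments of one scan's statistic distribution.

    Returns variance, skewness, excess kurtosis and the mean (a noncentrality
    proxy).  A constant vector yields variance 0 with higher moments flagged
    undefined.
    """
    t = np.asarray(t_values, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 statistics for moments")
    var = float(np.var(t, ddof=1))
    mean = float(np.mean(t))
    if var == 0.0:
        return {"variance": 0.0, "skewness": np.nan, "excess_kurtosis": np.nan,
                "mean": mean, "degenerate": True}
    return {
        "variance": var,
        "skewness": float(stats.skew(t)),
        "excess_kurtosis": float(stats.kurtosis(t)),
        "mean": mean,
        "degenerate": False,
    }
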
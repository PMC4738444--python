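"""Design matrices, OLS fitting, and sandwich covariance estimators.

The scan models for a repeating SNP x and a non-repeating SNP z on a
quantitative trait y are

    I    y = b0 + b1*z
    II   y = b0 + b1*x + b2*z
    III  y = b0 + b1*x + b2*z + b3*x*z
    IV   y = b0 + b1*x_a + b2*x_d + b3*z_a + b4*z_d
           + b5*x_a*z_a + b6*x_a*z_d + b7*x_d*z_a + b8*x_d*z_d

with 'a' the additive (0,1,2) dosage coding and 'd' the dominance (0,1,0)
coding.  The 1-df interaction test is the Wald test of the product coefficient
in model III; 2-df and 4-df interaction tests are residual-sum-of-squares F
tests on model III / IV.

Coefficient covariance follows the sandwich form
(X'X)^-1 X' Omega X (X'X)^-1 with Omega estimated as

    OLS:  diag[ sum(e_i^2) / (n-k) ]      (pooled; reduces to s^2 (X'X)^-1)
    HC0:  diag[ e_i^2 ]                   (White/Huber/Eicker)
    HC3:  diag[ e_i^2 / (1-h_ii)^2 ]      (leverage-adjusted)

where e_i are OLS residuals and h_ii hat-matrix leverages.  HC1/HC2 are not
provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MODEL_COLUMNS",
    "DesignMatrix",
    "FitResult",
    "CovarianceEstimate",
    "TestResult",
    "SingularDesignError",
    "DegenerateTestError",
    "build_design",
    "fit_ols",
    "covariance",
    "wald_t_test",
    "f_test",
]

MODEL_COLUMNS: dict[str, list[str]] = {
    "I": ["intercept", "nonrep_additive"],
    "II": ["intercept", "rep_additive", "nonrep_additive"],
    "III": ["intercept", "rep_additive", "nonrep_additive", "product"],
    "IV": [
        "intercept",
        "rep_additive",
        "rep_dominance",
        "nonrep_additive",
        "nonrep_dominance",
        "prod_aa",
        "prod_ad",
        "prod_da",
        "prod_dd",
    ],
}


class SingularDesignError(np.linalg.LinAlgError):
    """Design (or a nested reduction of it) is rank deficient.

    Carries the column labels of the offending design so a scan engine can
    convert the failure into a skip record.
    """

    def __init__(self, message: str, column_labels: list[str] | None = None):
        super().__init__(message)
        self.column_labels = column_labels or []


class DegenerateTestError(ValueError):
    """A requested test has zero estimated variance or leverage one."""


@dataclass
class DesignMatrix:
    columns: np.ndarray  # n x k, first column all ones
    column_labels: list[str]
    model_id: str

    @property
    def n(self) -> int:
        return self.columns.shape[0]

    @property
    def k(self) -> int:
        return self.columns.shape[1]


@dataclass
class FitResult:
    """One OLS fit: estimates, residuals, leverages, and scale."""

    beta_hat: np.ndarray
    residuals: np.ndarray
    leverage: np.ndarray
    rss: float
    n_used: int
    k: int
    sigma2_hat: float
    xtx_inv: np.ndarray  # (X'X)^-1, cached for covariance assembly


@dataclass
class CovarianceEstimate:
    matrix: np.ndarray
    estimator: str  # OLS | HC0 | HC3


@dataclass
class TestResult:
    statistic: float
    df_num: int
    df_den: int
    p_value: float
    test_id: str


def _dominance(g: np.ndarray) -> np.ndarray:
    return (g == 1).astype(float)


def build_design(model_id: str, x_rep, z_nonrep) -> DesignMatrix:
    """Assemble the design matrix for one SNP pair under the chosen model.

    ``x_rep`` is ignored by model I.  Inputs must be complete cases (the
    caller handles missingness).
    """
    z = np.asarray(z_nonrep, dtype=float)
    x = np.asarray(x_rep, dtype=float) if x_rep is not None else None
    if model_id not in MODEL_COLUMNS:
        raise ValueError(f"unknown model {model_id!r}")
    if model_id != "I":
        if x is None:
            raise ValueError(f"model {model_id} requires the repeating SNP")
        if x.shape != z.shape:
            raise ValueError("repeating and non-repeating dosage vectors differ in length")
    ones = np.ones_like(z)
    if model_id == "I":
        cols = [ones, z]
    elif model_id == "II":
        cols = [ones, x, z]
    elif model_id == "III":
        cols = [ones, x, z, x * z]
    else:  # IV
        xd, zd = _dominance(x), _dominance(z)
        cols = [ones, x, xd, z, zd, x * z, x * zd, xd * z, xd * zd]
    return DesignMatrix(
        columns=np.column_stack(cols),
        column_labels=list(MODEL_COLUMNS[model_id]),
        model_id=model_id,
    )


def fit_ols(design: DesignMatrix, y) -> FitResult:
    """Least-squares fit via QR, with leverages and residual scale.

    Rank deficiency (singular values below ``max(n,k)*eps*s_max``) raises
    :class:`SingularDesignError` rather than producing a pseudo-inverse fit:
    in a scan, a collapsed column means the pair is degenerate, not that a
    minimum-norm solution is wanted.
    """
    X = design.columns
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("response length does not match design rows")
    if n <= k:
        raise SingularDesignError(
            f"need more than k={k} observations, got {n}", design.column_labels
        )
    Q, R = np.linalg.qr(X, mode="reduced")
    diag = np.abs(np.diag(R))
    tol = max(n, k) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    if diag.min() <= tol:
        bad = [design.column_labels[i] for i in np.where(diag <= tol)[0]]
        raise SingularDesignError(f"rank-deficient design (columns {bad})", bad)
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    leverage = np.einsum("ij,ij->i", Q, Q)
    rss = float(resid @ resid)
    r_inv = np.linalg.solve(R, np.eye(k))
    xtx_inv = r_inv @ r_inv.T
    return FitResult(
        beta_hat=beta,
        residuals=resid,
        leverage=leverage,
        rss=rss,
        n_used=n,
        k=k,
        sigma2_hat=rss / (n - k),
        xtx_inv=xtx_inv,
    )


def covariance(fit: FitResult, design: DesignMatrix, estimator: str = "OLS") -> CovarianceEstimate:
    """Sandwich covariance of the coefficient estimates.

    The OLS branch uses the algebraic reduction s^2 (X'X)^-1; HC0/HC3 assemble
    the full sandwich with per-observation Omega weights.  HC3 requires every
    leverage strictly below one — a unit leverage means one observation fully
    determines a coefficient and the pair should be skipped.
    """
    if estimator == "OLS":
        return CovarianceEstimate(matrix=fit.sigma2_hat * fit.xtx_inv, estimator="OLS")
    if estimator == "HC0":
        w = fit.residuals**2
    elif estimator == "HC3":
        one_minus_h = 1.0 - fit.leverage
        if np.any(one_minus_h <= 1e-12):
            raise DegenerateTestError("HC3 undefined: an observation has leverage 1")
        w = fit.residuals**2 / one_minus_h**2
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    X = design.columns
    meat = (X * w[:, None]).T @ X
    V = fit.xtx_inv @ meat @ fit.xtx_inv
    return CovarianceEstimate(matrix=(V + V.T) / 2.0, estimator=estimator)


def wald_t_test(fit: FitResult, cov: CovarianceEstimate, coef_label: str, labels: list[str]) -> TestResult:
    """Two-sided Wald t test of a single coefficient against zero.

    The t reference with n-k degrees of freedom is used for every covariance
    estimator, including HC0/HC3 (a finite-sample convention; asymptotically
    the reference is normal).
    """
    j = labels.index(coef_label)
    var = cov.matrix[j, j]
    if var <= 0.0:
        raise DegenerateTestError(f"non-positive variance for {coef_label}")
    t = fit.beta_hat[j] / np.sqrt(var)
    df = fit.n_used - fit.k
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df_num=1, df_den=df, p_value=float(p), test_id=f"t_{coef_label}_{cov.estimator}")


def f_test(design_full: DesignMatrix, y, constrained_labels) -> TestResult:
    """RSS-based F test of H0: all ``constrained_labels`` coefficients are zero.

    Fits the full and reduced models; F = [(RSS_r - RSS_f)/q] / [RSS_f/(n-k)].
    Both fits must be full rank.
    """
    constrained = list(constrained_labels)
    labels = design_full.column_labels
    if "intercept" in constrained:
        raise ValueError("cannot constrain the intercept")
    missing = [c for c in constrained if c not in labels]
    if missing:
        raise ValueError(f"labels not in design: {missing}")
    y = np.asarray(y, dtype=float)
    fit_full = fit_ols(design_full, y)
    keep = [i for i, lab in enumerate(labels) if lab not in constrained]
    reduced = DesignMatrix(
        columns=design_full.columns[:, keep],
        column_labels=[labels[i] for i in keep],
        model_id=design_full.model_id,
    )
    fit_red = fit_ols(reduced, y)
    q = len(constrained)
    df_den = fit_full.n_used - fit_full.k
    fstat = ((fit_red.rss - fit_full.rss) / q) / (fit_full.rss / df_den)
    p = float(stats.f.sf(fstat, q, df_den))
    return TestResult(statistic=float(fstat), df_num=q, df_den=df_den, p_value=p, test_id=f"F_{'+'.join(constrained)}")
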
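"""Generalized least squares under a phylogenetic covariance structure.

The estimator is the classic GLS sandwich: beta = (X' V^-1 X)^-1 X' V^-1 y,
with a profiled Gaussian likelihood used for AIC-based comparison of
covariance structures (star, i.e. conventional independence, versus a
tree-derived Brownian structure).  Hypothesis tests on coefficients use
Student's t with degrees of freedom optionally reduced by one per soft
polytomy, the conservative correction applied during testing only.

Conventions, fixed here so model comparisons are well defined:

* the likelihood is ML (not REML): sigma2_hat = r' V^-1 r / n, so models
  sharing fixed effects but differing in V are AIC-comparable;
* AIC counts the residual variance scale: k = n_coef + 1.  Star and
  tree structures add no further parameter (the height exponent is
  fixed), so delta-AIC reduces to delta(-2 logL);
* coefficient standard errors use the unbiased scale r' V^-1 r / (n - p);
* AIC ties within 1e-9 resolve to the star model, the simpler
  covariance assumption.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .tree import CovMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PglsError",
    "DegenerateFitError",
    "GLSFit",
    "TestResult",
    "ModelComparison",
    "fit_gls",
    "aic",
    "akaike_weights",
    "corrected_df",
    "t_test_coefficient",
    "compare_models",
]

AIC_TIE_TOL = 1e-9
# residual quadratic form at or below this fraction of the whitened
# response's sum of squares is treated as an exact fit (roundoff only)
_DEGENERATE_REL_TOL = 1e-20


class PglsError(ValueError):
    """Invalid GLS problem or test."""


class DegenerateFitError(PglsError):
    """Fit with (numerically) zero residual variance; likelihood undefined."""


@dataclass
class GLSFit:
    """One fitted GLS model."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    coef_names: list[str]
    sigma2_hat: float  # ML scale: r' V^-1 r / n
    sigma2_unbiased: float  # r' V^-1 r / (n - p); nan when n == p
    log_likelihood: Optional[float]
    n_obs: int
    n_coef: int
    aic: Optional[float]
    covariance_label: str
    degenerate: bool = False

    @property
    def df_raw(self) -> int:
        return self.n_obs - self.n_coef

    def to_dict(self) -> dict:
        return {
            "covariance_label": self.covariance_label,
            "coefficients": {
                name: float(b)
                for name, b in zip(self.coef_names, self.coefficients)
            },
            "standard_errors": {
                name: float(s)
                for name, s in zip(self.coef_names, self.standard_errors)
            },
            "sigma2_hat": self.sigma2_hat,
            "logLik": self.log_likelihood,
            "AIC": self.aic,
            "n_obs": self.n_obs,
            "n_coef": self.n_coef,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class TestResult:
    """Two-sided t-test of one coefficient."""

    t_statistic: float
    df_raw: int
    df_corrected: int
    p_value: float

    def __post_init__(self) -> None:
        if self.df_corrected > self.df_raw:
            raise PglsError("corrected df cannot exceed raw df")

    def to_dict(self) -> dict:
        return {
            "t": self.t_statistic,
            "df_raw": self.df_raw,
            "df_corrected": self.df_corrected,
            "p": self.p_value,
        }


def _as_matrix(V: Union[CovMatrix, np.ndarray]) -> np.ndarray:
    if isinstance(V, CovMatrix):
        return V.values
    return np.asarray(V, dtype=float)


def _cholesky_with_jitter(V: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        n = V.shape[0]
        jitter = 1e-10 * np.trace(V) / n
        logger.warning(
            "covariance Cholesky failed; retrying with jitter %.3e on the diagonal",
            jitter,
        )
        try:
            return np.linalg.cholesky(V + jitter * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise PglsError(
                "covariance matrix is singular even after jitter; consider a "
                "larger replicate-branch epsilon"
            ) from exc


def _collinear_columns(Xw: np.ndarray, names: Sequence[str]) -> list[str]:
    _, R, piv = sla.qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xw.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[piv[i]] for i in range(rank, len(names))]


def fit_gls(
    y: np.ndarray,
    X: np.ndarray,
    V: Union[CovMatrix, np.ndarray],
    coef_names: Optional[Sequence[str]] = None,
    covariance_label: str = "custom",
) -> GLSFit:
    """Fit y = X beta + e with e ~ N(0, sigma2 * V) by generalized least
    squares, profiling sigma2 at its ML value.

    With V = I this reproduces ordinary least squares exactly.  A fit
    whose residuals vanish (e.g. a saturated design) is returned flagged
    ``degenerate`` with likelihood and AIC set to None.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Vm = _as_matrix(V)
    n, p = X.shape
    if y.shape[0] != n or Vm.shape != (n, n):
        raise PglsError(
            f"shape mismatch: y has {y.shape[0]} rows, X {n}x{p}, V {Vm.shape}"
        )
    if p > n:
        raise PglsError(f"more coefficients ({p}) than observations ({n})")
    if coef_names is None:
        coef_names = [f"x{i}" for i in range(p)]
    coef_names = list(coef_names)

    L = _cholesky_with_jitter(Vm)
    # whiten: solve L z = . so that z ~ iid under the model
    Xw = sla.solve_triangular(L, X, lower=True)
    yw = sla.solve_triangular(L, y, lower=True)

    if np.linalg.matrix_rank(Xw) < p:
        bad = _collinear_columns(Xw, coef_names)
        raise PglsError(f"design matrix is rank deficient; collinear columns: {bad}")

    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta
    quad = float(resid_w @ resid_w)  # r' V^-1 r
    sigma2_ml = quad / n
    sigma2_unbiased = quad / (n - p) if n > p else float("nan")
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))

    XtViX_inv = np.linalg.inv(Xw.T @ Xw)
    if n > p and sigma2_unbiased > 0:
        se = np.sqrt(np.diag(XtViX_inv) * sigma2_unbiased)
    else:
        se = np.full(p, np.nan)

    ss_total = float(yw @ yw)
    if n == p or quad <= _DEGENERATE_REL_TOL * max(ss_total, 1.0):
        return GLSFit(
            coefficients=beta,
            standard_errors=se,
            coef_names=coef_names,
            sigma2_hat=sigma2_ml,
            sigma2_unbiased=sigma2_unbiased,
            log_likelihood=None,
            n_obs=n,
            n_coef=p,
            aic=None,
            covariance_label=covariance_label,
            degenerate=True,
        )

    log_lik = (
        -0.5 * n * math.log(2.0 * math.pi * sigma2_ml) - 0.5 * logdet_V - 0.5 * n
    )
    k = p + 1  # residual variance scale counted
    return GLSFit(
        coefficients=beta,
        standard_errors=se,
        coef_names=coef_names,
        sigma2_hat=sigma2_ml,
        sigma2_unbiased=sigma2_unbiased,
        log_likelihood=log_lik,
        n_obs=n,
        n_coef=p,
        aic=-2.0 * log_lik + 2.0 * k,
        covariance_label=covariance_label,
    )


def aic(fit: GLSFit) -> float:
    """-2 logL + 2k with k = n_coef + 1 (the variance scale)."""
    if fit.degenerate or fit.aic is None:
        raise DegenerateFitError(
            "AIC undefined for a degenerate fit (zero residual variance)"
        )
    return fit.aic


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Normalized relative likelihoods exp(-delta_i/2) of competing models."""
    a = np.asarray(list(aics), dtype=float)
    if a.size < 2:
        raise PglsError("need at least two AIC values to compare")
    if not np.all(np.isfinite(a)):
        raise PglsError(f"non-finite AIC values: {a}")
    rel = np.exp(-0.5 * (a - a.min()))
    return rel / rel.sum()


def corrected_df(n_obs: int, n_coef: int, n_polytomies: int) -> int:
    """Residual df after subtracting one per estimated coefficient and one
    per unresolved (soft-polytomy) node."""
    if min(n_obs, n_coef) < 0 or n_polytomies < 0:
        raise PglsError("counts must be non-negative")
    df = n_obs - n_coef - n_polytomies
    if df <= 0:
        raise PglsError(
            f"corrected df {df} <= 0 (n_obs={n_obs}, n_coef={n_coef}, "
            f"n_polytomies={n_polytomies}); test impossible"
        )
    return df


def t_test_coefficient(fit: GLSFit, coef_index: int, df: int) -> TestResult:
    """Two-sided t-test of one coefficient at the supplied (possibly
    polytomy-corrected) degrees of freedom."""
    if df < 1:
        raise PglsError(f"df must be >= 1, got {df}")
    se = fit.standard_errors[coef_index]
    if not np.isfinite(se) or se <= 0:
        raise PglsError(f"standard error of {fit.coef_names[coef_index]!r} is not positive")
    t = float(fit.coefficients[coef_index] / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult(
        t_statistic=t, df_raw=fit.df_raw, df_corrected=df, p_value=p
    )


@dataclass
class ModelComparison:
    """Star vs tree-structured GLS fits of the same mean model.

    ``tests`` holds the coefficient tests of the best (lowest-AIC) model;
    ``tests_by_model`` keeps both sets — the star model tested at raw df
    and the tree model at polytomy-corrected df.
    """

    fits: dict[str, GLSFit]
    akaike_weights: dict[str, float]
    best: str
    tests: list[TestResult]
    tests_by_model: dict[str, list[TestResult]]
    n_polytomies: int
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "best": self.best,
            "n_polytomies": self.n_polytomies,
            "models": {},
        }
        for label, fit in self.fits.items():
            coef_tests = {
                name: test.to_dict()
                for name, test in zip(fit.coef_names, self.tests_by_model[label])
            }
            model = fit.to_dict()
            model["AICw"] = self.akaike_weights[label]
            model["coefficient_tests"] = coef_tests
            out["models"][label] = model
        if self.extra:
            out["extra"] = self.extra
        return out


def compare_models(
    y: np.ndarray,
    X: np.ndarray,
    V_tree: Union[CovMatrix, np.ndarray],
    n_polytomies: int,
    coef_names: Optional[Sequence[str]] = None,
    extra: Optional[dict] = None,
) -> ModelComparison:
    """Fit the same mean model under star (identity) and tree covariance,
    compute AIC/Akaike weights, and test every coefficient under each
    structure (raw df for star, polytomy-corrected df for the tree)."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    fit_star = fit_gls(y, X, np.eye(n), coef_names, covariance_label="star")
    fit_tree = fit_gls(y, X, V_tree, coef_names, covariance_label="grafen")
    fits = {"star": fit_star, "grafen": fit_tree}
    aics = [aic(fit_star), aic(fit_tree)]
    weights = akaike_weights(aics)
    if abs(aics[0] - aics[1]) < AIC_TIE_TOL:
        best = "star"  # tie: prefer the simpler covariance assumption
    else:
        best = "star" if aics[0] < aics[1] else "grafen"
    df_star = fit_star.df_raw
    df_tree = corrected_df(fit_tree.n_obs, fit_tree.n_coef, n_polytomies)
    tests_by_model = {
        "star": [t_test_coefficient(fit_star, i, df_star) for i in range(fit_star.n_coef)],
        "grafen": [t_test_coefficient(fit_tree, i, df_tree) for i in range(fit_tree.n_coef)],
    }
    return ModelComparison(
        fits=fits,
        akaike_weights={"star": float(weights[0]), "grafen": float(weights[1])},
        best=best,
        tests=tests_by_model[best],
        tests_by_model=tests_by_model,
        n_polytomies=n_polytomies,
        extra=extra or {},
    )
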
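"""Inferential models: GLS and mixed models with ARMA within-subject errors.

The response (log10 blood biomarker) is regressed on time from trauma, its
square, the log10 CSF level and the log10 albumin quotient, while the
within-subject residual series follows a stationary, invertible ARMA(p, q)
process on the regular alignment grid.  Two estimators are provided:

* :class:`MarginalGLS` -- a population-average ("marginal") model: generalized
  least squares with block-diagonal correlation ``R_i(phi, theta)`` per
  subject, the correlation parameters maximized numerically with the fixed
  effects and the residual variance profiled out.
* :class:`LinearMixedModel` -- adds a random intercept and random slope in
  time per subject: ``V_i = Z_i Psi Z_i' + sigma^2 R_i``, with ``Psi``
  parameterized through its Cholesky factor so the fit can reach the
  boundary ``Psi = 0`` (in which case it coincides with the marginal model,
  and the fit is flagged).

Estimation uses restricted maximum likelihood (REML) by default for
variance/random structure and plain ML for fixed-effect likelihood-ratio
tests.  Satterthwaite effective degrees of freedom are derived from the
numeric curvature of the (RE)ML surface in the variance parameters.
Stationarity and invertibility are enforced by the usual smooth
partial-autocorrelation reparameterization, so the optimizer works on an
unconstrained scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.tsa.arima_process import arma_acf
from statsmodels.tsa.statespace.tools import (
    constrain_stationary_univariate,
    unconstrain_stationary_univariate,
)
from statsmodels.tsa.stattools import acf as sm_acf
from statsmodels.tsa.stattools import kpss as sm_kpss
from statsmodels.tsa.stattools import pacf as sm_pacf

__all__ = [
    "ArmaSpec",
    "arma_correlation_matrix",
    "ModelFit",
    "MarginalGLS",
    "LinearMixedModel",
    "fit_marginal_gls",
    "fit_linear_mixed",
    "KpssResult",
    "kpss_test",
    "select_arma_by_aic",
    "LrtResult",
    "compare_models_lrt",
    "type1_f_tests",
    "satterthwaite_df",
    "model_diagnostics",
    "make_clearance_design",
    "DEFAULT_ARMA_GRID",
]


# ---------------------------------------------------------------------------
# ARMA correlation structure


def _min_root_modulus(poly: np.ndarray) -> float:
    """Smallest |root| of a lag polynomial; tiny coefficients are dropped."""
    coeffs = np.where(np.abs(poly) < 1e-12, 0.0, np.asarray(poly, dtype=float))
    while len(coeffs) > 1 and coeffs[-1] == 0.0:
        coeffs = coeffs[:-1]
    if len(coeffs) == 1:
        return np.inf
    roots = np.roots(coeffs[::-1])
    return float(np.min(np.abs(roots))) if len(roots) else np.inf


@dataclass(frozen=True)
class ArmaSpec:
    """Orders and coefficients of a stationary, invertible ARMA(p, q)."""

    p: int
    q: int
    phi: tuple = ()
    theta: tuple = ()
    phi_ci: tuple | None = None  # ((lo, hi), ...) per coefficient
    theta_ci: tuple | None = None

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0:
            raise ValueError("orders must be non-negative")
        if len(self.phi) != self.p or len(self.theta) != self.q:
            raise ValueError("coefficient lengths must match orders")
        # stationarity/invertibility: all roots of the lag polynomial strictly
        # outside the unit circle
        if self.p and _min_root_modulus(np.r_[1.0, -np.asarray(self.phi)]) <= 1.0 + 1e-10:
            raise ValueError(f"non-stationary AR coefficients {self.phi}")
        if self.q and _min_root_modulus(np.r_[1.0, np.asarray(self.theta)]) <= 1.0 + 1e-10:
            raise ValueError(f"non-invertible MA coefficients {self.theta}")

    @property
    def n_params(self) -> int:
        return self.p + self.q


def arma_correlation_matrix(spec: ArmaSpec, n: int) -> np.ndarray:
    """Theoretical n x n autocorrelation matrix of a stationary ARMA process.

    Entry (i, j) equals the process autocorrelation at lag ``|i - j|``; for
    ARMA(1, 1) this is ``rho(1) = (1 + phi theta)(phi + theta) /
    (1 + theta^2 + 2 phi theta)`` and ``rho(k) = phi rho(k-1)`` beyond.
    Symmetric positive definite with unit diagonal.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    # flush subnormal coefficients to zero -- they destabilize the acf solve
    phi = np.where(np.abs(spec.phi) < 1e-12, 0.0, np.asarray(spec.phi, dtype=float))
    theta = np.where(np.abs(spec.theta) < 1e-12, 0.0, np.asarray(spec.theta, dtype=float))
    if not (np.any(phi) or np.any(theta)):
        return np.eye(n)
    rho = arma_acf(np.r_[1.0, -phi], np.r_[1.0, theta], lags=n)
    return linalg.toeplitz(rho)


def _split_params(u: np.ndarray, p: int, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Map unconstrained parameters to stationary AR / invertible MA coefs."""
    phi = constrain_stationary_univariate(u[:p]) if p else np.empty(0)
    th = -constrain_stationary_univariate(u[p : p + q]) if q else np.empty(0)
    return phi, th

def _join_params(phi: Sequence[float], theta: Sequence[float]) -> np.ndarray:
    a = unconstrain_stationary_univariate(np.asarray(phi)) if len(phi) else np.empty(0)
    b = unconstrain_stationary_univariate(-np.asarray(theta)) if len(theta) else np.empty(0)
    return np.r_[a, b]


# ---------------------------------------------------------------------------
# fit container


@dataclass
class ModelFit:
    """Estimates and diagnostics from a marginal or mixed clearance model."""

    kind: str  # "marginal_gls" | "linear_mixed"
    response: str
    terms: tuple
    params: pd.DataFrame  # index term; columns estimate, se, df, t, p
    sigma2: float
    arma: ArmaSpec
    random_effects: np.ndarray | None  # 2x2 Psi or None
    loglik_ml: float
    loglik_reml: float
    estimation: str  # criterion the parameters maximize
    aic: float
    n_obs: int
    n_subjects: int
    n_params: int  # fixed + correlation + variance (+ random) parameters
    converged: bool
    boundary_psi: bool = False
    message: str = ""
    model: "MarginalGLS | LinearMixedModel | None" = field(default=None, repr=False)

    @property
    def loglik(self) -> float:
        return self.loglik_reml if self.estimation == "reml" else self.loglik_ml

    def fitted(self) -> np.ndarray:
        return self.model.X @ self.params["estimate"].to_numpy()

    def residuals(self) -> np.ndarray:
        return self.model.y - self.fitted()


class ConvergenceError(RuntimeError):
    """Raised when the variance-parameter optimizer fails; carries its trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# marginal GLS


class MarginalGLS:
    """GLS with block-diagonal ARMA(p, q) within-subject correlation.

    ``y`` and rows of ``X`` must be sorted by subject and, within subject, in
    time order on a regular grid (ARMA lags are grid steps).
    """

    kind = "marginal_gls"

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        groups: np.ndarray,
        order: tuple[int, int] = (1, 1),
        terms: Sequence[str] | None = None,
        response: str = "y",
    ):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.groups = np.asarray(groups)
        self.order = (int(order[0]), int(order[1]))
        self.response = response
        self.terms = tuple(terms) if terms is not None else tuple(
            f"x{i}" for i in range(self.X.shape[1])
        )
        if len(self.y) != len(self.X) or len(self.y) != len(self.groups):
            raise ValueError("y, X and groups must have equal length")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("singular fixed-effect design matrix")
        # contiguous blocks per subject, preserving input order
        _, first = np.unique(self.groups, return_index=True)
        self.block_slices = []
        for start in sorted(first):
            g = self.groups[start]
            stop = start
            while stop < len(self.groups) and self.groups[stop] == g:
                stop += 1
            self.block_slices.append(slice(start, stop))
        self.n_obs = len(self.y)
        self.n_subjects = len(self.block_slices)
        self.n_fixed = self.X.shape[1]

    # -- covariance pieces --------------------------------------------------

    def _n_cov_params(self) -> int:
        return sum(self.order)

    def _block_cov(self, u: np.ndarray, sl: slice, cache: dict) -> np.ndarray:
        n = sl.stop - sl.start
        if n not in cache:
            p, q = self.order
            phi, th = _split_params(u, p, q)
            spec = ArmaSpec(p, q, tuple(phi), tuple(th))
            cache[n] = arma_correlation_matrix(spec, n)
        return cache[n]

    # -- likelihood ---------------------------------------------------------

    def _profile(self, u: np.ndarray) -> dict:
        """GLS solve at fixed covariance parameters; profiled sigma^2."""
        p_fixed = self.n_fixed
        XtX = np.zeros((p_fixed, p_fixed))
        Xty = np.zeros(p_fixed)
        yty = 0.0
        logdet = 0.0
        cache: dict = {}
        for sl in self.block_slices:
            W = self._block_cov(u, sl, cache)
            try:
                L = linalg.cholesky(W, lower=True)
            except linalg.LinAlgError as exc:
                raise FloatingPointError("covariance not positive definite") from exc
            Xw = linalg.solve_triangular(L, self.X[sl], lower=True)
            yw = linalg.solve_triangular(L, self.y[sl], lower=True)
            XtX += Xw.T @ Xw
            Xty += Xw.T @ yw
            yty += float(yw @ yw)
            logdet += 2.0 * float(np.sum(np.log(np.diag(L))))
        beta = np.linalg.solve(XtX, Xty)
        rss = max(yty - float(beta @ Xty), 1e-300)
        n, p = self.n_obs, p_fixed
        s2_ml = rss / n
        s2_reml = rss / (n - p)
        ll_ml = -0.5 * (n * np.log(2 * np.pi * s2_ml) + logdet + n)
        sign, logdet_xtx = np.linalg.slogdet(XtX)
        ll_reml = -0.5 * (
            (n - p) * np.log(2 * np.pi * s2_reml) + logdet + logdet_xtx + (n - p)
        )
        return {
            "beta": beta,
            "XtX": XtX,
            "rss": rss,
            "logdet": logdet,
            "ll_ml": ll_ml,
            "ll_reml": ll_reml,
            "s2_ml": s2_ml,
            "s2_reml": s2_reml,
        }

    def nll(self, u: np.ndarray, reml: bool = True) -> float:
        try:
            prof = self._profile(np.asarray(u, dtype=float))
        except FloatingPointError:
            return 1e12
        val = -(prof["ll_reml"] if reml else prof["ll_ml"])
        return val if np.isfinite(val) else 1e12

    def _starts(self, n_starts: int) -> list[np.ndarray]:
        k = self._n_cov_params()
        if k == 0:
            return [np.empty(0)]
        starts = [np.zeros(k)]
        p, q = self.order
        moderate = _join_params([0.5] * p if p else [], [0.3] * q if q else [])
        starts.append(moderate)
        rng = np.random.default_rng(20200527)
        while len(starts) < n_starts:
            starts.append(rng.normal(scale=0.8, size=k))
        return starts[:n_starts]

    def fit(self, estimation: str = "reml", n_starts: int = 3) -> ModelFit:
        """Maximize the (RE)ML likelihood over the correlation parameters."""
        reml = estimation == "reml"
        k = self._n_cov_params()
        if k == 0:
            u_hat = np.empty(0)
            converged, message = True, "closed form (no correlation parameters)"
        else:
            best = None
            traces = []
            for u0 in self._starts(n_starts):
                res = optimize.minimize(
                    self.nll, u0, args=(reml,), method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
                )
                res = optimize.minimize(
                    self.nll, res.x, args=(reml,), method="L-BFGS-B",
                    options={"ftol": 1e-12, "gtol": 1e-8},
                )
                traces.append(res)
                if best is None or res.fun < best.fun:
                    best = res
            if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
                raise ConvergenceError("ARMA covariance optimization failed", traces)
            u_hat, converged, message = best.x, True, str(best.message)
        return self._pack(u_hat, estimation, converged, message)

    # -- packaging ----------------------------------------------------------

    def _spec_at(self, u: np.ndarray) -> ArmaSpec:
        p, q = self.order
        phi, th = _split_params(u, p, q)
        return ArmaSpec(p, q, tuple(float(v) for v in phi), tuple(float(v) for v in th))

    def _arma_cis(self, u: np.ndarray, reml: bool) -> tuple[tuple | None, tuple | None]:
        """Wald CIs on the unconstrained scale, endpoints back-transformed."""
        k = len(u)
        if k == 0:
            return None, None
        try:
            H = _numeric_hessian(lambda v: self.nll(v, reml), u)
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            return None, None
        zc = stats.norm.ppf(0.975)
        p, q = self.order
        lo_u, hi_u = u - zc * se, u + zc * se

        def endpoint(vec):
            phi, th = _split_params(np.asarray(vec), p, q)
            return np.r_[phi, th]

        a, b = endpoint(lo_u), endpoint(hi_u)
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        phi_ci = tuple((float(lo[i]), float(hi[i])) for i in range(p)) or None
        th_ci = tuple((float(lo[p + i]), float(hi[p + i])) for i in range(q)) or None
        return phi_ci, th_ci

    def _n_model_params(self) -> int:
        return self.n_fixed + self._n_cov_params() + 1  # + sigma^2

    def _pack(self, u_hat: np.ndarray, estimation: str, converged: bool, message: str) -> ModelFit:
        reml = estimation == "reml"
        prof = self._profile(u_hat)
        s2 = prof["s2_reml"] if reml else prof["s2_ml"]
        cov_beta = s2 * np.linalg.inv(prof["XtX"])
        se = np.sqrt(np.diag(cov_beta))
        df_resid = self.n_obs - self.n_fixed
        tvals = prof["beta"] / se
        pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
        params = pd.DataFrame(
            {
                "estimate": prof["beta"],
                "se": se,
                "df": float(df_resid),
                "t": tvals,
                "p": pvals,
            },
            index=pd.Index(self.terms, name="term"),
        )
        phi_ci, th_ci = self._arma_cis(u_hat, reml)
        spec = self._spec_at(u_hat)
        spec = ArmaSpec(spec.p, spec.q, spec.phi, spec.theta, phi_ci, th_ci)
        n_par = self._n_model_params()
        ll = prof["ll_reml"] if reml else prof["ll_ml"]
        fit = ModelFit(
            kind=self.kind,
            response=self.response,
            terms=self.terms,
            params=params,
            sigma2=float(s2),
            arma=spec,
            random_effects=self._psi_at(u_hat, s2),
            loglik_ml=float(prof["ll_ml"]),
            loglik_reml=float(prof["ll_reml"]),
            estimation=estimation,
            aic=float(-2 * ll + 2 * n_par),
            n_obs=self.n_obs,
            n_subjects=self.n_subjects,
            n_params=n_par,
            converged=converged,
            boundary_psi=self._psi_boundary(u_hat, s2),
            message=message,
            model=self,
        )
        fit._u_hat = u_hat  # variance parameters on the unconstrained scale
        fit._cov_beta = cov_beta
        return fit

    def _psi_at(self, u: np.ndarray, s2: float):
        return None

    def _psi_boundary(self, u: np.ndarray, s2: float) -> bool:
        return False

    # -- pieces used by Satterthwaite --------------------------------------

    def cov_beta_at(self, v: np.ndarray) -> np.ndarray:
        """Covariance of beta-hat as a function of the full variance vector.

        ``v`` = (unconstrained correlation/random params..., log sigma^2).
        """
        u, log_s2 = v[:-1], v[-1]
        prof = self._profile(u)
        return np.exp(log_s2) * np.linalg.inv(prof["XtX"])

    def nll_full(self, v: np.ndarray, reml: bool = True) -> float:
        """Negative (RE)ML loglik with sigma^2 an explicit free parameter."""
        u, log_s2 = v[:-1], v[-1]
        s2 = np.exp(log_s2)
        try:
            prof = self._profile(u)
        except FloatingPointError:
            return 1e12
        n, p = self.n_obs, self.n_fixed
        if reml:
            sign, logdet_xtx = np.linalg.slogdet(prof["XtX"])
            val = 0.5 * (
                (n - p) * np.log(2 * np.pi * s2)
                + prof["logdet"]
                + logdet_xtx
                + prof["rss"] / s2
            )
        else:
            val = 0.5 * (n * np.log(2 * np.pi * s2) + prof["logdet"] + prof["rss"] / s2)
        return val if np.isfinite(val) else 1e12

    def variance_vector(self, fit: ModelFit) -> np.ndarray:
        return np.r_[fit._u_hat, np.log(fit.sigma2)]


# ---------------------------------------------------------------------------
# linear mixed model


class LinearMixedModel(MarginalGLS):
    """Random intercept + slope per subject on top of ARMA residuals.

    ``z_slope`` is the covariate carrying the random slope (same scale as the
    fixed-effect time term).  The random-effect covariance ``Psi`` is
    parameterized relative to ``sigma^2`` through a lower-triangular Cholesky
    factor with unconstrained entries, so ``Psi = 0`` is attainable; fits on
    that boundary are flagged and the marginal model recommended.
    """

    kind = "linear_mixed"

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        groups: np.ndarray,
        z_slope: np.ndarray,
        order: tuple[int, int] = (1, 1),
        terms: Sequence[str] | None = None,
        response: str = "y",
    ):
        super().__init__(y, X, groups, order=order, terms=terms, response=response)
        if self.n_subjects < 3:
            raise ValueError("at least 3 subjects needed to estimate a 2x2 Psi")
        self.Z = np.column_stack([np.ones(self.n_obs), np.asarray(z_slope, dtype=float)])

    def _n_cov_params(self) -> int:
        return sum(self.order) + 3

    def _block_cov(self, u: np.ndarray, sl: slice, cache: dict) -> np.ndarray:
        n = sl.stop - sl.start
        z_key = self.Z[sl, 1].tobytes()
        key = (n, z_key)
        if key not in cache:
            p, q = self.order
            phi, th = _split_params(u[: p + q], p, q)
            spec = ArmaSpec(p, q, tuple(phi), tuple(th))
            R = arma_correlation_matrix(spec, n)
            L = self._chol_factor(u)
            G = L @ L.T
            Z = self.Z[sl]
            cache[key] = Z @ G @ Z.T + R
        return cache[key]

    @staticmethod
    def _chol_from(entries: np.ndarray) -> np.ndarray:
        return np.array([[entries[0], 0.0], [entries[1], entries[2]]])

    def _chol_factor(self, u: np.ndarray) -> np.ndarray:
        return self._chol_from(u[-3:])

    def _starts(self, n_starts: int) -> list[np.ndarray]:
        k_arma = sum(self.order)
        base = super()._starts(max(n_starts, 2))
        starts = []
        for i, b in enumerate(base):
            chol0 = np.array([0.3, 0.0, 0.3]) if i % 2 == 0 else np.array([0.05, 0.0, 0.05])
            starts.append(np.r_[b[:k_arma] if k_arma else np.empty(0), chol0])
        return starts[:n_starts]

    def _spec_at(self, u: np.ndarray) -> ArmaSpec:
        return super()._spec_at(u[: sum(self.order)])

    def _arma_cis(self, u, reml):
        # observed information over the full parameter vector, then the
        # ARMA sub-block's marginal intervals
        k_arma = sum(self.order)
        if k_arma == 0:
            return None, None
        try:
            H = _numeric_hessian(lambda v: self.nll(v, reml), u)
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov)[:k_arma], 0, None))
        except np.linalg.LinAlgError:
            return None, None
        zc = stats.norm.ppf(0.975)
        p, q = self.order
        lo_u = u[:k_arma] - zc * se
        hi_u = u[:k_arma] + zc * se

        def endpoint(vec):
            phi, th = _split_params(np.asarray(vec), p, q)
            return np.r_[phi, th]

        a, b = endpoint(lo_u), endpoint(hi_u)
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        phi_ci = tuple((float(lo[i]), float(hi[i])) for i in range(p)) or None
        th_ci = tuple((float(lo[p + i]), float(hi[p + i])) for i in range(q)) or None
        return phi_ci, th_ci

    def _n_model_params(self) -> int:
        return self.n_fixed + sum(self.order) + 3 + 1

    def _psi_at(self, u: np.ndarray, s2: float) -> np.ndarray:
        L = self._chol_factor(u)
        return s2 * (L @ L.T)

    def _psi_boundary(self, u: np.ndarray, s2: float, rtol: float = 1e-2) -> bool:
        psi = self._psi_at(u, s2)
        return bool(np.any(np.diag(psi) < rtol * s2))


def fit_marginal_gls(
    y,
    X,
    groups,
    order: tuple[int, int] = (1, 1),
    terms: Sequence[str] | None = None,
    response: str = "y",
    estimation: str = "reml",
    n_starts: int = 3,
) -> ModelFit:
    """Fit a marginal (population-average) GLS clearance model."""
    return MarginalGLS(y, X, groups, order=order, terms=terms, response=response).fit(
        estimation=estimation, n_starts=n_starts
    )


def fit_linear_mixed(
    y,
    X,
    groups,
    z_slope,
    order: tuple[int, int] = (1, 1),
    terms: Sequence[str] | None = None,
    response: str = "y",
    estimation: str = "reml",
    n_starts: int = 3,
) -> ModelFit:
    """Fit the random-intercept + random-slope mixed clearance model.

    A fit whose estimated random-effect covariance collapses to the boundary
    is returned with ``boundary_psi=True`` (use the marginal model then, as
    the equivalent population-level fit).
    """
    fit = LinearMixedModel(
        y, X, groups, z_slope, order=order, terms=terms, response=response
    ).fit(estimation=estimation, n_starts=n_starts)
    if fit.boundary_psi:
        fit.message = (fit.message + "; random-effect covariance on boundary, "
                       "marginal model recommended").strip("; ")
    return fit


# ---------------------------------------------------------------------------
# KPSS stationarity screen


@dataclass(frozen=True)
class KpssResult:
    statistic: float
    lag_truncation: int
    level: float
    verdict: str  # "stationary_not_rejected" | "rejected"


def kpss_test(series, lag_truncation: int | None = None, level: float = 0.05) -> KpssResult:
    """Level-stationarity KPSS test.

    Statistic ``n^-2 sum_t S_t^2 / lrv`` with ``S_t`` partial sums of the
    demeaned series and ``lrv`` the Bartlett-window long-run variance at the
    given truncation, defaulting to ``floor(4 (n/100)^(1/4))``.  The verdict
    compares against the standard critical value at ``level``; the null is
    stationarity, so "rejected" means evidence of non-stationarity.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 8:
        raise ValueError("series too short for a KPSS screen (need >= 8 points)")
    if np.ptp(x) == 0:
        raise ValueError("constant series has zero long-run variance")
    if lag_truncation is None:
        lag_truncation = int(np.floor(4 * (n / 100.0) ** 0.25))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, _pval, used_lags, crit = sm_kpss(x, regression="c", nlags=lag_truncation)
    key = f"{level * 100:g}%"
    if key not in crit:
        raise ValueError(f"no critical value tabulated for level {level}")
    verdict = "rejected" if stat >= crit[key] else "stationary_not_rejected"
    return KpssResult(
        statistic=float(stat), lag_truncation=int(used_lags), level=level, verdict=verdict
    )


# ---------------------------------------------------------------------------
# model selection


#: all (p, q) with p, q in 0..4 -- 25 candidate correlation structures
DEFAULT_ARMA_GRID: tuple = tuple((p, q) for p in range(5) for q in range(5))


def select_arma_by_aic(
    y,
    X,
    groups,
    candidates: Sequence[tuple[int, int]] = DEFAULT_ARMA_GRID,
    z_slope=None,
    estimation: str = "reml",
    terms: Sequence[str] | None = None,
    response: str = "y",
) -> tuple[ModelFit, pd.DataFrame]:
    """Fit each candidate ARMA order and pick the lowest-AIC converged fit.

    Failed candidates are recorded in the table (aic = NaN) and excluded;
    ties break toward fewer parameters.  Raises if every candidate fails.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate order")
    rows, fits = [], {}
    for p, q in candidates:
        try:
            if z_slope is None:
                fit = fit_marginal_gls(
                    y, X, groups, order=(p, q), terms=terms, response=response,
                    estimation=estimation,
                )
            else:
                fit = fit_linear_mixed(
                    y, X, groups, z_slope, order=(p, q), terms=terms,
                    response=response, estimation=estimation,
                )
            fits[(p, q)] = fit
            rows.append({"p": p, "q": q, "aic": fit.aic, "loglik": fit.loglik,
                         "n_params": fit.n_params, "status": "ok"})
        except (ConvergenceError, FloatingPointError, np.linalg.LinAlgError, ValueError) as exc:
            rows.append({"p": p, "q": q, "aic": np.nan, "loglik": np.nan,
                         "n_params": np.nan, "status": f"failed: {exc}"})
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["aic"]).sort_values(["aic", "n_params"], kind="stable")
    if len(ok) == 0:
        raise ConvergenceError("all candidate ARMA structures failed to fit")
    best = ok.iloc[0]
    return fits[(int(best["p"]), int(best["q"]))], table


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    p: float


def compare_models_lrt(full: ModelFit, reduced: ModelFit) -> LrtResult:
    """Likelihood-ratio test between nested fits on the same rows.

    Fixed-effect comparisons should use ML fits; covariance/random-structure
    comparisons REML fits with identical fixed parts.  ``2 * delta loglik``
    against chi-square with the parameter-count difference as df; identical
    models give statistic 0 and p = 1.
    """
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits are not on the same response rows")
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("fixed-effect terms are not nested")
    if full.estimation != reduced.estimation:
        raise ValueError("compare fits estimated under the same criterion")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("'full' model has fewer parameters than 'reduced'")
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LrtResult(statistic=float(stat), df=int(df), p=p)


def type1_f_tests(fit: ModelFit) -> pd.DataFrame:
    """Sequential (type I) F tests for the fixed terms, in entry order.

    Terms are added one at a time on the whitened (estimated-covariance)
    scale; each F compares the drop in residual sum of squares against the
    full model's residual mean square.
    """
    model = fit.model
    u = fit._u_hat
    cache: dict = {}
    Xw_blocks, yw_blocks = [], []
    for sl in model.block_slices:
        W = model._block_cov(u, sl, cache)
        L = linalg.cholesky(W, lower=True)
        Xw_blocks.append(linalg.solve_triangular(L, model.X[sl], lower=True))
        yw_blocks.append(linalg.solve_triangular(L, model.y[sl], lower=True))
    Xw = np.vstack(Xw_blocks)
    yw = np.concatenate(yw_blocks)
    n, p = len(yw), Xw.shape[1]

    def rss(k: int) -> float:
        if k == 0:
            return float(yw @ yw)
        beta, *_ = np.linalg.lstsq(Xw[:, :k], yw, rcond=None)
        r = yw - Xw[:, :k] @ beta
        return float(r @ r)

    rss_seq = [rss(k) for k in range(p + 1)]
    mse = rss_seq[-1] / (n - p)
    rows = []
    for j in range(p):
        f = (rss_seq[j] - rss_seq[j + 1]) / mse
        rows.append(
            {
                "term": fit.terms[j],
                "F": f,
                "df1": 1,
                "df2": n - p,
                "p": float(stats.f.sf(f, 1, n - p)),
            }
        )
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# Satterthwaite degrees of freedom


def _numeric_hessian(fun: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    k = len(x)
    H = np.empty((k, k))
    f0 = fun(x)
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            if i == j:
                val = (fun(x + ei) - 2 * f0 + fun(x - ei)) / steps[i] ** 2
            else:
                val = (
                    fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * steps[i] * steps[j])
            H[i, j] = H[j, i] = val
    return H


def _numeric_gradient(fun: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    g = np.empty(len(x))
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(len(x)):
        e = np.zeros(len(x)); e[i] = steps[i]
        g[i] = (fun(x + e) - fun(x - e)) / (2 * steps[i])
    return g


def satterthwaite_df(fit: ModelFit, contrast) -> tuple[float, float, bool]:
    """Satterthwaite effective df and p-value for a fixed-effect contrast.

    ``df = 2 Var(c' beta)^2 / (g' A g)`` where ``g`` is the gradient of
    ``Var(c' beta)`` in the variance parameters and ``A`` their asymptotic
    covariance from the numeric observed information of the REML surface.
    Returns ``(df, p, fallback)``; when the information matrix is unusable
    the residual df ``n - rank(X)`` is used and flagged.
    """
    c = np.zeros(len(fit.terms))
    if isinstance(contrast, str):
        c[list(fit.terms).index(contrast)] = 1.0
    else:
        c = np.asarray(contrast, dtype=float)
    model = fit.model
    v_hat = model.variance_vector(fit)
    var_c = float(c @ fit._cov_beta @ c)
    est = float(c @ fit.params["estimate"].to_numpy())
    t_val = est / np.sqrt(var_c)
    df_fallback = fit.n_obs - model.n_fixed
    try:
        H = _numeric_hessian(lambda v: model.nll_full(v, reml=True), v_hat)
        # pseudo-inverse: unidentified variance directions (zero curvature)
        # contribute nothing rather than poisoning the whole matrix
        A = np.linalg.pinv(H, rcond=1e-10)
        g = _numeric_gradient(lambda v: float(c @ model.cov_beta_at(v) @ c), v_hat)
        denom = float(g @ A @ g)
        df = 2.0 * var_c**2 / denom
        if not np.isfinite(df) or df <= 0:
            raise np.linalg.LinAlgError("degenerate Satterthwaite denominator")
        fallback = False
    except (np.linalg.LinAlgError, FloatingPointError):
        df, fallback = float(df_fallback), True
    df = min(df, float(df_fallback))
    p = float(2 * stats.t.sf(abs(t_val), df))
    return df, p, fallback


# ---------------------------------------------------------------------------
# diagnostics


def model_diagnostics(fit: ModelFit, acf_lags: int = 10, outlier_z: float = 3.5) -> dict:
    """Graph-oriented validation summary of a converged fit.

    Returns normalized (whitened) residuals, fitted-vs-observed correlation,
    per-subject residual ACF/PACF, and subjects flagged as outliers by a
    robust distance on their mean absolute normalized residual.
    """
    model = fit.model
    u = fit._u_hat
    cache: dict = {}
    resid = fit.residuals()
    norm_resid = np.empty_like(resid)
    per_subject_acf, per_subject_pacf = {}, {}
    subj_score = {}
    sd = np.sqrt(fit.sigma2)
    for sl in model.block_slices:
        W = model._block_cov(u, sl, cache)
        L = linalg.cholesky(W, lower=True)
        r = linalg.solve_triangular(L, resid[sl], lower=True) / sd
        norm_resid[sl] = r
        sid = model.groups[sl.start]
        n_i = len(r)
        lags = min(acf_lags, n_i - 2)
        if lags >= 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                per_subject_acf[sid] = sm_acf(r, nlags=lags, fft=False)
                try:
                    per_subject_pacf[sid] = sm_pacf(r, nlags=min(lags, n_i // 2 - 1))
                except (ValueError, np.linalg.LinAlgError):
                    per_subject_pacf[sid] = np.array([1.0])
        subj_score[sid] = float(np.mean(np.abs(r)))
    scores = pd.Series(subj_score)
    med = scores.median()
    mad = float((scores - med).abs().median()) * 1.4826
    robust_z = (scores - med) / mad if mad > 0 else scores * 0.0
    flagged = tuple(scores.index[robust_z > outlier_z])
    fitted = fit.fitted()
    obs = model.y
    r_fo = float(np.corrcoef(fitted, obs)[0, 1]) if np.std(fitted) > 0 else 1.0
    return {
        "normalized_residuals": norm_resid,
        "fitted": fitted,
        "observed": obs,
        "fitted_observed_corr": r_fo,
        "residual_acf": per_subject_acf,
        "residual_pacf": per_subject_pacf,
        "subject_scores": scores,
        "outlier_subjects": flagged,
    }


# ---------------------------------------------------------------------------
# design-matrix helper


def make_clearance_design(
    values: pd.DataFrame,
    response: str,
    csf: str | None = None,
    qa: str | None = "QA",
    time_scale_h: float = 24.0,
    log10_response: bool = True,
) -> dict:
    """Build the clearance regression design from an aligned-grid frame.

    Response: log10 blood biomarker.  Fixed terms: centered time (in units of
    ``time_scale_h``, default days), its square, log10 CSF level and log10
    albumin quotient (covariates already log10-transformed upstream are
    passed as-is by naming them here).  Returns arrays plus term names; rows
    with any missing component are dropped (complete cases).
    """
    cols = [response] + [c for c in (csf, qa) if c is not None]
    d = values.dropna(subset=cols).sort_values(["subject_id", "time_h"])
    y = d[response].to_numpy(dtype=float)
    if log10_response:
        if np.any(y <= 0):
            raise ValueError("response must be positive for log10")
        y = np.log10(y)
    t = d["time_h"].to_numpy(dtype=float) / time_scale_h
    t_c = t - t.mean()
    terms = ["intercept", "time", "time2"]
    columns = [np.ones(len(d)), t_c, t_c**2]
    for name, col in (("csf", csf), ("qa", qa)):
        if col is not None:
            v = d[col].to_numpy(dtype=float)
            if np.any(v <= 0):
                raise ValueError(f"{col} must be positive for log10")
            columns.append(np.log10(v))
            terms.append(f"log10_{col.lower()}")
    X = np.column_stack(columns)
    return {
        "y": y,
        "X": X,
        "groups": d["subject_id"].to_numpy(),
        "z_slope": t_c,
        "terms": tuple(terms),
        "frame": d,
    }
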
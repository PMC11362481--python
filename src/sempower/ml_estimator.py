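"""Normal-theory maximum-likelihood estimation of factor models.

The estimator minimizes the ML discrepancy between the sample covariance S
(divisor n) and the model-implied covariance Σ(θ) = ΛΦΛ' + Θ,

    F_ML(θ) = ln|Σ(θ)| − ln|S| + tr(S Σ(θ)⁻¹) − p ,

over the free entries of a fitted-pattern :class:`ModelSpec`, using L-BFGS-B
with the exact analytic gradient

    ∂F/∂Λ = 2 E Λ Φ,   ∂F/∂Φ = Λ' E Λ,   ∂F/∂θ_ii = E_ii,
    where E = Σ⁻¹ − Σ⁻¹ S Σ⁻¹ .

Residual variances are optimized on the raw scale, so Heywood cases
(negative residual-variance estimates) remain representable; they are
flagged as inadmissible without affecting convergence status.  The test
statistic is T = n · F_ML and the log-likelihood is the multivariate-normal
likelihood at Σ(θ̂) with means saturated (the mean terms, common to all
candidate models, are omitted throughout).  A Wishart ``n-1`` multiplier is
available for sensitivity checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.optimize import minimize

from .datagen import Dataset
from .errors import DegeneracyError, InvalidParameterError
from .model_zoo import ImpliedCovariance, ModelSpec, count_free_parameters, model_df

__all__ = [
    "FitResult",
    "sample_cov",
    "fml",
    "fit",
    "fit_cov",
    "fit_baseline",
    "saturated_loglik",
]

_BIG = 1e12  # objective value returned outside the positive-definite region
LN2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one model fit to one dataset."""

    model: str
    converged: bool
    admissible: bool
    estimates: np.ndarray       # free-parameter vector in spec order
    F_ml: float
    loglik: float
    T: float
    df: int
    q: int                      # number of free parameters
    n: int
    diagnostics: dict = field(default_factory=dict)


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, Dataset):
        return data.values
    return np.asarray(data, dtype=float)


def sample_cov(data) -> np.ndarray:
    """ML (divisor n) covariance matrix of the columns of a dataset."""
    x = _as_matrix(data)
    n = x.shape[0]
    if n < 2:
        raise InvalidParameterError(f"sample covariance needs n >= 2, got n={n}")
    xc = x - x.mean(axis=0)
    s = xc.T @ xc / n
    if (np.diag(s) <= 0).any():
        warnings.warn("constant column: sample covariance is singular", stacklevel=2)
    return s


def fml(S, sigma) -> float:
    """ML discrepancy F(S, Σ) = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p."""
    if isinstance(sigma, ImpliedCovariance):
        sigma = sigma.sigma
    S = np.asarray(S, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise DegeneracyError("sample covariance is not positive definite")
    try:
        c, low = sla.cho_factor(sigma, lower=True)
    except np.linalg.LinAlgError as exc:
        raise DegeneracyError(f"model covariance is singular: {exc}") from exc
    logdet_sigma = 2.0 * np.log(np.diag(c)).sum()
    trace = np.trace(sla.cho_solve((c, low), S))
    return float(logdet_sigma - logdet_s + trace - p)


class _ParamMap:
    """Packs/unpacks the free entries of a spec into a flat vector.

    Order: free loadings (row-major), free factor covariances (upper
    triangle, row-major), free residual variances.
    """

    def __init__(self, spec: ModelSpec):
        m = spec.m
        self.spec = spec
        self.lmask = spec.loadings_free
        self.pmask = spec.factor_cov_free & np.triu(np.ones((m, m), dtype=bool))
        self.rmask = spec.residuals_free
        self.nl = int(self.lmask.sum())
        self.np_ = int(self.pmask.sum())
        self.nr = int(self.rmask.sum())
        self.q = self.nl + self.np_ + self.nr
        self._pu, self._pv = np.nonzero(self.pmask)
        # flat-index views and constant bases, precomputed for speed
        self._l_idx = np.flatnonzero(self.lmask.ravel())
        self._r_idx = np.flatnonzero(self.rmask)
        self._l_base = np.array(spec.loadings)
        self._phi_base = np.array(spec.factor_cov)
        self._r_base = np.array(spec.residuals)
        self._phi_mult = (2.0 - np.eye(m)).ravel()
        self._p_idx = self._pu * m + self._pv

    def start(self, S: np.ndarray) -> np.ndarray:
        """Starting values: loadings 0.5, factor correlations 0 (variances
        from the pattern), residuals 0.5·diag(S)."""
        theta = np.empty(self.q)
        theta[: self.nl] = self.spec.loadings[self.lmask]
        theta[self.nl : self.nl + self.np_] = self.spec.factor_cov[self.pmask]
        theta[self.nl + self.np_ :] = 0.5 * np.diag(S)[self.rmask]
        return theta

    def unpack(self, theta: np.ndarray):
        L = self._l_base.copy()
        L.ravel()[self._l_idx] = theta[: self.nl]
        phi = self._phi_base.copy()
        vals = theta[self.nl : self.nl + self.np_]
        phi[self._pu, self._pv] = vals
        phi[self._pv, self._pu] = vals
        th = self._r_base.copy()
        th[self._r_idx] = theta[self.nl + self.np_ :]
        return L, phi, th

    def pack_grad(self, gL, gPhi, gTh) -> np.ndarray:
        g = np.empty(self.q)
        g[: self.nl] = gL.ravel()[self._l_idx]
        # off-diagonal covariances appear twice in Φ
        g[self.nl : self.nl + self.np_] = (
            gPhi.ravel()[self._p_idx] * self._phi_mult[self._p_idx]
        )
        g[self.nl + self.np_ :] = gTh[self._r_idx]
        return g


def _make_objective(pm: _ParamMap, S: np.ndarray, logdet_s: float):
    p = S.shape[0]
    eye = np.eye(p)

    def objective(theta):
        L, phi, th = pm.unpack(theta)
        sigma = L @ phi @ L.T
        sigma[np.diag_indices_from(sigma)] += th
        try:
            c, low = sla.cho_factor(sigma, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return _BIG, np.zeros_like(theta)
        d = np.diag(c)
        if (d <= 0).any() or not np.isfinite(d).all():
            return _BIG, np.zeros_like(theta)
        logdet_sigma = 2.0 * np.log(d).sum()
        isigma = sla.cho_solve((c, low), eye, check_finite=False)
        A = isigma @ S
        f = logdet_sigma - logdet_s + np.trace(A) - p
        E = isigma - A @ isigma
        E = 0.5 * (E + E.T)
        gL = 2.0 * E @ L @ phi
        gPhi = L.T @ E @ L
        gTh = np.diag(E).copy()
        return f, pm.pack_grad(gL, gPhi, gTh)

    return objective


def _correlations_admissible(phi: np.ndarray) -> bool:
    d = np.diag(phi)
    if (d <= 0).any():
        return False
    corr = phi / np.sqrt(np.outer(d, d))
    off = corr[~np.eye(phi.shape[0], dtype=bool)]
    return bool((np.abs(off) <= 1.0 + 1e-10).all())


def fit_cov(
    spec: ModelSpec,
    S: np.ndarray,
    n: int,
    *,
    multiplier: str = "n",
    gtol: float = 1e-6,
    maxiter: int = 500,
    n_restarts: int = 1,
) -> FitResult:
    """Fit a fitted-pattern spec to a sample covariance matrix.

    Convergence requires the optimizer to finish within its iteration
    budget with gradient max-norm ≤ ``gtol`` at a point where Σ(θ̂) is
    positive definite; one jittered restart is attempted before declaring
    failure.  Statistical failure is recorded in the result, not raised.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if p != spec.p:
        raise InvalidParameterError(
            f"{spec.name}: data has {p} columns, spec expects {spec.p}"
        )
    df = model_df(spec)  # raises if under-identified
    q = count_free_parameters(spec)
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        return FitResult(
            model=spec.name, converged=False, admissible=False,
            estimates=np.full(q, np.nan), F_ml=np.nan, loglik=np.nan,
            T=np.nan, df=df, q=q, n=n,
            diagnostics={"reason": "singular sample covariance"},
        )

    pm = _ParamMap(spec)
    objective = _make_objective(pm, S, logdet_s)
    theta0 = pm.start(S)
    # deterministic jitter stream for restarts (keyed on the data)
    jitter_rng = np.random.default_rng(
        abs(int(np.round(S.sum() * 1e6)) + 7919 * n) % (2**31)
    )

    best = None
    n_tries = 0
    for attempt in range(1 + max(0, n_restarts)):
        start = theta0 if attempt == 0 else theta0 + jitter_rng.uniform(
            -0.2, 0.2, size=theta0.shape
        )
        res = minimize(
            objective,
            start,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                     "ftol": 1e-12, "gtol": gtol * 0.1},
        )
        n_tries += 1
        f_val, grad = objective(res.x)
        gnorm = float(np.abs(grad).max()) if grad.size else 0.0
        if f_val < _BIG / 2 and gtol < gnorm <= 1e-3:
            # Nearly there but stopped by L-BFGS-B's ftol rule; polish
            # with BFGS, which stops on gradient norm.  Gradients far
            # from zero mark empirically under-identified valleys where
            # further iterations do not help, so those are not polished.
            res2 = minimize(
                objective, res.x, jac=True, method="BFGS",
                options={"gtol": gtol * 0.1, "maxiter": 100},
            )
            f2, g2 = objective(res2.x)
            if f2 <= f_val and f2 < _BIG / 2:
                res, f_val, grad = res2, f2, g2
                gnorm = float(np.abs(grad).max())
        ok = f_val < _BIG / 2 and np.isfinite(f_val) and gnorm <= gtol
        cand = (ok, -f_val, res.x, f_val, gnorm, res)
        if best is None or cand[:2] > best[:2]:
            best = cand
        if best[0]:
            break

    ok, _, theta_hat, f_hat, gnorm, res = best
    L, phi, th = pm.unpack(theta_hat)
    sigma_hat = L @ phi @ L.T + np.diag(th)
    eig_min = float(np.linalg.eigvalsh(sigma_hat)[0])
    converged = bool(ok and eig_min > 0.0)
    admissible = bool(
        converged and (th >= 0.0).all() and _correlations_admissible(phi)
    )
    mult = float(n) if multiplier == "n" else float(n - 1)
    if converged:
        f_ml = max(float(f_hat), 0.0)
        loglik = -0.5 * n * (p * LN2PI + logdet_s + p) - 0.5 * n * f_ml
        T = mult * f_ml
    else:
        f_ml = loglik = T = float("nan")
    return FitResult(
        model=spec.name,
        converged=converged,
        admissible=admissible,
        estimates=theta_hat,
        F_ml=f_ml,
        loglik=loglik,
        T=T,
        df=df,
        q=q,
        n=n,
        diagnostics={
            "grad_max": gnorm,
            "n_starts": n_tries,
            "nit": int(res.nit),
            "sigma_min_eig": eig_min,
            "optimizer_status": int(res.status),
        },
    )


def fit(spec: ModelSpec, data, **kwargs) -> FitResult:
    """Fit a fitted-pattern spec to a dataset (see :func:`fit_cov`)."""
    x = _as_matrix(data)
    return fit_cov(spec, sample_cov(x), x.shape[0], **kwargs)


def saturated_loglik(S, n: int) -> float:
    """MVN log-likelihood of the saturated model (Σ̂ = S, means saturated)."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise DegeneracyError("sample covariance is not positive definite")
    return -0.5 * n * (p * LN2PI + logdet_s + p)


def fit_baseline(data_or_S, n: int | None = None, *, multiplier: str = "n") -> FitResult:
    """Closed-form fit of the independence baseline Σ = diag(S).

    Needed by the CFI; df = p(p−1)/2 and T₀ = n·[Σ ln s_ii − ln|S|].
    """
    if n is None:
        x = _as_matrix(data_or_S)
        S = sample_cov(x)
        n = x.shape[0]
    else:
        S = np.asarray(data_or_S, dtype=float)
    p = S.shape[0]
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise DegeneracyError("sample covariance is not positive definite")
    diag = np.diag(S)
    f0 = float(np.log(diag).sum() - logdet_s)
    mult = float(n) if multiplier == "n" else float(n - 1)
    loglik = -0.5 * n * (p * LN2PI + logdet_s + p) - 0.5 * n * f0
    return FitResult(
        model="baseline",
        converged=True,
        admissible=True,
        estimates=diag.copy(),
        F_ml=f0,
        loglik=loglik,
        T=mult * f0,
        df=p * (p - 1) // 2,
        q=p,
        n=n,
    )
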
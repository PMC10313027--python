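"""ARIMA(p, d, q) fitting on GAM residuals: exact likelihood, AIC order search.

The residual series is mean-zero by construction, so no intercept or drift is
estimated.  Missing values are handled inside the Kalman filter (prediction
without update); when d = 1 the series is differenced within contiguous
observed segments only, since a difference across a gap is undefined.

Estimation maximizes the exact Gaussian likelihood over partial-
autocorrelation-transformed parameters, which enforces stationarity of the
AR polynomial and invertibility of the MA polynomial by construction, with
the innovation variance profiled out in closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._kalman import filter_arma
from .errors import DomainError, NonStationaryError, SelectionError

logger = logging.getLogger(__name__)

DEFAULT_P_MAX = 5
DEFAULT_D_MAX = 1
DEFAULT_Q_MAX = 4

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ArmaSpec:
    """Model orders (p autoregressive, d differences, q moving-average)."""

    p: int
    d: int
    q: int

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0 or self.d not in (0, 1):
            raise DomainError(f"invalid ARIMA orders {(self.p, self.d, self.q)}")

    @property
    def k(self) -> int:
        """Parameter count entering the AIC penalty (+1 for sigma^2)."""
        return self.p + self.q + 1


@dataclass
class ArmaFit:
    spec: ArmaSpec
    ar_coefs: np.ndarray
    ma_coefs: np.ndarray
    sigma2: float
    loglik: float
    aic: float
    innovations: np.ndarray        # one-step prediction errors, NaN at gaps
    n_eff: int
    converged: bool = True
    degenerate: bool = False
    identifiable: bool = True
    message: str = ""
    trace: list = field(default_factory=list)
    zparams: np.ndarray | None = None  # unconstrained optimum, for warm starts

    def summary(self) -> dict:
        return {
            "order": (self.spec.p, self.spec.d, self.spec.q),
            "ar": list(np.round(self.ar_coefs, 6)),
            "ma": list(np.round(self.ma_coefs, 6)),
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_eff": self.n_eff,
            "converged": self.converged,
        }


# --------------------------------------------------------------------------
# Parameter transforms (Monahan / Jones): unconstrained <-> stationary coefs

def pacf_to_coefs(pacf: np.ndarray) -> np.ndarray:
    """Levinson-Durbin map from partial autocorrelations to AR coefficients."""
    coefs = np.zeros(0)
    for r in pacf:
        new = np.empty(len(coefs) + 1)
        new[:-1] = coefs - r * coefs[::-1]
        new[-1] = r
        coefs = new
    return coefs


def coefs_to_pacf(coefs: np.ndarray) -> np.ndarray:
    """Inverse Levinson-Durbin (requires a stationary coefficient vector)."""
    coefs = np.asarray(coefs, dtype=float).copy()
    pacf = np.zeros(len(coefs))
    for k in range(len(coefs), 0, -1):
        r = coefs[-1]
        pacf[k - 1] = r
        if abs(r) >= 1:
            raise NonStationaryError("coefficients are not stationary")
        if k > 1:
            prev = (coefs[:-1] + r * coefs[-2::-1]) / (1.0 - r * r)
            coefs = prev
    return pacf


def _unconstrained_to_coefs(z: np.ndarray) -> np.ndarray:
    return pacf_to_coefs(np.tanh(z))


def _coefs_to_unconstrained(coefs: np.ndarray) -> np.ndarray:
    pacf = np.clip(coefs_to_pacf(coefs), -0.999, 0.999)
    return np.arctanh(pacf)


def _poly_stationary(coefs: np.ndarray) -> bool:
    """True when 1 - c_1 z - ... - c_k z^k has all roots outside |z| = 1."""
    if len(coefs) == 0:
        return True
    poly = np.concatenate(([1.0], -np.asarray(coefs, dtype=float)))
    roots = np.roots(poly[::-1])
    return bool(np.all(np.abs(roots) > 1.0 + 1e-10))


#: Minimum distance between an AR and an MA root below which the two factors
#: are treated as a (non-identifiable) common factor.
CANCELLATION_TOL = 0.05


def _is_identifiable(phi: np.ndarray, theta: np.ndarray,
                     tol: float = CANCELLATION_TOL) -> bool:
    """Reject fits whose AR and MA polynomials share a near-common root.

    A near-cancelling factor pair leaves the likelihood flat along a whole
    parameter direction: the fit's nominal parameter count then overstates
    its effective dimension and its AIC is not comparable with honest fits,
    so order selection must skip it (same treatment as non-convergence).
    """
    if len(phi) == 0 or len(theta) == 0:
        return True
    ar_roots = np.roots(np.concatenate(([1.0], -phi))[::-1])
    ma_roots = np.roots(np.concatenate(([1.0], theta))[::-1])
    dist = np.abs(ar_roots[:, None] - ma_roots[None, :])
    return bool(dist.min() > tol)


# --------------------------------------------------------------------------
# Series preparation

def _prepare_series(series: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Apply within-segment differencing; return (values, observed mask)."""
    y = np.asarray(series, dtype=float)
    obs = np.isfinite(y)
    if d == 0:
        return np.where(obs, y, 0.0), obs.astype(np.uint8)
    if d != 1:
        raise DomainError("only d in {0, 1} is supported")
    z = np.full(len(y) - 1, np.nan)
    both = obs[1:] & obs[:-1]
    z[both] = y[1:][both] - y[:-1][both]
    zobs = np.isfinite(z)
    return np.where(zobs, z, 0.0), zobs.astype(np.uint8)


# --------------------------------------------------------------------------
# Likelihood

def _filter_stats(y, obs, phi, theta):
    v, Fv, nobs = filter_arma(y, obs, phi, theta)
    fin = np.isfinite(v)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        ssq = float(np.sum(v[fin] ** 2 / Fv[fin]))
        sumlogF = float(np.sum(np.log(Fv[fin])))
    return v, Fv, int(nobs), ssq, sumlogF


def arma_loglik(series: np.ndarray, spec: ArmaSpec,
                params: np.ndarray) -> float:
    """Exact Gaussian log-likelihood at explicit parameter values.

    ``params`` concatenates the AR coefficients, the MA coefficients and the
    innovation variance sigma^2 (length p + q + 1).
    """
    params = np.asarray(params, dtype=float)
    if len(params) != spec.p + spec.q + 1:
        raise DomainError(f"expected {spec.p + spec.q + 1} parameters")
    phi = params[: spec.p]
    theta = params[spec.p: spec.p + spec.q]
    sigma2 = float(params[-1])
    if sigma2 <= 0:
        raise DomainError("sigma^2 must be positive")
    if not _poly_stationary(phi):
        raise NonStationaryError("AR polynomial has a root inside the unit circle")
    if not _poly_stationary(-np.asarray(theta)):
        # invertibility: 1 + t_1 z + ... must have roots outside the circle
        raise NonStationaryError("MA polynomial is not invertible")

    y, obs = _prepare_series(series, spec.d)
    if int(obs.sum()) <= spec.p + spec.q:
        raise DomainError("series too short for the requested orders")
    _, _, nobs, ssq, sumlogF = _filter_stats(y, obs, phi, theta)
    return -0.5 * (nobs * _LOG2PI + sumlogF + nobs * np.log(sigma2)
                   + ssq / sigma2)


# --------------------------------------------------------------------------
# Fitting

def fit_arma(series: np.ndarray, spec: ArmaSpec,
             maxiter: int = 100,
             starts: list[np.ndarray] | None = None) -> ArmaFit:
    """Maximum-likelihood ARIMA fit with profiled innovation variance.

    Deterministic: fixed starting values (zeros, plus a Yule-Walker-style
    start for the AR part, or the caller-supplied ``starts`` on the
    unconstrained scale) and fixed optimizer settings.  A fit that fails to
    converge is returned flagged so order selection can skip it.
    """
    y, obs = _prepare_series(series, spec.d)
    n_eff = int(obs.sum())
    if n_eff <= spec.p + spec.q + 1:
        raise DomainError("series too short for the requested orders")

    yobs = y[obs.astype(bool)]
    if float(np.var(yobs)) < 1e-14:
        innov = np.full(len(y), np.nan)
        innov[obs.astype(bool)] = 0.0
        return ArmaFit(spec=spec, ar_coefs=np.zeros(spec.p),
                       ma_coefs=np.zeros(spec.q), sigma2=0.0,
                       loglik=np.nan, aic=np.inf, innovations=innov,
                       n_eff=n_eff, converged=False, degenerate=True,
                       message="series is (numerically) constant")

    p, q = spec.p, spec.q

    def neg_profiled(z: np.ndarray) -> float:
        phi = _unconstrained_to_coefs(z[:p])
        # minus sign: the transform makes 1 - sum(c_l z^l) stationary, and
        # theta = -c then makes 1 + sum(theta_l z^l) invertible
        theta = -_unconstrained_to_coefs(z[p:])
        _, _, nobs, ssq, sumlogF = _filter_stats(y, obs, phi, theta)
        sigma2 = max(ssq / nobs, 1e-300)
        val = 0.5 * (nobs * _LOG2PI + sumlogF + nobs * np.log(sigma2) + nobs)
        if not np.isfinite(val):
            return 1e12
        return val

    if p + q == 0:
        z_hat = np.zeros(0)
        converged = True
        message = "closed form"
    else:
        if starts is None:
            starts = [np.zeros(p + q)]
            try:
                pac = _sample_pacf(yobs, p)
                z0 = np.zeros(p + q)
                z0[:p] = np.arctanh(np.clip(pac, -0.95, 0.95))
                starts.append(z0)
            except Exception:  # degenerate ACF; zero start still stands
                pass
        # |z| <= 6 keeps every partial autocorrelation below tanh(6) ~ 0.99999,
        # away from the numerically explosive unit-root boundary
        bounds = [(-6.0, 6.0)] * (p + q)
        best = None
        for z0 in starts:
            res = minimize(neg_profiled,
                           np.clip(np.asarray(z0, dtype=float), -6.0, 6.0),
                           method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": maxiter, "ftol": 1e-9})
            if best is None or res.fun < best.fun:
                best = res
        z_hat = best.x
        converged = bool(best.success)
        message = str(best.message)

    phi = _unconstrained_to_coefs(z_hat[:p])
    theta = -_unconstrained_to_coefs(z_hat[p:])
    v, Fv, nobs, ssq, sumlogF = _filter_stats(y, obs, phi, theta)
    sigma2 = ssq / nobs
    loglik = -0.5 * (nobs * _LOG2PI + sumlogF + nobs * np.log(max(sigma2, 1e-300))
                     + nobs)
    aic = -2.0 * loglik + 2.0 * spec.k
    return ArmaFit(spec=spec, ar_coefs=phi, ma_coefs=theta,
                   sigma2=float(sigma2), loglik=float(loglik),
                   aic=float(aic), innovations=v, n_eff=nobs,
                   converged=converged, identifiable=_is_identifiable(phi, theta),
                   message=message, zparams=z_hat)


def _sample_pacf(y: np.ndarray, nlags: int) -> np.ndarray:
    """Sample partial autocorrelations via Levinson-Durbin on the sample ACF."""
    if nlags == 0:
        return np.zeros(0)
    n = len(y)
    yc = y - y.mean()
    denom = float(yc @ yc)
    acf = np.array([float(yc[k:] @ yc[: n - k]) / denom
                    for k in range(nlags + 1)])
    pacf = np.zeros(nlags)
    phi_prev = np.zeros(0)
    for k in range(1, nlags + 1):
        if k == 1:
            r = acf[1]
        else:
            num = acf[k] - phi_prev @ acf[1:k][::-1]
            den = 1.0 - phi_prev @ acf[1:k]
            r = num / den if abs(den) > 1e-12 else 0.0
        pacf[k - 1] = r
        phi = np.empty(k)
        phi[: k - 1] = phi_prev - r * phi_prev[::-1]
        phi[-1] = r
        phi_prev = phi
    return np.clip(pacf, -0.99, 0.99)


# --------------------------------------------------------------------------
# Order selection

class _OrderSearch:
    """Shared fit cache and bookkeeping for the order search strategies."""

    def __init__(self, series: np.ndarray):
        self.series = series
        self.fits: dict[tuple, ArmaFit | None] = {}
        self.failures: dict[tuple, str] = {}
        self.z_cache: dict[tuple, np.ndarray] = {}

    def fit(self, p: int, d: int, q: int) -> ArmaFit | None:
        key = (p, d, q)
        if key in self.fits:
            return self.fits[key]
        starts = None
        if p + q > 0:
            starts = []
            prev = self.z_cache.get((p - 1, d, q))
            if prev is not None:
                starts.append(np.concatenate(
                    [prev[: p - 1], [0.0], prev[p - 1:]]))
            prev = self.z_cache.get((p, d, q - 1))
            if prev is not None:
                starts.append(np.concatenate([prev, [0.0]]))
            if not starts:
                starts = None  # fall back to the default cold starts
        try:
            fit = fit_arma(self.series, ArmaSpec(p, d, q), starts=starts)
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            self.failures[key] = f"{type(exc).__name__}: {exc}"
            self.fits[key] = None
            return None
        if fit.zparams is not None:
            self.z_cache[key] = fit.zparams
        if fit.degenerate or not np.isfinite(fit.aic):
            self.failures[key] = fit.message or "degenerate"
            fit = None
        elif not fit.converged:
            self.failures[key] = f"non-convergence: {fit.message}"
            fit = None
        elif not fit.identifiable:
            self.failures[key] = "near-cancelling AR/MA roots"
            fit = None
        self.fits[key] = fit
        return fit


def select_arma_order(
    series: np.ndarray,
    p_max: int = DEFAULT_P_MAX,
    d_max: int = DEFAULT_D_MAX,
    q_max: int = DEFAULT_Q_MAX,
    search: str = "stepwise",
) -> ArmaFit:
    """AIC order selection over p in 0..p_max, d in 0..d_max, q in 0..q_max.

    ``search="stepwise"`` (default) runs, within each d, a deterministic
    local search in (p, q): start from the AIC-best of a small seed set,
    then repeatedly move to the best AIC-improving neighbour (p and q each
    changed by at most one) until no move improves; the per-d winners are
    then compared.  This mirrors common ARIMA auto-selection practice and
    avoids the spurious large near-cancelling fits an exhaustive scan is
    prone to reward on weakly autocorrelated series.

    ``search="exhaustive"`` scans the full grid.

    Either way the result is the converged, identifiable fit with minimal
    AIC among those visited; ties break toward smaller p + q, then smaller
    q.  Degenerate, non-converged and non-identifiable fits are excluded;
    if every visited cell fails, :class:`SelectionError` carries the
    per-cell diagnostics.
    """
    if p_max < 0 or d_max < 0 or q_max < 0:
        raise DomainError("grid bounds must be non-negative")
    if search not in ("stepwise", "exhaustive"):
        raise ValueError(f"unknown search strategy {search!r}")
    state = _OrderSearch(np.asarray(series, dtype=float))
    d_max = min(d_max, 1)

    key = lambda f: (f.aic, f.spec.p + f.spec.q, f.spec.q, f.spec.p)  # noqa: E731

    visited: list[ArmaFit] = []
    if search == "exhaustive":
        for d in range(d_max + 1):
            for p in range(p_max + 1):
                for q in range(q_max + 1):
                    fit = state.fit(p, d, q)
                    if fit is not None:
                        visited.append(fit)
    else:
        for d in range(d_max + 1):
            seeds = [(min(2, p_max), d, min(2, q_max)), (0, d, 0)]
            if p_max >= 1:
                seeds.append((1, d, 0))
            if q_max >= 1:
                seeds.append((0, d, 1))
            seed_fits = [f for s in dict.fromkeys(seeds)
                         if (f := state.fit(*s)) is not None]
            visited.extend(seed_fits)
            if not seed_fits:
                continue
            current = min(seed_fits, key=key)
            while True:
                p, q = current.spec.p, current.spec.q
                best_move = None
                for dp in (-1, 0, 1):
                    for dq in (-1, 0, 1):
                        if dp == dq == 0:
                            continue
                        np_, nq = p + dp, q + dq
                        if not (0 <= np_ <= p_max and 0 <= nq <= q_max):
                            continue
                        fit = state.fit(np_, d, nq)
                        if fit is None:
                            continue
                        visited.append(fit)
                        if fit.aic < current.aic - 1e-9 and (
                                best_move is None or key(fit) < key(best_move)):
                            best_move = fit
                if best_move is None:
                    break
                current = best_move

    if not visited:
        raise SelectionError(f"all ARIMA fits failed: {state.failures}")
    best = min(visited, key=key)
    best.trace = sorted({(f.spec, f.aic) for f in visited},
                        key=lambda t: t[1])
    if state.failures:
        logger.info("select_arma_order: %d cells excluded",
                    len(state.failures))
    return best
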
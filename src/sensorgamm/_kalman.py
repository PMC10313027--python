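"""Exact Gaussian ARMA likelihood via a Kalman filter with missing support.

State-space form (Hamilton): state is the AR companion vector of dimension
r = max(p, q + 1); the observation row is [1, theta_1, ..., theta_q, 0, ...].
The filter starts from the exact stationary state covariance (discrete
Lyapunov solve) so the likelihood is the exact joint Gaussian density.
Missing observations skip the update step (prediction only) and contribute
nothing to the likelihood.

Innovation variance enters only as a scale: the filter runs with unit
innovation variance and returns the scaled prediction errors v_t and their
variances F_t, from which the profiled sigma^2 and the log-likelihood at any
sigma^2 follow in closed form.

For speed the filter switches to a steady-state recursion (constant gain)
once the prediction-error variance has converged, falling back to full
covariance updates whenever a missing observation perturbs the covariance.
The kernel is jitted with numba when available; a pure-Python fallback keeps
the package importable (slowly) without it.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def _stationary_cov(F: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Solve P = F P F' + Q via the vectorized linear system."""
    r = F.shape[0]
    A = np.eye(r * r)
    for i in range(r):
        for j in range(r):
            for k in range(r):
                for l in range(r):
                    A[i * r + j, k * r + l] -= F[i, k] * F[j, l]
    vec = np.linalg.solve(A, Q.ravel().copy())
    return vec.reshape((r, r))


@njit(cache=True)
def filter_arma(y: np.ndarray, obs: np.ndarray, phi: np.ndarray,
                theta: np.ndarray):
    """Run the filter at unit innovation variance.

    Parameters
    ----------
    y : observation vector (any values at non-observed slots)
    obs : uint8 mask, 1 = observed
    phi, theta : AR and MA coefficients

    Returns
    -------
    v : prediction errors (NaN where not observed)
    Fv : prediction-error variances (NaN where not observed)
    nobs : number of observed points
    """
    p = phi.shape[0]
    q = theta.shape[0]
    r = max(p, q + 1)
    n = y.shape[0]

    F = np.zeros((r, r))
    for i in range(p):
        F[0, i] = phi[i]
    for i in range(r - 1):
        F[i + 1, i] = 1.0

    Z = np.zeros(r)
    Z[0] = 1.0
    for i in range(q):
        Z[i + 1] = theta[i]

    Q = np.zeros((r, r))
    Q[0, 0] = 1.0

    a = np.zeros(r)                 # updated state a_{t|t}
    P = _stationary_cov(F, Q)       # updated covariance P_{t|t} (t = 0)

    a_pred = np.zeros(r)
    Pp = np.zeros((r, r))
    FP = np.zeros((r, r))
    PZ = np.zeros(r)
    K = np.zeros(r)

    v = np.full(n, np.nan)
    Fv = np.full(n, np.nan)
    nobs = 0

    steady = False
    Ft_prev = -1.0
    n_same = 0
    Ft = 1.0

    for t in range(n):
        # ---- predict: a_pred = F a ; Pp = F P F' + Q
        for i in range(r):
            s = 0.0
            for j in range(r):
                s += F[i, j] * a[j]
            a_pred[i] = s
        if not steady:
            for i in range(r):
                for j in range(r):
                    s = 0.0
                    for k in range(r):
                        s += F[i, k] * P[k, j]
                    FP[i, j] = s
            for i in range(r):
                for j in range(r):
                    s = 0.0
                    for k in range(r):
                        s += FP[i, k] * F[j, k]
                    Pp[i, j] = s
            Pp[0, 0] += 1.0

        if obs[t]:
            if not steady:
                for i in range(r):
                    s = 0.0
                    for j in range(r):
                        s += Pp[i, j] * Z[j]
                    PZ[i] = s
                Ft = 0.0
                for i in range(r):
                    Ft += Z[i] * PZ[i]
                if Ft < 1e-300:
                    Ft = 1e-300
                for i in range(r):
                    K[i] = PZ[i] / Ft
            za = 0.0
            for i in range(r):
                za += Z[i] * a_pred[i]
            vt = y[t] - za
            v[t] = vt
            Fv[t] = Ft
            nobs += 1
            for i in range(r):
                a[i] = a_pred[i] + K[i] * vt
            if not steady:
                # P = Pp - K (PZ)'
                for i in range(r):
                    for j in range(r):
                        P[i, j] = Pp[i, j] - K[i] * PZ[j]
                for i in range(r):
                    for j in range(i + 1, r):
                        m = 0.5 * (P[i, j] + P[j, i])
                        P[i, j] = m
                        P[j, i] = m
                # steady-state detection on consecutive identical Ft
                if Ft_prev > 0.0 and abs(Ft - Ft_prev) < 1e-12 * Ft:
                    n_same += 1
                    if n_same >= 3:
                        steady = True
                else:
                    n_same = 0
                Ft_prev = Ft
        else:
            for i in range(r):
                a[i] = a_pred[i]
            if steady:
                # covariance must evolve again; P currently holds the
                # steady updated covariance, so resume full updates
                steady = False
                Ft_prev = -1.0
                n_same = 0
                for i in range(r):
                    for j in range(r):
                        s = 0.0
                        for k in range(r):
                            s += F[i, k] * P[k, j]
                        FP[i, j] = s
                for i in range(r):
                    for j in range(r):
                        s = 0.0
                        for k in range(r):
                            s += FP[i, k] * F[j, k]
                        Pp[i, j] = s
                Pp[0, 0] += 1.0
            for i in range(r):
                for j in range(r):
                    P[i, j] = Pp[i, j]
    return v, Fv, nobs
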
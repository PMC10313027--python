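"""Penalized univariate spline smooths and the additive (GAM) stage.

Each covariate enters through a low-rank natural-cubic ("thin-plate-type" in
one dimension) spline basis with an exact curvature penalty — the integrated
squared second derivative of the interpolating natural spline.  The basis is
built with ``max_df + 1`` knots at quantiles of the observed covariate and a
sum-to-zero centering constraint, so the maximum attainable effective degrees
of freedom per smooth is exactly ``max_df`` (default 6) and the penalty null
space after centering is the straight line: infinite smoothing collapses a
term to ordinary linear regression, it never removes it.

Smoothing parameters are selected by minimizing the Gaussian AIC

    AIC = n * log(rss / n) + 2 * (edf_total + 1)

with ``edf_total = trace`` of the influence matrix (intercept included), by a
bounded search on each log-lambda, cycled to convergence.  Variable selection
is bidirectional stepwise over whole smooth terms under the same criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve
from scipy.optimize import minimize_scalar

from .errors import CollinearityError, DegenerateCovariateError
from .io import AlignedDataset

logger = logging.getLogger(__name__)

DEFAULT_MAX_DF = 6

_LOG_LAMBDA_LO = -12.0
_LOG_LAMBDA_HI = 16.0


# --------------------------------------------------------------------------
# Natural cubic spline machinery (Green & Silverman parameterization)

def _ncs_system(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Second-difference matrix D ((K-2) x K) and Gram matrix W of the
    natural cubic spline so that the curvature penalty is g' D^T W^-1 D g."""
    h = np.diff(knots)
    K = len(knots)
    D = np.zeros((K - 2, K))
    W = np.zeros((K - 2, K - 2))
    for i in range(K - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        W[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < K - 3:
            W[i, i + 1] = W[i + 1, i] = h[i + 1] / 6.0
    return D, W


def _ncs_eval_matrix(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Matrix M with f(x) = M @ g for the natural cubic spline interpolating
    values g at ``knots``; linear extrapolation beyond the boundary knots."""
    x = np.asarray(x, dtype=float)
    K = len(knots)
    h = np.diff(knots)
    D, W = _ncs_system(knots)
    G = solve(W, D, assume_a="pos")  # interior second derivatives = G @ g

    n = len(x)
    M = np.zeros((n, K))
    C = np.zeros((n, K))  # weights on the *full* gamma vector (ends are 0)

    inside = (x >= knots[0]) & (x <= knots[-1])
    left = x < knots[0]
    right = x > knots[-1]

    if inside.any():
        xi = x[inside]
        i = np.clip(np.searchsorted(knots, xi, side="right") - 1, 0, K - 2)
        hi = h[i]
        a = (knots[i + 1] - xi) / hi          # weight on g_i
        b = (xi - knots[i]) / hi              # weight on g_{i+1}
        rows = np.nonzero(inside)[0]
        np.add.at(M, (rows, i), a)
        np.add.at(M, (rows, i + 1), b)
        prod = (xi - knots[i]) * (knots[i + 1] - xi) / 6.0
        np.add.at(C, (rows, i), -prod * (1.0 + a))
        np.add.at(C, (rows, i + 1), -prod * (1.0 + b))

    if left.any():
        # f(t) = g_0 + (t - s_0) * f'(s_0),  f'(s_0) = (g_1-g_0)/h_0 - h_0*gamma_1/6
        t = x[left] - knots[0]
        rows = np.nonzero(left)[0]
        np.add.at(M, (rows, np.zeros(len(rows), dtype=int)), 1.0 - t / h[0])
        np.add.at(M, (rows, np.ones(len(rows), dtype=int)), t / h[0])
        np.add.at(C, (rows, np.ones(len(rows), dtype=int)), -t * h[0] / 6.0)

    if right.any():
        t = x[right] - knots[-1]
        rows = np.nonzero(right)[0]
        np.add.at(M, (rows, np.full(len(rows), K - 2)), -t / h[-1])
        np.add.at(M, (rows, np.full(len(rows), K - 1)), 1.0 + t / h[-1])
        np.add.at(C, (rows, np.full(len(rows), K - 2)), t * h[-1] / 6.0)

    # fold the gamma dependence back onto g (interior gammas only)
    M += C[:, 1:K - 1] @ G
    return M


def _ncs_penalty(knots: np.ndarray) -> np.ndarray:
    """Exact curvature penalty: integral of the squared second derivative."""
    D, W = _ncs_system(knots)
    S = D.T @ solve(W, D, assume_a="pos")
    return (S + S.T) / 2.0


# --------------------------------------------------------------------------
# Basis construction

@dataclass
class SmoothBasis:
    """Centered penalized spline basis for one covariate.

    ``design`` holds the centered design at the training data (columns sum
    to zero exactly); ``penalty`` is the matching PSD curvature penalty,
    scaled so its Frobenius norm equals that of the design's Gram matrix
    (keeps lambda searches comparable across covariates and makes fitted
    values invariant to affine covariate rescaling).
    """

    name: str
    knots: np.ndarray
    constraint: np.ndarray          # K x (K-1) null basis of the centering constraint
    design: np.ndarray              # n x (K-1)
    penalty: np.ndarray             # (K-1) x (K-1), PSD, scaled
    penalty_scale: float
    x_min: float
    x_max: float
    max_df: int

    @property
    def dim(self) -> int:
        return self.design.shape[1]

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Centered basis evaluated at new covariate values."""
        return _ncs_eval_matrix(np.asarray(x, dtype=float), self.knots) @ self.constraint


def build_smooth_basis(x: np.ndarray, max_df: int = DEFAULT_MAX_DF,
                       name: str = "") -> SmoothBasis:
    """Build the rank-``max_df + 1`` centered spline basis for covariate x.

    Knots sit at quantiles of the distinct observed values.  Requires at
    least ``max_df + 2`` distinct values.  After the sum-to-zero constraint
    the basis has ``max_df`` columns, its penalty has a one-dimensional null
    space (the centered straight line) and the maximum attainable effective
    df is exactly ``max_df``.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    ux = np.unique(x)
    K = max_df + 1
    if ux.size < max_df + 2:
        raise DegenerateCovariateError(
            f"covariate {name!r}: {ux.size} distinct values, "
            f"need at least {max_df + 2}"
        )
    idx = np.round(np.linspace(0, ux.size - 1, K)).astype(int)
    knots = ux[idx]

    N = _ncs_eval_matrix(x, knots)           # n x K
    S = _ncs_penalty(knots)                  # K x K

    # sum-to-zero over the data: c^T g = 0 with c the column sums of N
    c = N.sum(axis=0)
    # Householder-style null basis via QR of c
    Q, _ = np.linalg.qr(c[:, None], mode="complete")
    Z = Q[:, 1:]                             # K x (K-1)

    Xc = N @ Z
    Xc = Xc - Xc.mean(axis=0)                # exact zero column sums (roundoff)
    Sc = Z.T @ S @ Z
    Sc = (Sc + Sc.T) / 2.0

    gram = Xc.T @ Xc
    s_norm = np.linalg.norm(Sc)
    scale = float(np.linalg.norm(gram) / s_norm) if s_norm > 0 else 1.0
    return SmoothBasis(name=name, knots=knots, constraint=Z, design=Xc,
                       penalty=Sc * scale, penalty_scale=scale,
                       x_min=float(x.min()), x_max=float(x.max()),
                       max_df=max_df)


# --------------------------------------------------------------------------
# Penalized additive fit

@dataclass
class SmoothTerm:
    basis: SmoothBasis
    coefficients: np.ndarray
    lam: float
    edf: float

    @property
    def name(self) -> str:
        return self.basis.name


@dataclass
class GamFit:
    """Fitted additive model on the complete-case rows of a dataset."""

    intercept: float
    terms: dict[str, SmoothTerm]
    rows: np.ndarray                     # boolean mask into the source grid
    fitted: np.ndarray
    residuals: np.ndarray
    rss: float
    tss: float
    edf_total: float
    aic: float
    deviance_explained: float
    n: int
    sigma2: float
    coef_cov: np.ndarray
    slices: dict[str, slice]
    trace: list = field(default_factory=list)

    @property
    def term_names(self) -> list[str]:
        return list(self.terms)

    def residuals_on_grid(self, n_grid: int) -> np.ndarray:
        """Residual series on the full grid, NaN at unused rows."""
        out = np.full(n_grid, np.nan)
        out[self.rows] = self.residuals
        return out


class _PenalizedDesign:
    """Precomputed cross-products for fast lambda search."""

    def __init__(self, y: np.ndarray, bases: Sequence[SmoothBasis]):
        n = len(y)
        self.n = n
        self.ybar = float(y.mean())
        yc = y - self.ybar
        cols = [np.ones((n, 1))] + [b.design for b in bases]
        self.X = np.hstack(cols)
        self.p = self.X.shape[1]
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ yc
        self.yty = float(yc @ yc)
        self.tss = self.yty
        self.bases = list(bases)
        self.slices: dict[str, slice] = {}
        start = 1
        for b in bases:
            self.slices[b.name] = slice(start, start + b.dim)
            start += b.dim

    def solve(self, lams: np.ndarray):
        """Penalized LS at the given lambda vector.

        Returns (beta, rss, edf_by_term, edf_total, chol) or raises
        CollinearityError if the penalized normal matrix is singular.
        """
        A = self.XtX.copy()
        for lam, b in zip(lams, self.bases):
            sl = self.slices[b.name]
            A[sl, sl] += lam * b.penalty
        try:
            chol = cho_factor(A, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
            raise CollinearityError(
                "singular penalized design; run vif_screen on the candidates"
            ) from exc
        beta = cho_solve(chol, self.Xty)
        rss = max(self.yty - 2.0 * beta @ self.Xty + beta @ self.XtX @ beta, 0.0)
        # influence matrix trace: diag of A^-1 XtX, blockwise
        B = cho_solve(chol, self.XtX)
        diag = np.diag(B)
        edf_by_term = {name: float(diag[sl].sum())
                       for name, sl in self.slices.items()}
        edf_total = float(diag.sum())
        return beta, rss, edf_by_term, edf_total, chol

    def aic(self, lams: np.ndarray) -> float:
        _, rss, _, edf_total, _ = self.solve(lams)
        rss = max(rss, 1e-300)
        return self.n * np.log(rss / self.n) + 2.0 * (edf_total + 1.0)


def fit_penalized_gam(
    data: AlignedDataset,
    terms: Sequence[str],
    max_df: int = DEFAULT_MAX_DF,
    rows: np.ndarray | None = None,
    lambdas: dict[str, float] | None = None,
    aic_tol: float = 1e-6,
    max_cycles: int = 50,
) -> GamFit:
    """Fit the additive model with AIC-selected smoothing parameters.

    ``rows`` restricts the fit to a caller-chosen complete-case mask (the
    stepwise search passes the mask of the full candidate set so AICs stay
    comparable across sub-models).  ``lambdas`` pins smoothing parameters
    instead of optimizing them (used by oracle tests for the linear limit).
    """
    terms = list(terms)
    if rows is None:
        rows = data.complete_rows(terms)
    rows = np.asarray(rows, dtype=bool)
    y = data.response[rows]
    n = len(y)
    if n < 2:
        raise DegenerateCovariateError("fewer than two complete rows")

    bases = [
        build_smooth_basis(data.covariates[t].to_numpy(dtype=float)[rows],
                           max_df=max_df, name=t)
        for t in terms
    ]
    budget = 1 + max_df * len(bases)
    if n <= budget:
        raise DegenerateCovariateError(
            f"{n} complete rows cannot support an edf budget of {budget}"
        )

    design = _PenalizedDesign(y, bases)

    if terms:
        if lambdas is not None:
            lams = np.array([float(lambdas[t]) for t in terms])
        else:
            lams = np.ones(len(terms))
            prev_aic = np.inf
            for _ in range(max_cycles):
                for k in range(len(terms)):
                    def objective(loglam: float, k: int = k) -> float:
                        trial = lams.copy()
                        trial[k] = np.exp(loglam)
                        return design.aic(trial)

                    res = minimize_scalar(
                        objective, bounds=(_LOG_LAMBDA_LO, _LOG_LAMBDA_HI),
                        method="bounded", options={"xatol": 1e-3},
                    )
                    lams[k] = np.exp(res.x)
                cur_aic = design.aic(lams)
                if abs(prev_aic - cur_aic) < aic_tol * (abs(cur_aic) + 1.0):
                    break
                prev_aic = cur_aic
    else:
        lams = np.zeros(0)

    beta, rss, edf_by_term, edf_total, chol = design.solve(lams)
    fitted = design.X @ beta + design.ybar
    residuals = y - fitted
    rss_direct = float(residuals @ residuals)
    tss = design.tss
    dev = 100.0 * (1.0 - rss_direct / tss) if tss > 0 else 0.0
    aic = n * np.log(max(rss_direct, 1e-300) / n) + 2.0 * (edf_total + 1.0)
    sigma2 = rss_direct / max(n - edf_total, 1.0)
    coef_cov = sigma2 * cho_solve(chol, np.eye(design.p))

    fit_terms = {
        b.name: SmoothTerm(basis=b,
                           coefficients=beta[design.slices[b.name]].copy(),
                           lam=float(lam), edf=edf_by_term[b.name])
        for b, lam in zip(bases, lams)
    }
    return GamFit(
        intercept=float(beta[0] + design.ybar),
        terms=fit_terms,
        rows=rows,
        fitted=fitted,
        residuals=residuals,
        rss=rss_direct,
        tss=tss,
        edf_total=edf_total,
        aic=float(aic),
        deviance_explained=float(dev),
        n=n,
        sigma2=float(sigma2),
        coef_cov=coef_cov,
        slices=dict(design.slices),
    )


# --------------------------------------------------------------------------
# Stepwise selection

def stepwise_select_gam(
    data: AlignedDataset,
    candidates: Sequence[str],
    max_df: int = DEFAULT_MAX_DF,
) -> GamFit:
    """Bidirectional stepwise selection of smooth terms by AIC.

    Starts from the full candidate set; at each step evaluates every
    single-term addition or removal and accepts the move with the lowest
    AIC provided it strictly lowers the current AIC.  Ties are broken by
    candidate-list order.  The returned fit carries the selection trace as
    ``fit.trace`` (list of ``(term_tuple, aic)``).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate")
    rows = data.complete_rows(candidates)

    cache: dict[tuple, GamFit] = {}

    def fit_for(subset: tuple) -> GamFit:
        if subset not in cache:
            cache[subset] = fit_penalized_gam(data, list(subset),
                                              max_df=max_df, rows=rows)
        return cache[subset]

    current = tuple(candidates)
    best = fit_for(current)
    trace: list[tuple[tuple, float]] = [(current, best.aic)]

    while True:
        moves: list[tuple] = []
        for c in candidates:
            if c in current:
                moves.append(tuple(t for t in current if t != c))
            else:
                moves.append(tuple(t for t in candidates
                                   if t in current or t == c))
        best_move = None
        best_aic = best.aic
        for mv in moves:
            f = fit_for(mv)
            if f.aic < best_aic:
                best_aic = f.aic
                best_move = mv
        if best_move is None:
            break
        current = best_move
        best = fit_for(current)
        trace.append((current, best.aic))
        logger.info("stepwise: -> %s (AIC=%.3f)", list(current), best.aic)

    best.trace = trace
    return best


# --------------------------------------------------------------------------
# Partial effects

def evaluate_partial_effects(fit: GamFit, grid_points: int = 100) -> pd.DataFrame:
    """Tabulate each smooth and its standard error on an even covariate grid.

    Returns a long-format frame with columns ``covariate, value, effect,
    se``.  Effects are centered so that they average zero over the training
    data; standard errors come from the penalized-fit coefficient
    covariance.
    """
    if grid_points < 2:
        raise ValueError("grid_points must be at least 2")
    frames = []
    for name, term in fit.terms.items():
        b = term.basis
        xg = np.linspace(b.x_min, b.x_max, grid_points)
        Xg = b.evaluate(xg)
        effect = Xg @ term.coefficients
        V = fit.coef_cov[fit.slices[name], fit.slices[name]]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, V, Xg), 0.0))
        frames.append(pd.DataFrame({"covariate": name, "value": xg,
                                    "effect": effect, "se": se}))
    if not frames:
        return pd.DataFrame(columns=["covariate", "value", "effect", "se"])
    return pd.concat(frames, ignore_index=True)
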
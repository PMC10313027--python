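"""Two-step GAMM: additive stage + ARMA errors, aAIC, and variable importance.

Conventions fixed here (and echoed into reports):

* ``aaic(n, sigma2, k) = n * ln(sigma2) + 2 * k``.
* ``k_total = gam.edf_total + p + q`` — intercept counted inside the GAM's
  effective degrees of freedom; sigma^2 itself not counted.
* Total deviance explained is measured against the response's total sum of
  squares about its mean, with the GAMM's residual sum of squares taken as
  the sum of squared one-step-ahead innovations (n_eff * sigma2_hat).
* Importance refits keep the full model's ARIMA orders (coefficients
  re-estimated) and the full model's selected smooth set minus one term,
  with smoothing parameters re-optimized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .arma import (
    DEFAULT_D_MAX,
    DEFAULT_P_MAX,
    DEFAULT_Q_MAX,
    ArmaFit,
    ArmaSpec,
    fit_arma,
    select_arma_order,
)
from .errors import DomainError
from .io import AlignedDataset
from .smooth import DEFAULT_MAX_DF, GamFit, fit_penalized_gam, stepwise_select_gam

logger = logging.getLogger(__name__)

AR_SHARE_LABEL = "autoregressive"


def aaic(n: int, sigma2: float, k: float) -> float:
    """Approximate AIC: ``n * ln(sigma^2) + 2 * k``."""
    if n < 1:
        raise DomainError("n must be at least 1")
    if sigma2 <= 0:
        raise DomainError("sigma^2 must be positive")
    if k < 0:
        raise DomainError("k must be non-negative")
    return n * math.log(sigma2) + 2.0 * k


@dataclass
class GammFit:
    """Joint result of the two modelling stages."""

    gam: GamFit
    arma: ArmaFit
    k_total: float
    aaic: float
    total_deviance_explained: float
    n: int

    @property
    def covariate_names(self) -> list[str]:
        return self.gam.term_names


def _total_deviance(gam: GamFit, arma: ArmaFit) -> float:
    ss_innov = arma.n_eff * arma.sigma2
    return 100.0 * (1.0 - ss_innov / gam.tss)


def _combine(gam: GamFit, arma: ArmaFit) -> GammFit:
    k_total = gam.edf_total + arma.spec.p + arma.spec.q
    # a numerically perfect fit has sigma2 -> 0; clamp so the aAIC stays
    # defined (it is then a huge negative number, as it should be)
    sigma2 = max(arma.sigma2, np.finfo(float).tiny)
    return GammFit(
        gam=gam,
        arma=arma,
        k_total=float(k_total),
        aaic=aaic(gam.n, sigma2, k_total),
        total_deviance_explained=_total_deviance(gam, arma),
        n=gam.n,
    )


def fit_gamm_two_step(
    data: AlignedDataset,
    candidates: Sequence[str],
    arma_grid: tuple[int, int, int] = (DEFAULT_P_MAX, DEFAULT_D_MAX, DEFAULT_Q_MAX),
    max_df: int = DEFAULT_MAX_DF,
    stepwise: bool = True,
) -> GammFit:
    """Step one: AIC-stepwise GAM.  Step two: AIC-selected ARIMA on residuals."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate covariate")
    if stepwise:
        gam = stepwise_select_gam(data, candidates, max_df=max_df)
    else:
        gam = fit_penalized_gam(data, candidates, max_df=max_df)
    residuals = gam.residuals_on_grid(data.n)
    p_max, d_max, q_max = arma_grid
    if float(np.nanvar(residuals)) < 1e-14:
        # perfect GAM fit: nothing left for the ARMA stage to model
        arma = fit_arma(residuals, ArmaSpec(0, 0, 0))
    else:
        arma = select_arma_order(residuals, p_max=p_max, d_max=d_max,
                                 q_max=q_max)
    fit = _combine(gam, arma)
    logger.info(
        "two-step fit: terms=%s ARIMA%s total deviance=%.2f%% aAIC=%.1f",
        gam.term_names, (arma.spec.p, arma.spec.d, arma.spec.q),
        fit.total_deviance_explained, fit.aaic,
    )
    return fit


def compare_gam_gamm(gamm: GammFit) -> pd.DataFrame:
    """Side-by-side aAIC and deviance explained for the two stages.

    The GAM row uses the variance of the GAM residuals as sigma^2 and the
    GAM's effective degrees of freedom as k; both rows use the same n so
    the comparison is internally consistent.
    """
    gam = gamm.gam
    sigma2_gam = gam.rss / gam.n
    rows = [
        {
            "model": "GAM",
            "aaic": aaic(gam.n, sigma2_gam, gam.edf_total),
            "deviance_explained": gam.deviance_explained,
            "sigma2": sigma2_gam,
            "k": gam.edf_total,
        },
        {
            "model": "GAMM",
            "aaic": gamm.aaic,
            "deviance_explained": gamm.total_deviance_explained,
            "sigma2": gamm.arma.sigma2,
            "k": gamm.k_total,
        },
    ]
    return pd.DataFrame(rows)


class ImportanceTable:
    """Leave-one-covariate-out importance, in percentage points of deviance.

    Indexing by a covariate name that was absent from the full model raises
    ``KeyError`` (an undefined importance is an error, not zero).
    """

    def __init__(self, values: dict[str, float], ar_share: float):
        self._values = dict(values)
        self.ar_share = float(ar_share)

    def __getitem__(self, name: str) -> float:
        if name == AR_SHARE_LABEL:
            return self.ar_share
        if name not in self._values:
            raise KeyError(
                f"{name!r} was not a covariate of the full model; "
                "its importance is undefined"
            )
        return self._values[name]

    def __contains__(self, name: str) -> bool:
        return name in self._values

    @property
    def covariates(self) -> list[str]:
        return list(self._values)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"component": k, "importance": v}
                for k, v in self._values.items()]
        rows.append({"component": AR_SHARE_LABEL, "importance": self.ar_share})
        df = pd.DataFrame(rows)
        return df.sort_values("importance", ascending=False,
                              kind="stable").reset_index(drop=True)


def variable_importance(data: AlignedDataset, full: GammFit,
                        max_df: int | None = None) -> ImportanceTable:
    """Drop each covariate in turn and measure the loss in total deviance.

    Each reduced model keeps the full model's remaining smooth terms
    (lambdas re-optimized) and the full model's ARIMA orders (coefficients
    re-estimated), so the difference isolates the covariate's contribution.
    The autoregressive share is the gap between the GAMM's total deviance
    and the GAM stage's deviance.
    """
    names = full.gam.term_names
    if not names:
        raise ValueError("full model has no covariates")
    if max_df is None:
        max_df = next(iter(full.gam.terms.values())).basis.max_df

    values: dict[str, float] = {}
    for name in names:
        remaining = [t for t in names if t != name]
        reduced_gam = fit_penalized_gam(data, remaining, max_df=max_df,
                                        rows=full.gam.rows)
        reduced_res = reduced_gam.residuals_on_grid(data.n)
        reduced_arma = fit_arma(reduced_res, full.arma.spec)
        reduced = _combine(reduced_gam, reduced_arma)
        values[name] = (full.total_deviance_explained
                        - reduced.total_deviance_explained)
        logger.info("importance[%s] = %.3f pp", name, values[name])

    ar_share = full.total_deviance_explained - full.gam.deviance_explained
    return ImportanceTable(values, ar_share)
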
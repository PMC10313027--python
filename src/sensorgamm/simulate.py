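"""Synthetic sensor datasets with known ground truth.

The generator builds covariates with diel (24 h) and seasonal (365.25 d)
sinusoids, AR(1) noise and storm-like event pulses (instant rise,
exponential decay; event times can be shared between an elevation-style and
a turbidity-style covariate), passes them through named smooth effect
shapes, adds an exactly stationary ARMA error, and finally injects gap runs
and flagged anomalies.  Truth columns are retained so every pipeline stage
can be validated against known quantities, and the forward identity

    response = intercept + sum_k effect_k + eta

holds row-wise before any masking.

All randomness flows through one ``numpy`` generator seeded from the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import solve_discrete_lyapunov
from scipy.signal import lfilter, lfiltic

from .errors import SimulationSpecError
from .io import RESPONSE, TIME_COLUMN, TURBIDITY, AlignedDataset

#: Named smooth-effect shapes, applied to the z-scored covariate.
SHAPES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "zero": lambda z: np.zeros_like(z),
    "linear": lambda z: z,
    "quadratic": lambda z: z * z - 1.0,
    "sine": lambda z: np.sin(np.pi * z),
    "sigmoid": lambda z: np.tanh(z),
}


@dataclass(frozen=True)
class CovariateRecipe:
    """Signal recipe for one simulated sensor stream."""

    mean: float
    diel_amp: float = 0.0
    diel_phase: float = 0.0
    seasonal_amp: float = 0.0
    seasonal_phase: float = 0.0
    ar1: float = 0.0
    noise_scale: float = 0.0
    event_rate: float = 0.0          # events per day
    event_height: float = 0.0
    event_decay: float = 1.0         # e-folding time in days
    share_events_with: str | None = None
    nonnegative: bool = False


@dataclass(frozen=True)
class TruthSpec:
    """Complete description of one synthetic dataset."""

    n: int
    seed: int
    start: str = "2018-01-01T00:00:00Z"
    step_minutes: int = 15
    covariates: dict[str, CovariateRecipe] = field(default_factory=dict)
    effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    intercept: float = 0.0
    ar: tuple[float, ...] = ()
    ma: tuple[float, ...] = ()
    sigma: float = 1.0
    gap_fraction: float = 0.0
    gap_mean_run: float = 8.0
    anomaly_fraction: float = 0.0
    anomaly_scale: float = 8.0       # offset in column standard deviations
    site_label: str = "synthetic"

    def validate(self) -> None:
        if self.seed is None:
            raise SimulationSpecError("seed is mandatory")
        if self.n < 1:
            raise SimulationSpecError("n must be positive")
        if self.sigma < 0:
            raise SimulationSpecError("sigma must be non-negative")
        for name, rec in self.covariates.items():
            if rec.event_rate > 0 and rec.event_decay <= 0:
                raise SimulationSpecError(
                    f"covariate {name!r}: event decay must be positive")
            if rec.share_events_with is not None and \
                    rec.share_events_with not in self.covariates:
                raise SimulationSpecError(
                    f"covariate {name!r} shares events with unknown "
                    f"{rec.share_events_with!r}")
        for name, (shape, _) in self.effects.items():
            if shape not in SHAPES:
                raise SimulationSpecError(f"unknown effect shape {shape!r}")
            if name != TIME_COLUMN and name not in self.covariates:
                raise SimulationSpecError(f"effect on unknown covariate {name!r}")
        if not _stationary(self.ar):
            raise SimulationSpecError("AR coefficients are not stationary")
        if not _stationary(tuple(-m for m in self.ma)):
            raise SimulationSpecError("MA coefficients are not invertible")


def _stationary(coefs: tuple[float, ...]) -> bool:
    if not coefs:
        return True
    poly = np.concatenate(([1.0], -np.asarray(coefs, dtype=float)))
    return bool(np.all(np.abs(np.roots(poly[::-1])) > 1.0))


# --------------------------------------------------------------------------
# Covariate signals

def simulate_covariates(spec: TruthSpec,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Raw (untransformed) covariate streams on the spec's grid."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t_days = np.arange(spec.n) * spec.step_minutes / 1440.0
    total_days = t_days[-1] if spec.n > 1 else 0.0

    event_times: dict[str, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for name, rec in spec.covariates.items():
        col = np.full(spec.n, rec.mean)
        col += rec.diel_amp * np.sin(2.0 * np.pi * t_days + rec.diel_phase)
        col += rec.seasonal_amp * np.sin(
            2.0 * np.pi * t_days / 365.25 + rec.seasonal_phase)
        if rec.noise_scale > 0:
            eps = rng.standard_normal(spec.n) * rec.noise_scale
            if abs(rec.ar1) > 0:
                scale0 = rec.noise_scale / np.sqrt(1.0 - rec.ar1 ** 2)
                zi = lfiltic([1.0], [1.0, -rec.ar1],
                             [rng.standard_normal() * scale0])
                noise, _ = lfilter([1.0], [1.0, -rec.ar1], eps, zi=zi)
            else:
                noise = eps
            col += noise
        if rec.event_rate > 0 or rec.share_events_with:
            if rec.share_events_with and rec.share_events_with in event_times:
                times = event_times[rec.share_events_with]
            else:
                k = rng.poisson(rec.event_rate * max(total_days, 0.0))
                times = np.sort(rng.uniform(0.0, max(total_days, 1e-9), size=k))
            event_times[name] = times
            for t0 in times:
                after = t_days >= t0
                col[after] += rec.event_height * np.exp(
                    -(t_days[after] - t0) / rec.event_decay)
        if rec.nonnegative:
            col = np.maximum(col, 0.0)
        out[name] = col
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# ARMA errors with exact stationary initialization

def arma_stationary_variance(ar, ma, sigma: float) -> float:
    """Stationary variance of the ARMA process (closed form via Lyapunov)."""
    ar = np.asarray(ar, dtype=float)
    ma = np.asarray(ma, dtype=float)
    p, q = len(ar), len(ma)
    r = max(p, q + 1)
    F = np.zeros((r, r))
    F[0, :p] = ar
    for i in range(r - 1):
        F[i + 1, i] = 1.0
    Q = np.zeros((r, r))
    Q[0, 0] = sigma ** 2
    P = solve_discrete_lyapunov(F, Q)
    Z = np.zeros(r)
    Z[0] = 1.0
    Z[1: q + 1] = ma
    return float(Z @ P @ Z)


def simulate_arma_errors(
    spec: TruthSpec, n: int | None = None,
    rng: np.random.Generator | None = None,
    return_innovations: bool = False,
):
    """Draw an exactly stationary ARMA error series.

    The AR state history is drawn from the stationary distribution (discrete
    Lyapunov covariance), so no burn-in is needed and the marginal law of
    every sample equals the stationary law.
    """
    spec.validate()
    if n is None:
        n = spec.n
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ar = np.asarray(spec.ar, dtype=float)
    ma = np.asarray(spec.ma, dtype=float)
    sigma = float(spec.sigma)
    p, q = len(ar), len(ma)

    if sigma == 0:
        eta = np.zeros(n)
        return (eta, np.zeros(n)) if return_innovations else eta

    r = max(p, q + 1)
    F = np.zeros((r, r))
    F[0, :p] = ar
    for i in range(r - 1):
        F[i + 1, i] = 1.0
    Q = np.zeros((r, r))
    Q[0, 0] = sigma ** 2
    P = solve_discrete_lyapunov(F, Q)
    L = np.linalg.cholesky(P + 1e-12 * sigma ** 2 * np.eye(r))
    alpha0 = L @ rng.standard_normal(r)       # (u_0, u_-1, ..., u_{1-r})

    eps = sigma * rng.standard_normal(n)
    if p > 0:
        a_poly = np.concatenate(([1.0], -ar))
        zi = lfiltic([1.0], a_poly, alpha0[:p])
        u, _ = lfilter([1.0], a_poly, eps, zi=zi)
    else:
        u = eps
    if q > 0:
        hist = alpha0[:q][::-1]               # (u_{1-q}, ..., u_0)
        u_ext = np.concatenate([hist, u])
        eta = lfilter(np.concatenate(([1.0], ma)), [1.0], u_ext)[q:]
    else:
        eta = u
    return (eta, eps) if return_innovations else eta


# --------------------------------------------------------------------------
# Full dataset

@dataclass
class SyntheticDataset:
    """Aligned dataset plus per-row ground truth and injection bookkeeping."""

    data: AlignedDataset
    truth: pd.DataFrame               # response_true, eta, eps, f_<name>...
    raw_covariates: pd.DataFrame      # untransformed, pre-masking
    spec: TruthSpec
    gap_mask: np.ndarray              # True = row lost to a gap
    anomalies: list[tuple[int, str]]  # (row, variable) flagged anomalous

    def designed_total_deviance(self) -> float:
        """Deviance explained a perfect two-step fit would report."""
        var_y = float(np.var(self.truth["response_true"]))
        return 100.0 * (1.0 - self.spec.sigma ** 2 / var_y)

    def designed_gam_deviance(self) -> float:
        """Deviance share of the smooth (covariate) part alone."""
        var_y = float(np.var(self.truth["response_true"]))
        var_eta = float(np.var(self.truth["eta"]))
        return 100.0 * (1.0 - var_eta / var_y)

    def designed_importance_order(self) -> list[str]:
        """Effect names ordered by the variance of their true contribution."""
        shares = {
            name: float(np.var(self.truth[f"f_{name}"]))
            for name in self.spec.effects
        }
        return sorted(shares, key=shares.get, reverse=True)

    # -------------------------------------------------------------- export
    def write_sensor_tables(self, outdir: str | Path) -> dict[str, Path]:
        """Write per-variable sensor CSVs that round-trip through sensor_io.

        Gap rows are omitted (the sensor was silent); anomalous cells are
        written with their outlier value and ``qc_flag=1``.  Turbidity is
        exported on the raw FNU scale.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        anom = {(row, var) for row, var in self.anomalies}
        grid = self.data.grid
        paths: dict[str, Path] = {}

        def write_one(name: str, values: np.ndarray) -> None:
            sd = float(np.std(values)) or 1.0
            rows = []
            for i, ts in enumerate(grid):
                if self.gap_mask[i]:
                    continue
                val = values[i]
                flag = 0
                if (i, name) in anom:
                    val = val + self.spec.anomaly_scale * sd
                    flag = 1
                rows.append((ts.isoformat(), val, flag))
            path = outdir / f"{name}.csv"
            pd.DataFrame(rows, columns=["timestamp", "value", "qc_flag"]) \
                .to_csv(path, index=False)
            paths[name] = path

        write_one(RESPONSE, self.truth["response_true"].to_numpy())
        for name in self.raw_covariates.columns:
            write_one(name, self.raw_covariates[name].to_numpy())
        return paths


def _gap_runs(n: int, fraction: float, mean_run: float,
              rng: np.random.Generator) -> np.ndarray:
    """Two-state Markov gap mask with geometric run lengths."""
    mask = np.zeros(n, dtype=bool)
    if fraction <= 0:
        return mask
    if fraction >= 1:
        raise SimulationSpecError("gap fraction must be below 1")
    p_exit = 1.0 / max(mean_run, 1.0)
    p_enter = fraction * p_exit / (1.0 - fraction)
    in_gap = rng.random() < fraction
    draws = rng.random(n)
    for i in range(n):
        mask[i] = in_gap
        if in_gap:
            in_gap = draws[i] >= p_exit
        else:
            in_gap = draws[i] < p_enter
    return mask


def simulate_dataset(spec: TruthSpec) -> SyntheticDataset:
    """Assemble the full forward model and inject gaps and anomalies."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    raw = simulate_covariates(spec, rng)
    model = raw.copy()
    if TURBIDITY in model.columns:
        model[TURBIDITY] = np.log1p(np.maximum(model[TURBIDITY], 0.0))
    t_days = np.arange(spec.n) * spec.step_minutes / 1440.0
    model[TIME_COLUMN] = t_days

    truth = pd.DataFrame(index=range(spec.n))
    signal = np.full(spec.n, float(spec.intercept))
    for name, (shape, amp) in spec.effects.items():
        col = model[name].to_numpy(dtype=float)
        sd = float(col.std()) or 1.0
        z = (col - col.mean()) / sd
        f = amp * SHAPES[shape](z)
        f = f - f.mean()              # identifiable against the intercept
        truth[f"f_{name}"] = f
        signal += f

    eta, eps = simulate_arma_errors(spec, rng=rng, return_innovations=True)
    response = signal + eta
    truth["eta"] = eta
    truth["eps"] = eps
    truth["response_true"] = response

    gap_mask = _gap_runs(spec.n, spec.gap_fraction, spec.gap_mean_run, rng)

    anomalies: list[tuple[int, str]] = []
    if spec.anomaly_fraction > 0:
        eligible = np.nonzero(~gap_mask)[0]
        k = int(round(spec.anomaly_fraction * spec.n))
        k = min(k, len(eligible))
        rows = rng.choice(eligible, size=k, replace=False)
        variables = [RESPONSE, *spec.covariates.keys()]
        for row in np.sort(rows):
            anomalies.append((int(row), variables[rng.integers(len(variables))]))

    response_obs = response.copy()
    response_obs[gap_mask] = np.nan
    cov_obs = model.copy()
    cov_cols = [c for c in cov_obs.columns if c != TIME_COLUMN]
    cov_obs.loc[gap_mask, cov_cols] = np.nan
    for row, var in anomalies:
        if var == RESPONSE:
            response_obs[row] = np.nan
        else:
            cov_obs.iloc[row, cov_obs.columns.get_loc(var)] = np.nan

    grid = pd.date_range(pd.Timestamp(spec.start),
                         periods=spec.n, freq=f"{spec.step_minutes}min")
    metadata = {
        "turbidity_transform": "log1p" if TURBIDITY in model.columns else None,
        "synthetic": True,
        "seed": spec.seed,
    }
    data = AlignedDataset(grid=grid, response=response_obs,
                          covariates=cov_obs, site_label=spec.site_label,
                          metadata=metadata)
    return SyntheticDataset(data=data, truth=truth, raw_covariates=raw,
                            spec=spec, gap_mask=gap_mask, anomalies=anomalies)


# --------------------------------------------------------------------------
# Scenarios

_SITE_STYLE = {
    # intercept, conductance, oxygen, temperature mean / seasonal amplitude
    "low": dict(nitrate=5.5, cond=531.6, do=7.3, temp=(15.0, 12.0)),
    "medium": dict(nitrate=28.4, cond=77.15, do=12.34, temp=(6.0, 5.0)),
    "high": dict(nitrate=192.0, cond=577.8, do=9.55, temp=(10.0, 8.0)),
}


def scenario(name: str = "medium", n: int = 10000, seed: int = 0,
             gap_fraction: float = 0.0, anomaly_fraction: float = 0.0) -> TruthSpec:
    """Ready-made specs for low / medium / high nitrate regimes.

    Active effects (conductance: sigmoid, temperature: sine, oxygen:
    quadratic) have graded amplitudes; turbidity, elevation and time are
    null covariates.  Errors are ARMA(2, 1) with lag-one autocorrelation
    around 0.8.
    """
    if name not in _SITE_STYLE:
        raise SimulationSpecError(
            f"unknown scenario {name!r}; choose from {sorted(_SITE_STYLE)}")
    style = _SITE_STYLE[name]
    b0 = style["nitrate"]
    temp_mean, temp_seas = style["temp"]
    covariates = {
        "specific_conductance": CovariateRecipe(
            mean=style["cond"], diel_amp=0.02 * style["cond"],
            seasonal_amp=0.05 * style["cond"], ar1=0.9,
            noise_scale=0.02 * style["cond"]),
        "dissolved_oxygen": CovariateRecipe(
            mean=style["do"], diel_amp=0.8, diel_phase=1.2,
            seasonal_amp=0.8, ar1=0.8, noise_scale=0.25),
        "temperature": CovariateRecipe(
            mean=temp_mean, diel_amp=1.5, diel_phase=-0.6,
            seasonal_amp=temp_seas, ar1=0.85, noise_scale=0.4),
        "elevation": CovariateRecipe(
            mean=230.0, diel_amp=0.02, ar1=0.7, noise_scale=0.02,
            event_rate=0.1, event_height=0.4, event_decay=1.0),
        "turbidity": CovariateRecipe(
            mean=3.0, diel_amp=0.5, diel_phase=0.8, ar1=0.6,
            noise_scale=1.0, event_rate=0.1, event_height=60.0,
            event_decay=0.4, share_events_with="elevation",
            nonnegative=True),
    }
    effects = {
        "specific_conductance": ("sigmoid", 0.30 * b0),
        "temperature": ("sine", 0.18 * b0),
        "dissolved_oxygen": ("quadratic", 0.10 * b0),
        "turbidity": ("zero", 0.0),
        "elevation": ("zero", 0.0),
        TIME_COLUMN: ("zero", 0.0),
    }
    # oscillatory AR(2) + MA(1): lag-one autocorrelation 0.8, clearly
    # distinguishable from any ARMA(1, q) approximation
    return TruthSpec(
        n=n, seed=seed, covariates=covariates, effects=effects,
        intercept=b0, ar=(1.2, -0.5), ma=(0.5,), sigma=0.05 * b0,
        gap_fraction=gap_fraction, anomaly_fraction=anomaly_fraction,
        site_label=f"synthetic-{name}",
    )


SCENARIOS = tuple(_SITE_STYLE)


# --------------------------------------------------------------------------
# Spec (de)serialization

def spec_to_yaml(spec: TruthSpec, path: str | Path) -> None:
    payload = {
        "n": spec.n, "seed": spec.seed, "start": spec.start,
        "step_minutes": spec.step_minutes,
        "intercept": spec.intercept,
        "ar": list(spec.ar), "ma": list(spec.ma), "sigma": spec.sigma,
        "gap_fraction": spec.gap_fraction, "gap_mean_run": spec.gap_mean_run,
        "anomaly_fraction": spec.anomaly_fraction,
        "anomaly_scale": spec.anomaly_scale,
        "site_label": spec.site_label,
        "covariates": {k: vars(v).copy() for k, v in spec.covariates.items()},
        "effects": {k: list(v) for k, v in spec.effects.items()},
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def spec_from_yaml(path: str | Path) -> TruthSpec:
    payload = yaml.safe_load(Path(path).read_text())
    covariates = {k: CovariateRecipe(**v)
                  for k, v in payload.pop("covariates", {}).items()}
    effects = {k: (v[0], float(v[1]))
               for k, v in payload.pop("effects", {}).items()}
    payload["ar"] = tuple(payload.get("ar", ()))
    payload["ma"] = tuple(payload.get("ma", ()))
    spec = TruthSpec(covariates=covariates, effects=effects, **payload)
    spec.validate()
    return spec
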
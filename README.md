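# sensorgamm

Two-stage additive modelling of high-frequency water-quality sensor time
series: explain nitrate concentration from co-measured covariates (specific
conductance, dissolved oxygen, temperature, turbidity, surface-water
elevation, and a continuous time term) with

1. **a penalized-spline GAM** — low-rank natural-cubic smooths with an exact
   curvature penalty, effective degrees of freedom capped at 6 per smooth,
   smoothing parameters and variable set selected by Gaussian AIC
   (bidirectional stepwise), and
2. **an ARIMA model on the GAM residuals** — exact Gaussian likelihood via a
   Kalman filter that handles missing values, partial-autocorrelation
   parameterization for stationarity/invertibility, and AIC order selection
   over p ≤ 5, d ≤ 1, q ≤ 4.

On top of the two stages the package provides the approximate AIC
(`aAIC = n·ln(σ²) + 2k`) for GAM-vs-GAMM comparison, total deviance
explained based on one-step-ahead innovations, leave-one-covariate-out
variable importance, VIF collinearity screening (threshold 6), NEON-style
sensor-table ingestion with quality-flag filtering and 15-minute grid
alignment, and a fully seeded synthetic data generator with known ground
truth (diel/seasonal cycles, storm pulses, ARMA errors, gaps, flagged
anomalies).

## CLI

```sh
# generate a synthetic dataset (three scenarios: low / medium / high nitrate)
sensorgamm simulate --scenario medium --n 10000 --seed 1 --out runs/sim

# full pipeline: VIF screen -> stepwise GAM -> ARIMA on residuals ->
# importance + aAIC comparison; writes CSV/text reports
sensorgamm fit --aligned runs/sim/aligned.csv --out runs/fit

# raw sensor tables with a column-mapping dialect also work
sensorgamm fit --table nitrate.csv --dialect nitrate_dialect.yaml \
               --table temperature.csv --dialect temp_dialect.yaml \
               --out runs/fit

# single-artifact variants
sensorgamm compare --aligned runs/sim/aligned.csv --out runs/cmp
sensorgamm importance --aligned runs/sim/aligned.csv --out runs/imp
```

`fit` writes: `summary.csv` (per-variable descriptive statistics),
`vif.csv`, `selection_trace.txt` (stepwise AIC path),
`partial_effects.csv` (smooths with standard errors),
`aaic_comparison.csv` (GAM vs GAMM), `importance.csv` (per-covariate
deviance loss plus the autoregressive share), `report.txt` and
`config_echo.yaml` (the exact configuration used, for reproducibility).

## Conventions

- Complete-case rows only: a grid row enters the fit when the response and
  all candidate covariates are present; anomalous records are removed
  before alignment; turbidity is modelled as `log(turbidity + 1)`.
- Total deviance explained = `100·(1 − SS_innovations / TSS)`, with the
  innovation sum of squares from the selected ARIMA's one-step-ahead
  prediction errors; the GAM row of the comparison uses its residual
  variance. `k_total` counts the GAM's effective df (intercept included)
  plus p + q.
- ARIMA order selection defaults to a deterministic local (stepwise) search
  in (p, q) within each d, excluding non-converged, degenerate and
  near-cancelling (non-identifiable) fits; `search="exhaustive"` is
  available.
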
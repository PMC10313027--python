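"""Tests for the ground-truth synthetic data generator."""

import numpy as np
import pytest
from scipy.stats import poisson

from sensorgamm.errors import SimulationSpecError
from sensorgamm.io import align_to_response_grid, read_sensor_table, transform_covariates
from sensorgamm.simulate import (
    CovariateRecipe,
    TruthSpec,
    arma_stationary_variance,
    scenario,
    simulate_arma_errors,
    simulate_covariates,
    simulate_dataset,
    spec_from_yaml,
    spec_to_yaml,
)


def spec_with(**kwargs):
    defaults = dict(n=1000, seed=1)
    defaults.update(kwargs)
    return TruthSpec(**defaults)


class TestCovariates:
    def test_degenerate_constant(self):
        spec = spec_with(covariates={"temperature": CovariateRecipe(mean=4.5)})
        cols = simulate_covariates(spec)
        np.testing.assert_array_equal(cols["temperature"], 4.5)

    def test_diel_range_twice_amplitude(self):
        spec = spec_with(
            n=96 * 4,  # four full days at 15 minutes
            covariates={"temperature": CovariateRecipe(mean=10.0, diel_amp=3.0)})
        col = simulate_covariates(spec)["temperature"].to_numpy()
        day = col[:96]
        assert day.max() - day.min() == pytest.approx(6.0, rel=1e-3)

    def test_event_count_in_poisson_interval(self):
        # rate 1/10 days over 100 days -> 10 expected events
        n = 100 * 96
        spec = spec_with(
            n=n, seed=7,
            covariates={"elevation": CovariateRecipe(
                mean=100.0, event_rate=0.1, event_height=5.0, event_decay=0.5)})
        col = simulate_covariates(spec)["elevation"].to_numpy()
        jumps = np.diff(col)
        count = int((jumps > 2.0).sum())  # pulse rises dominate decay steps
        lo, hi = poisson.interval(0.99, 10)
        assert lo <= count <= hi

    def test_shared_event_times(self):
        spec = spec_with(
            n=2000, seed=9,
            covariates={
                "elevation": CovariateRecipe(mean=100.0, event_rate=0.5,
                                             event_height=5.0, event_decay=0.5),
                "turbidity": CovariateRecipe(mean=2.0, event_rate=0.0,
                                             event_height=50.0, event_decay=0.3,
                                             share_events_with="elevation",
                                             nonnegative=True),
            })
        cols = simulate_covariates(spec)
        elev_jumps = set(np.nonzero(np.diff(cols["elevation"]) > 2.0)[0])
        turb_jumps = set(np.nonzero(np.diff(cols["turbidity"]) > 20.0)[0])
        assert turb_jumps and turb_jumps.issubset(elev_jumps)

    def test_bad_decay_rejected(self):
        spec = spec_with(covariates={"turbidity": CovariateRecipe(
            mean=1.0, event_rate=0.1, event_height=1.0, event_decay=-2.0)})
        with pytest.raises(SimulationSpecError):
            simulate_covariates(spec)


class TestArmaErrors:
    def test_white_noise_variance(self):
        eta = simulate_arma_errors(spec_with(n=100000, seed=2, sigma=1.0))
        assert np.var(eta) == pytest.approx(1.0, rel=0.05)

    def test_ar1_lag1_acf(self):
        eta = simulate_arma_errors(spec_with(n=100000, seed=3, ar=(0.8,),
                                             sigma=1.0))
        acf1 = np.corrcoef(eta[1:], eta[:-1])[0, 1]
        assert acf1 == pytest.approx(0.8, abs=0.02)

    def test_ma1_acf_closed_form(self):
        eta = simulate_arma_errors(spec_with(n=100000, seed=4, ma=(0.6,),
                                             sigma=1.0))
        acf1 = np.corrcoef(eta[1:], eta[:-1])[0, 1]
        acf2 = np.corrcoef(eta[2:], eta[:-2])[0, 1]
        assert acf1 == pytest.approx(0.6 / 1.36, abs=0.02)
        assert acf2 == pytest.approx(0.0, abs=0.02)

    def test_stationary_variance_matches_theory(self):
        spec = spec_with(n=200000, seed=5, ar=(0.65, 0.2), ma=(0.35,),
                         sigma=1.3)
        eta = simulate_arma_errors(spec)
        theory = arma_stationary_variance(spec.ar, spec.ma, spec.sigma)
        assert np.var(eta) == pytest.approx(theory, rel=0.05)

    def test_nonstationary_spec_rejected(self):
        with pytest.raises(SimulationSpecError):
            simulate_arma_errors(spec_with(ar=(1.1,)))


class TestDataset:
    def test_forward_identity(self):
        ds = simulate_dataset(scenario("medium", n=2000, seed=6))
        total = (ds.spec.intercept
                 + sum(ds.truth[f"f_{k}"] for k in ds.spec.effects)
                 + ds.truth["eta"])
        np.testing.assert_allclose(ds.truth["response_true"], total,
                                   rtol=0, atol=1e-10)

    def test_zero_everything_gives_intercept(self):
        spec = spec_with(
            n=50, intercept=4.2, sigma=0.0,
            covariates={"temperature": CovariateRecipe(mean=1.0,
                                                       diel_amp=0.5)},
            effects={"temperature": ("zero", 0.0)})
        ds = simulate_dataset(spec)
        np.testing.assert_allclose(ds.data.response, 4.2)

    def test_same_seed_identical(self):
        a = simulate_dataset(scenario("low", n=500, seed=8,
                                      gap_fraction=0.1, anomaly_fraction=0.01))
        b = simulate_dataset(scenario("low", n=500, seed=8,
                                      gap_fraction=0.1, anomaly_fraction=0.01))
        np.testing.assert_array_equal(a.data.response, b.data.response)
        assert a.anomalies == b.anomalies
        np.testing.assert_array_equal(a.gap_mask, b.gap_mask)

    def test_scenario_medians_ordered(self):
        meds = {}
        for name in ("low", "medium", "high"):
            ds = simulate_dataset(scenario(name, n=2000, seed=10))
            meds[name] = float(np.nanmedian(ds.data.response))
        assert meds["low"] < meds["medium"] < meds["high"]
        # design anchors: 5.5 / 28.4 / 192 within generous tolerance
        assert meds["low"] == pytest.approx(5.5, rel=0.25)
        assert meds["high"] == pytest.approx(192.0, rel=0.25)

    def test_gap_fraction_realized(self):
        ds = simulate_dataset(scenario("medium", n=8000, seed=11,
                                       gap_fraction=0.2))
        frac = ds.gap_mask.mean()
        assert frac == pytest.approx(0.2, abs=0.07)
        assert np.isnan(ds.data.response[ds.gap_mask]).all()

    def test_anomalies_masked_and_listed(self):
        ds = simulate_dataset(scenario("medium", n=4000, seed=12,
                                       anomaly_fraction=0.01))
        assert len(ds.anomalies) == pytest.approx(40, abs=1)
        for row, var in ds.anomalies:
            if var == "nitrate":
                assert np.isnan(ds.data.response[row])
            else:
                assert np.isnan(ds.data.covariates[var].iloc[row])

    def test_designed_deviances_consistent(self):
        ds = simulate_dataset(scenario("medium", n=5000, seed=13))
        total = ds.designed_total_deviance()
        gam = ds.designed_gam_deviance()
        assert 0 < gam < total < 100

    def test_round_trip_through_sensor_tables(self, tmp_path):
        ds = simulate_dataset(scenario("medium", n=400, seed=14,
                                       anomaly_fraction=0.02))
        paths = ds.write_sensor_tables(tmp_path)
        records = []
        for name, path in paths.items():
            records.extend(read_sensor_table(
                path, {"timestamp": "timestamp", "value": "value",
                       "flag": "qc_flag", "variable": name}))
        aligned = transform_covariates(align_to_response_grid(records))
        np.testing.assert_allclose(aligned.response, ds.data.response,
                                   atol=1e-9)
        for col in ds.data.covariates.columns:
            np.testing.assert_allclose(
                aligned.covariates[col].to_numpy(),
                ds.data.covariates[col].to_numpy(), atol=1e-9,
                err_msg=col)

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = scenario("high", n=777, seed=5, gap_fraction=0.05)
        path = tmp_path / "spec.yaml"
        spec_to_yaml(spec, path)
        back = spec_from_yaml(path)
        assert back == spec
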
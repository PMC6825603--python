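"""FCS model evaluation, the three fit variants, QC and derived values."""

import numpy as np
import pytest

from aostedfcs.correlator import ACF
from aostedfcs.fcsmodels import (FCSModelParams, concentration, fit_confocal,
                                 fit_sted_coupled, fit_sted_fixed_lateral,
                                 model_g, qc_long_lag, residual_metric, tau_z)
from aostedfcs.volume import KCalibration

LAGS = np.geomspace(2e-6, 0.1, 90)


def make_acf(params, noise=0.0, seed=0):
    g = model_g(LAGS, params)
    if noise:
        g = g + noise * np.random.default_rng(seed).standard_normal(LAGS.size)
    return ACF(LAGS, g)


class TestModelG:
    def test_zero_lag_limit_is_inverse_N(self):
        p = FCSModelParams(N=5.0, tau_xy=1e-3, T=0.0, delta=0.0)
        assert model_g(1e-12, p) == pytest.approx(0.2, rel=1e-6)

    def test_half_amplitude_at_transit_time_for_large_K(self):
        p = FCSModelParams(N=2.0, tau_xy=1e-3, K=1e6, T=0.0)
        assert model_g(1e-3, p) == pytest.approx(0.25, rel=1e-5)

    def test_triplet_amplitude_factor(self):
        p = FCSModelParams(N=1.0, tau_xy=1.0, K=1e6, T=0.3, tau_T=1e-5)
        # at τ→0 the blinking factor is 1/(1−T)
        assert model_g(1e-12, p) == pytest.approx(1.0 / 0.7, rel=1e-6)

    def test_strictly_decreasing_without_triplet(self):
        p = FCSModelParams(N=3.0, tau_xy=5e-4, K=3.0, T=0.0, alpha=0.75)
        g = model_g(LAGS, p)
        assert np.all(np.diff(g) < 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            model_g(1e-3, FCSModelParams(N=-1.0, tau_xy=1e-3))


class TestFitConfocal:
    def test_noise_free_self_consistency(self):
        truth = FCSModelParams(N=5.0, tau_xy=1e-3, alpha=1.0, K=4.0,
                               T=0.15, tau_T=12e-6)
        fit = fit_confocal(make_acf(truth), K_fixed=4.0, tau_T=12e-6)
        assert fit.params.N == pytest.approx(5.0, rel=1e-5)
        assert fit.params.tau_xy == pytest.approx(1e-3, rel=1e-5)
        assert fit.params.T == pytest.approx(0.15, abs=1e-4)

    def test_K_pinned_regardless_of_data(self):
        truth = FCSModelParams(N=2.0, tau_xy=5e-4, K=2.0, T=0.1, tau_T=12e-6)
        fit = fit_confocal(make_acf(truth, noise=1e-3), K_fixed=4.0, tau_T=12e-6)
        assert fit.params.K == 4.0
        assert "K" in fit.fixed_mask

    def test_requires_lag_coverage(self):
        with pytest.raises(ValueError):
            fit_confocal(ACF(np.geomspace(1e-5, 5e-5, 12), np.ones(12)))


class TestStedFits:
    cal = KCalibration(np.empty((0, 2)), w_inf=0.7, kappa=1.0, K_conf=4.0)
    conf_truth = FCSModelParams(N=5.0, tau_xy=1e-3, K=4.0, T=0.1, tau_T=12e-6)

    def _conf_fit(self):
        return fit_confocal(make_acf(self.conf_truth), K_fixed=4.0, tau_T=12e-6)

    def test_identical_data_recovers_confocal_point(self):
        conf = self._conf_fit()
        sted = fit_sted_coupled(make_acf(self.conf_truth), conf, self.cal)
        assert sted.params.K == pytest.approx(4.0, abs=0.05)
        assert sted.params.tau_xy == pytest.approx(1e-3, rel=0.02)

    def test_coupled_recovers_shrunken_volume(self):
        K_true = 2.0
        om = self.cal.omega(K_true)
        sted_truth = FCSModelParams(N=5.0, tau_xy=1e-3 * om**2, K=K_true,
                                    T=0.1, tau_T=12e-6)
        conf = self._conf_fit()
        fit = fit_sted_coupled(make_acf(sted_truth), conf, self.cal)
        assert fit.params.K == pytest.approx(K_true, abs=0.05)
        assert fit.params.N == pytest.approx(5.0, rel=0.02)

    def test_legacy_pins_lateral_transit(self):
        conf = self._conf_fit()
        sted_truth = FCSModelParams(N=4.0, tau_xy=8e-4, K=2.5, T=0.1, tau_T=12e-6)
        fit = fit_sted_fixed_lateral(make_acf(sted_truth), conf)
        assert fit.params.tau_xy == conf.params.tau_xy
        assert "tau_xy" in fit.fixed_mask

    def test_models_coincide_without_lateral_shrink(self):
        """With an identity calibration the coupled and legacy fits agree."""
        from aostedfcs.volume import identity_calibration
        ident = identity_calibration(4.0)
        sted_truth = FCSModelParams(N=5.0, tau_xy=1e-3, K=2.0, T=0.1, tau_T=12e-6)
        conf = self._conf_fit()
        coupled = fit_sted_coupled(make_acf(sted_truth), conf, ident)
        legacy = fit_sted_fixed_lateral(make_acf(sted_truth), conf)
        assert coupled.params.N == pytest.approx(legacy.params.N, rel=0.05)
        assert coupled.params.K == pytest.approx(legacy.params.K, rel=0.10)

    def test_lateral_shrink_biases_legacy_K(self):
        """30% lateral shrink: the legacy fixed-lateral fit absorbs the
        faster lateral transit into a biased K; the coupled fit does not."""
        K_true = 2.0
        om = self.cal.omega(K_true)
        sted_truth = FCSModelParams(N=5.0, tau_xy=1e-3 * om**2, K=K_true,
                                    T=0.1, tau_T=12e-6)
        conf = self._conf_fit()
        acf = make_acf(sted_truth, noise=5e-4, seed=1)
        coupled = fit_sted_coupled(acf, conf, self.cal)
        legacy = fit_sted_fixed_lateral(acf, conf)
        bias_coupled = abs(coupled.params.K - K_true)
        bias_legacy = abs(legacy.params.K - K_true)
        assert bias_legacy > 3 * bias_coupled


class TestResidualMetricAndQC:
    truth = FCSModelParams(N=5.0, tau_xy=1e-3, K=4.0, T=0.1, tau_T=12e-6)

    def test_perfect_fit_gives_zero(self):
        fit = fit_confocal(make_acf(self.truth), K_fixed=4.0, tau_T=12e-6)
        assert residual_metric(make_acf(self.truth), fit) < 1e-8

    def test_scale_invariance(self):
        """Scaling data and model together leaves the metric unchanged."""
        acf = make_acf(self.truth, noise=2e-3, seed=2)
        fit = fit_confocal(acf, K_fixed=4.0, tau_T=12e-6)
        m1 = residual_metric(acf, fit)
        scaled_truth = FCSModelParams(N=self.truth.N / 3, tau_xy=1e-3, K=4.0,
                                      T=0.1, tau_T=12e-6)
        acf2 = make_acf(scaled_truth, noise=6e-3, seed=2)
        fit2 = fit_confocal(acf2, K_fixed=4.0, tau_T=12e-6)
        m2 = residual_metric(acf2, fit2)
        assert m2 == pytest.approx(m1, rel=0.15)

    def test_metric_scales_with_noise_power(self):
        ms = []
        for sigma in (1e-3, 2e-3):
            vals = []
            for seed in range(20):
                acf = make_acf(self.truth, noise=sigma, seed=seed)
                fit = fit_confocal(acf, K_fixed=4.0, tau_T=12e-6)
                vals.append(residual_metric(acf, fit))
            ms.append(np.mean(vals))
        assert ms[1] / ms[0] == pytest.approx(4.0, rel=0.30)

    def test_qc_clean_curve_passes(self):
        fit = fit_confocal(make_acf(self.truth), K_fixed=4.0, tau_T=12e-6)
        assert qc_long_lag(make_acf(self.truth), fit)

    def test_qc_offset_tail_fails(self):
        g = model_g(LAGS, self.truth) + 0.05
        fit = fit_confocal(make_acf(self.truth), K_fixed=4.0, tau_T=12e-6)
        assert not qc_long_lag(ACF(LAGS, g), fit)

    def test_qc_infinite_threshold_always_passes(self):
        g = model_g(LAGS, self.truth) + 1.0
        assert qc_long_lag(ACF(LAGS, g), threshold=np.inf)


class TestDerivedQuantities:
    def test_tau_z_brownian_K_squared(self):
        from aostedfcs.fcsmodels import FitResult
        p = FCSModelParams(N=1.0, tau_xy=1e-3, K=4.0, alpha=1.0)
        assert tau_z(FitResult(p)) == pytest.approx(16e-3)
        p1 = FCSModelParams(N=1.0, tau_xy=1e-3, K=1.0)
        assert tau_z(FitResult(p1)) == pytest.approx(1e-3)

    def test_concentration_nanomolar_example(self):
        # one molecule in 1 fL is 1.66 nM
        assert concentration(1.0, 1e-15) == pytest.approx(1.66e-9, rel=1e-3)
        with pytest.raises(ValueError):
            concentration(1.0, 0.0)
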
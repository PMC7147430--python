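"""Pooled hydrothermal-time model: cardinal temperatures, branches, fits."""

import numpy as np
import pytest

from conftest import (
    PSI_LEVELS,
    SUB_TEMPS,
    cells_to_timecourses,
    noiseless_htt_cells,
)
from helpers import profiled_htt_grid
from seedhtt import (
    NEVER,
    HTParams,
    HTTParams,
    ceiling_temperature,
    classify_branch,
    fit_htt,
    fit_htt_suboptimal,
    fit_htt_supraoptimal,
    predict_htt_time_to_g,
    predict_time_to_g,
)
from seedhtt.hydrothermal import _supra_predictor
from seedhtt.probit import inverse_probit


class TestCeilingTemperature:
    def test_median_ceiling_in_water(self, htt_truth):
        assert ceiling_temperature(htt_truth, 0.0, 0.5) == pytest.approx(27.2)

    def test_median_ceiling_at_reduced_psi(self, htt_truth):
        assert ceiling_temperature(htt_truth, -0.2, 0.5) == pytest.approx(25.2)

    def test_monotone_decreasing_in_g(self, htt_truth):
        gs = np.linspace(0.05, 0.95, 30)
        tc = [ceiling_temperature(htt_truth, 0.0, g) for g in gs]
        assert np.all(np.diff(tc) < 0)

    def test_sub_threshold_psi_rejected(self, htt_truth):
        with pytest.raises(ValueError, match="cannot"):
            ceiling_temperature(htt_truth, -0.6, 0.9)

    def test_requires_supra_branch(self):
        sub_only = HTTParams(theta_HT=43.9, t_b=7.0, psi_b50=-0.67,
                             sigma_psib_sub=0.28)
        with pytest.raises(ValueError, match="supra"):
            ceiling_temperature(sub_only, 0.0, 0.5)


class TestClassifyBranch:
    @pytest.mark.parametrize("T, t_o, branch",
                             [(20.5, 20.5, "sub"), (28.0, 20.5, "supra"),
                              (11.0, 20.5, "sub")])
    def test_boundary_convention(self, T, t_o, branch):
        assert classify_branch(T, t_o) == branch


class TestHTTParams:
    def test_ceiling_identity_enforced(self, htt_truth):
        assert htt_truth.t_c50 == pytest.approx(
            htt_truth.t_o - htt_truth.psi_b50 / htt_truth.k_T)

    def test_inconsistent_t_c50_rejected(self):
        with pytest.raises(ValueError, match="identity"):
            HTTParams(theta_HT=43.9, t_b=7.0, psi_b50=-0.67, sigma_psib_sub=0.28,
                      t_o=20.5, k_T=0.1, t_c50=30.0)

    def test_cardinal_ordering_enforced(self):
        with pytest.raises(ValueError):
            HTTParams(theta_HT=43.9, t_b=21.0, psi_b50=-0.67, sigma_psib_sub=0.28,
                      t_o=20.5, k_T=0.1)


class TestPredictTime:
    def test_suboptimal_median_time_in_water(self, htt_truth):
        t = predict_htt_time_to_g(htt_truth, 15.0, 0.0, 0.5)
        assert t == pytest.approx(43.9 / ((15 - 7) * 0.67), abs=1e-9)

    def test_at_base_temperature_never(self, htt_truth):
        assert predict_htt_time_to_g(htt_truth, 7.0, 0.0, 0.5) == NEVER

    def test_at_ceiling_never(self, htt_truth):
        assert predict_htt_time_to_g(htt_truth, htt_truth.t_c50, 0.0, 0.5) == NEVER

    def test_equals_ht_prediction_with_scaled_theta(self, htt_truth):
        """Sub-optimal branch is the hydrotime model with
        theta_H = theta_HT / (T - T_b)."""
        for T in SUB_TEMPS:
            ht = HTParams(temperature=T,
                          theta_H=htt_truth.theta_HT / (T - htt_truth.t_b),
                          psi_b50=htt_truth.psi_b50,
                          sigma_psib=htt_truth.sigma_psib_sub)
            for g in (0.2, 0.5, 0.8):
                for psi in (0.0, -0.2):
                    assert predict_htt_time_to_g(htt_truth, T, psi, g) == \
                        pytest.approx(predict_time_to_g(ht, psi, g), abs=1e-9)

    def test_k_t_to_zero_reduces_to_suboptimal_predictor(self, htt_truth):
        T, psi, t = 24.0, np.array([-0.2]), np.array([5.0])
        x_actual = _supra_predictor(T, psi, t, htt_truth.theta_HT, htt_truth.t_b,
                                    htt_truth.t_o, 1e-12, "actual")
        x_sub = psi - htt_truth.theta_HT / ((T - htt_truth.t_b) * t)
        assert x_actual == pytest.approx(x_sub, abs=1e-9)
        # the capped convention freezes the thermal factor at T_o instead
        x_capped = _supra_predictor(T, psi, t, htt_truth.theta_HT, htt_truth.t_b,
                                    htt_truth.t_o, 1e-12, "capped")
        x_at_to = psi - htt_truth.theta_HT / ((htt_truth.t_o - htt_truth.t_b) * t)
        assert x_capped == pytest.approx(x_at_to, abs=1e-9)


class TestFitSuboptimal:
    def test_noiseless_recovery_within_grid_resolution(self, htt_truth):
        cells = noiseless_htt_cells(htt_truth)
        tcs = cells_to_timecourses(*cells)
        fit = fit_htt_suboptimal(tcs)
        assert fit.t_b == pytest.approx(htt_truth.t_b, abs=0.1)
        assert fit.theta_HT == pytest.approx(htt_truth.theta_HT, rel=0.01)
        assert fit.psi_b50 == pytest.approx(htt_truth.psi_b50, abs=0.01)
        assert fit.sigma_psib_sub == pytest.approx(htt_truth.sigma_psib_sub, abs=0.01)
        assert not fit.t_b_on_boundary

    def test_refined_and_exhaustive_search_agree(self, htt_truth):
        cells = noiseless_htt_cells(htt_truth, temps=(11.0, 20.0),
                                    days=np.array([4.0, 8.0, 16.0, 24.0]),
                                    trials=2000)
        tcs = cells_to_timecourses(*cells)
        a = fit_htt_suboptimal(tcs, t_b_search="refine")
        b = fit_htt_suboptimal(tcs, t_b_search="exhaustive")
        assert a.t_b == pytest.approx(b.t_b, abs=1e-9)
        assert a.theta_HT == pytest.approx(b.theta_HT, abs=0.01)

    def test_matches_exhaustive_grid_on_small_instance(self, htt_truth):
        """Nested profiling equals brute-force (T_b, theta) enumeration with
        an independent inner solver."""
        cells = noiseless_htt_cells(htt_truth, temps=(11.0, 20.0),
                                    psis=(0.0, -0.4),
                                    days=np.array([5.0, 15.0]), trials=2000)
        T, psi, t, s, n = cells
        assert T.size == 8
        tcs = cells_to_timecourses(*cells)
        fit = fit_htt_suboptimal(tcs)
        tb_g, theta_g, b0, b1, ll = profiled_htt_grid(
            T, psi, t, s, n, np.arange(5.0, 9.05, 0.1), np.arange(38.0, 50.0, 0.1))
        assert fit.t_b == pytest.approx(tb_g, abs=0.1)
        assert fit.theta_HT == pytest.approx(theta_g, abs=0.1)
        assert fit.fit_sub.log_likelihood >= ll - 1e-6

    def test_single_temperature_rejected(self, htt_truth):
        cells = noiseless_htt_cells(htt_truth, temps=(15.0,))
        tcs = cells_to_timecourses(*cells)
        with pytest.raises(ValueError, match="fit_ht"):
            fit_htt_suboptimal(tcs)


@pytest.fixture(scope="module")
def noiseless_full(htt_truth):
    sub_cells = noiseless_htt_cells(htt_truth)
    sub = fit_htt_suboptimal(cells_to_timecourses(*sub_cells))
    supra_rows = []
    days = np.arange(1.0, 26.0)
    trials = 10**6
    for T in (24.0, 28.0):
        for psi in PSI_LEVELS:
            x = _supra_predictor(T, psi, days, htt_truth.theta_HT,
                                 htt_truth.t_b, htt_truth.t_o,
                                 htt_truth.k_T, "capped")
            p = inverse_probit((x - htt_truth.psi_b50)
                               / htt_truth.sigma_psib_sub)
            supra_rows.append((np.full_like(days, T), np.full_like(days, psi),
                               days, np.round(trials * p), np.full_like(days, trials)))
    arrs = [np.concatenate(cols) for cols in zip(*supra_rows)]
    return sub, cells_to_timecourses(*arrs)


class TestFitSupraoptimal:
    def test_noiseless_recovery_within_grid_resolution(self, htt_truth, noiseless_full):
        sub, supra_tcs = noiseless_full
        fit = fit_htt_supraoptimal(supra_tcs, sub, t_o_bounds=(20.0, 24.0))
        assert fit.t_o == pytest.approx(htt_truth.t_o, abs=0.1)
        assert fit.k_T == pytest.approx(htt_truth.k_T, abs=0.01)
        assert fit.supra_match_ok
        assert fit.t_c50 == pytest.approx(fit.t_o - fit.psi_b50 / fit.k_T)

    def test_fit_htt_wrapper_partitions_at_fgp_maximum(self, htt_truth):
        from seedhtt import SimulationConfig, simulate_experiment
        cfg = SimulationConfig(truth=htt_truth, rng_seed=3)
        tcs, _ = simulate_experiment(cfg)
        fit = fit_htt(tcs)
        assert fit.t_o is not None
        assert abs(fit.t_o - htt_truth.t_o) <= 1.5
        assert fit.t_b < fit.t_o < fit.t_c50
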
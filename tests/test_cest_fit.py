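"""Global CEST fitting: target function, recovery, uncertainties."""

import numpy as np
import pytest

from sidechain_nmr.cest_fit import (
    FitConfig,
    FitResult,
    chi_square,
    fit_cest,
    grid_search_uncertainty,
)
from sidechain_nmr.errors import (
    ConfigurationError,
    InvalidParameterError,
    MappingError,
)
from sidechain_nmr.spin_models import (
    CestProfile,
    CestSchedule,
    GlobalExchangeParams,
    SpinExchangeParams,
    simulate_intensities,
)
from sidechain_nmr.synthetic import generate_cest_dataset

# single-B1 schedule without inhomogeneity averaging keeps test fits fast
FAST_SCHEDULE = CestSchedule(
    offsets=np.linspace(-600.0, 600.0, 50),
    b1_field=25.0,
    t_sat=0.5,
    spectrometer_freq=150.9,
    b1_inhomogeneity=0.0,
    n_b1_quadrature=1,
)

SPIN = SpinExchangeParams("V1", 1.0, -1.2, 0.2, 4.0, 6.0, 35.0)


def _profile_with_residuals(residuals, sigma=0.01):
    """Observed = simulated + the requested residuals, so chi2 is exact."""
    glob = GlobalExchangeParams(100.0, 0.02)
    sched = CestSchedule(
        offsets=np.linspace(-300, 300, len(residuals)),
        b1_field=20.0,
        t_sat=0.4,
        spectrometer_freq=150.9,
        n_b1_quadrature=1,
        b1_inhomogeneity=0.0,
    )
    calc = simulate_intensities(SPIN, glob, sched)
    prof = CestProfile(
        label=SPIN.label,
        schedule=sched,
        intensities=calc + np.asarray(residuals, dtype=float),
        sigma=np.full(len(residuals), sigma),
    )
    return prof, glob


class TestChiSquare:
    def test_perfect_model_gives_zero(self):
        prof, glob = _profile_with_residuals(np.zeros(12))
        assert chi_square([prof], glob, {SPIN.label: SPIN}) == 0.0

    def test_single_point_one_sigma_residual_gives_one(self):
        prof, glob = _profile_with_residuals(np.zeros(12))
        prof.intensities[4] += prof.sigma[4]
        assert chi_square([prof], glob, {SPIN.label: SPIN}) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_one_two_three_sigma_residuals_sum_to_fourteen(self):
        prof, glob = _profile_with_residuals(np.zeros(12))
        prof.intensities[2] += 1.0 * prof.sigma[2]
        prof.intensities[5] += 2.0 * prof.sigma[5]
        prof.intensities[9] += 3.0 * prof.sigma[9]
        assert chi_square([prof], glob, {SPIN.label: SPIN}) == pytest.approx(
            14.0, abs=1e-10
        )

    def test_unmatched_label_raises_mapping_error(self):
        prof, glob = _profile_with_residuals(np.zeros(12))
        with pytest.raises(MappingError):
            chi_square([prof], glob, {"other": SPIN})

    def test_nonpositive_sigma_rejected(self):
        prof, glob = _profile_with_residuals(np.zeros(12))
        prof.sigma[:] = 0.0
        with pytest.raises(InvalidParameterError):
            chi_square([prof], glob, {SPIN.label: SPIN})


class TestFitCest:
    def test_noiseless_data_recovers_ground_truth(self, fast_fit_config):
        truth = GlobalExchangeParams(128.0, 0.0115)
        profiles, _ = generate_cest_dataset([SPIN], truth, FAST_SCHEDULE, 0.0, 1)
        for p in profiles:
            p.sigma = np.full_like(p.intensities, 0.005)
        fit = fit_cest(profiles, fast_fit_config, j_cc=35.0)
        assert fit.global_params.k_ex == pytest.approx(128.0, rel=1e-3)
        assert fit.global_params.p_e == pytest.approx(0.0115, rel=1e-3)
        sp = fit.spin_params[SPIN.label]
        assert sp.shift_ground == pytest.approx(1.0, abs=1e-3)
        assert sp.shift_excited == pytest.approx(-1.2, abs=1e-3)
        assert sp.r2_ground == pytest.approx(4.0, rel=1e-3)

    def test_no_exchange_data_flags_unidentifiable_excited_shift(
        self, fast_fit_config
    ):
        truth = GlobalExchangeParams(0.0, 0.0)
        profiles, _ = generate_cest_dataset([SPIN], truth, FAST_SCHEDULE, 0.003, 2)
        fit = fit_cest(profiles, fast_fit_config, j_cc=35.0)
        assert "omega_e_unidentifiable" in fit.flags
        # the fitted exchange contribution stays below the noise floor:
        # removing it changes the predicted profile by less than sigma
        no_exchange = GlobalExchangeParams(0.0, 0.0)
        with_fit = simulate_intensities(
            fit.spin_params[SPIN.label], fit.global_params, FAST_SCHEDULE
        )
        without = simulate_intensities(
            fit.spin_params[SPIN.label], no_exchange, FAST_SCHEDULE
        )
        assert np.max(np.abs(with_fit - without)) <= 3.0 * 0.003

    def test_too_few_points_rejected(self):
        sched = CestSchedule(np.linspace(-300, 300, 5), 20.0, 0.4, 150.9)
        prof = CestProfile("V1", sched, np.ones(5), sigma=np.full(5, 0.01))
        with pytest.raises(ConfigurationError):
            fit_cest([prof], FitConfig())

    def test_chi2_per_dof_near_one_for_correct_noise_model(self):
        truth = GlobalExchangeParams(150.0, 0.02)
        profiles, _ = generate_cest_dataset([SPIN], truth, FAST_SCHEDULE, 0.005, 42)
        fit = fit_cest(profiles, FitConfig(), j_cc=35.0)
        assert 0.5 <= fit.reduced_chi2 <= 1.5

    def test_parameter_recovery_over_stochastic_replicates(self):
        """Median recovery error of the global pair stays below 10%."""
        rng = np.random.default_rng(0)
        errs_k, errs_p = [], []
        for rep in range(12):
            k_ex = rng.uniform(50, 500)
            p_e = rng.uniform(0.005, 0.05)
            truth = GlobalExchangeParams(k_ex, p_e)
            profiles, _ = generate_cest_dataset(
                [SPIN], truth, FAST_SCHEDULE, 0.005, 100 + rep
            )
            fit = fit_cest(profiles, FitConfig(), j_cc=35.0)
            errs_k.append(abs(fit.global_params.k_ex - k_ex) / k_ex)
            errs_p.append(abs(fit.global_params.p_e - p_e) / p_e)
        assert np.median(errs_k) <= 0.10
        assert np.median(errs_p) <= 0.10

    def test_shared_r2_never_beats_free_r2(self):
        """Nested models: constraining R2G = R2E cannot lower chi2."""
        rng = np.random.default_rng(7)
        for rep in range(3):
            spin = SpinExchangeParams(
                "X", 1.0, -1.2, 0.2, rng.uniform(3, 8), rng.uniform(5, 12), 35.0
            )
            truth = GlobalExchangeParams(rng.uniform(80, 300), rng.uniform(0.01, 0.04))
            profiles, _ = generate_cest_dataset(
                [spin], truth, FAST_SCHEDULE, 0.005, 200 + rep
            )
            shared = fit_cest(
                profiles, FitConfig(share_r2=True), j_cc=35.0
            )
            free = fit_cest(
                profiles, FitConfig(share_r2=False), j_cc=35.0,
                warm_start=shared,
            )
            assert free.chi2 <= shared.chi2 + 1e-6
            assert free.dof == shared.dof - 1


class TestGridSearch:
    @pytest.fixture(scope="class")
    def fitted(self):
        truth = GlobalExchangeParams(150.0, 0.02)
        profiles, _ = generate_cest_dataset([SPIN], truth, FAST_SCHEDULE, 0.005, 42)
        fit = fit_cest(profiles, FitConfig(), j_cc=35.0)
        return profiles, fit

    def test_surface_minimum_consistent_with_fit(self, fitted):
        profiles, fit = fitted
        k = fit.global_params.k_ex
        p = fit.global_params.p_e
        grid = grid_search_uncertainty(
            profiles, fit,
            np.linspace(0.8 * k, 1.2 * k, 5),
            np.linspace(0.9 * p, 1.1 * p, 5),
            j_cc=35.0,
        )
        assert grid.chi2_surface.min() >= fit.chi2 - 0.05
        assert grid.chi2_surface.min() <= fit.chi2 + 1.0
        assert not grid.truncated
        assert grid.region_mask.any()

    def test_confidence_region_shrinks_with_noise(self, fitted):
        profiles, fit = fitted
        k = fit.global_params.k_ex
        p = fit.global_params.p_e
        k_grid = np.linspace(0.7 * k, 1.3 * k, 5)
        p_grid = np.linspace(0.8 * p, 1.2 * p, 5)
        sizes = []
        for scale in (1.0, 0.2):
            profs = [
                CestProfile(
                    pr.label, pr.schedule,
                    # shrink residuals and stated noise by the same factor
                    simulate_intensities(
                        fit.spin_params[pr.label], fit.global_params, pr.schedule
                    ) + scale * (pr.intensities - simulate_intensities(
                        fit.spin_params[pr.label], fit.global_params, pr.schedule
                    )),
                    sigma=pr.sigma * scale,
                )
                for pr in profiles
            ]
            refit = fit_cest(profs, FitConfig(), j_cc=35.0, warm_start=fit)
            grid = grid_search_uncertainty(
                profs, refit, k_grid, p_grid, j_cc=35.0
            )
            sizes.append(int(grid.region_mask.sum()))
        assert sizes[1] <= sizes[0]
        assert sizes[1] >= 1

    def test_covariance_and_profile_widths_agree_within_factor_two(self, fitted):
        profiles, fit = fitted
        k = fit.global_params.k_ex
        p = fit.global_params.p_e
        sd_k = fit.uncertainties["k_ex"]
        sd_p = fit.uncertainties["p_e"]
        grid = grid_search_uncertainty(
            profiles, fit,
            np.linspace(k - 3 * sd_k, k + 3 * sd_k, 9),
            np.linspace(p - 3 * sd_p, p + 3 * sd_p, 9),
            j_cc=35.0,
        )
        lo, hi = grid.profile_interval("k_ex", delta_chi2=1.0)
        width_k = (hi - lo) / 2.0
        lo, hi = grid.profile_interval("p_e", delta_chi2=1.0)
        width_p = (hi - lo) / 2.0
        assert 0.5 <= width_k / sd_k <= 2.0
        assert 0.5 <= width_p / sd_p <= 2.0

    def test_grid_not_bracketing_optimum_warns_and_flags(self, fitted):
        profiles, fit = fitted
        k = fit.global_params.k_ex
        with pytest.warns(UserWarning, match="outside the grid"):
            grid = grid_search_uncertainty(
                profiles, fit,
                np.linspace(2 * k, 3 * k, 3),
                np.linspace(0.001, 0.005, 3),
                j_cc=35.0,
                max_nfev=20,
            )
        assert grid.truncated
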
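"""Multi-component distribution fitting: basis, NNLS solve, errors, sw."""

import numpy as np
import pytest
from scipy.optimize import nnls

from photosv.decomposition import (
    ComponentDistribution,
    ComponentSpec,
    SingularComponentsError,
    build_signal_basis,
    fit_conventional,
    fit_mcmc,
    monte_carlo_errors,
    sw_integrate,
)
from photosv.lamm import SedimentingSpecies, solve_lamm
from photosv.photoswitch import IlluminationProfile, Photoswitcher, ResetSchedule
from photosv.synthetic import (
    SyntheticComponent,
    SyntheticRunConfig,
    default_scan_times,
    generate_synthetic,
)

from conftest import MIX_NOISE, S_GRID, STABLE_S, SWITCH_S, TEST_DR, TEST_DT


class TestSignalBasis:
    def test_non_switching_columns_equal_lamm_solutions(self, geometry):
        """With alpha = 1 and no FRAP the basis reduces to the conventional
        c(s) basis: plain Lamm solutions scaled by eps0."""
        ps = Photoswitcher(name="stable", epsilon0=1.7, alpha=1.0, beta=0.0)
        comp = ComponentSpec("stable", ps)
        times = np.array([600.0, 2400.0])
        radii = np.linspace(6.0, 7.2, 241)
        s_grid = np.array([2.0, 4.0])
        basis = build_signal_basis(
            [comp], s_grid, geometry, times, radii, dt_max=TEST_DT
        )
        for k, s_val in enumerate(s_grid):
            chi = solve_lamm(
                SedimentingSpecies(s=s_val, loading_signal=1.0), geometry, times,
                grid=radii, dt_max=TEST_DT,
            )
            expected = 1.7 * chi.values[:, basis.mask].ravel()
            np.testing.assert_allclose(basis.matrix[:, k], expected, rtol=1e-12)
        assert basis.matrix.min() >= 0

    def test_off_switching_column_depletes(self, geometry, off_switcher):
        comp = ComponentSpec("rsEGFP2", off_switcher)
        times = np.array([600.0, 14400.0])
        radii = np.linspace(6.0, 7.2, 241)
        basis = build_signal_basis(
            [comp], np.array([2.5]), geometry, times, radii, dt_max=TEST_DT
        )
        col = basis.matrix[:, 0].reshape(2, -1)
        plateau = (basis.radii > 6.7) & (basis.radii < 6.9)
        assert col[1][plateau].mean() < col[0][plateau].mean()

    def test_zero_amplitude_frap_matches_no_frap(self, geometry, off_switcher):
        comp = ComponentSpec("rsEGFP2", off_switcher)
        times = np.array([1800.0, 3600.0])
        radii = np.linspace(6.0, 7.2, 241)
        s_grid = np.array([2.5, 4.0])
        plain = build_signal_basis(
            [comp], s_grid, geometry, times, radii, dt_max=TEST_DT
        )
        null_beam = IlluminationProfile(((0.0, 6.5, 0.05),), ())
        frap = build_signal_basis(
            [comp], s_grid, geometry, times, radii, frap=null_beam, dt_max=TEST_DT
        )
        np.testing.assert_allclose(frap.matrix, plain.matrix, atol=1e-10)

    def test_empty_component_list_rejected(self, geometry):
        with pytest.raises(ValueError, match="empty"):
            build_signal_basis(
                [], np.array([2.5]), geometry, np.array([600.0]),
                np.linspace(6.0, 7.2, 61),
            )

    def test_identical_signatures_abort(self, geometry, off_switcher):
        comps = [
            ComponentSpec("a", off_switcher),
            ComponentSpec("b", off_switcher),
        ]
        with pytest.raises(SingularComponentsError, match="'a' and 'b'"):
            build_signal_basis(
                comps, np.array([2.5]), geometry, np.array([600.0]),
                np.linspace(6.0, 7.2, 61),
            )


class TestFitMCMC:
    def test_single_species_recovery(self, geometry, stable_switcher):
        """Single stable species at 3.57 S with 0.5% noise: the recovered
        distribution integrates to the loading signal within 1% and sw is
        within 1% of truth."""
        cfg = SyntheticRunConfig(
            components=[
                SyntheticComponent(
                    SedimentingSpecies(s=3.57, loading_signal=1.0), stable_switcher
                )
            ],
            geometry=geometry,
            scan_times=default_scan_times(600.0, 21600.0),
            dr=TEST_DR, noise_sd=0.005, seed=7, dt_max=TEST_DT,
        )
        scans, _ = generate_synthetic(cfg)
        fit = fit_mcmc(
            scans, [ComponentSpec("DL488", stable_switcher)], S_GRID,
            geometry=geometry, dt_max=TEST_DT,
        )
        dist = fit.distributions["DL488"]
        assert dist.total_signal() == pytest.approx(1.0, rel=0.01)
        assert dist.sw() == pytest.approx(3.57, rel=0.01)

    def test_noise_free_fit_is_exact(self, mixture_clean, mixture_components,
                                     geometry, mixture_basis):
        scans, _ = mixture_clean
        fit = fit_mcmc(
            scans, mixture_components, S_GRID, geometry=geometry,
            dt_max=TEST_DT, basis=mixture_basis,
        )
        assert fit.rmsd < 1e-8

    def test_two_component_sw_recovery(self, mixture_fit):
        """Both components' sw recovered within 2% on the noisy mixture."""
        assert mixture_fit.sw("DL488") == pytest.approx(STABLE_S, rel=0.02)
        assert mixture_fit.sw("rsEGFP2") == pytest.approx(SWITCH_S, rel=0.02)

    def test_distribution_edge_hygiene(self, mixture_fit):
        """Less than 1% of the recovered signal sits in the outermost s-grid
        cells on well-posed data."""
        for dist in mixture_fit.distributions.values():
            total = dist.values.sum()
            edges = dist.values[0] + dist.values[-1]
            assert edges < 0.01 * total

    def test_regularization_monotonicity(self, mixture_noisy, mixture_components,
                                         geometry, mixture_basis):
        scans, _ = mixture_noisy
        rmsds = []
        for lam in (0.0, 1e-4, 1e-2, 1.0):
            fit = fit_mcmc(
                scans, mixture_components, S_GRID, geometry=geometry,
                regularization=lam, dt_max=TEST_DT, basis=mixture_basis,
            )
            rmsds.append(fit.rmsd)
        assert all(b >= a - 1e-15 for a, b in zip(rmsds, rmsds[1:]))

    def test_reduces_to_direct_nnls_cs_analysis(self, geometry, stable_switcher):
        """A single non-switching component with regularization disabled must
        reproduce a direct NNLS c(s) solve on the Lamm-solution basis."""
        cfg = SyntheticRunConfig(
            components=[
                SyntheticComponent(
                    SedimentingSpecies(s=3.5, loading_signal=1.0), stable_switcher
                )
            ],
            geometry=geometry,
            scan_times=default_scan_times(1200.0, 10800.0),
            dr=TEST_DR, noise_sd=0.01, seed=5, dt_max=TEST_DT,
        )
        scans, _ = generate_synthetic(cfg)
        s_grid = np.arange(1.0, 6.01, 0.5)
        fit = fit_mcmc(
            scans, [ComponentSpec("c", stable_switcher)], s_grid,
            geometry=geometry, regularization=0.0, baseline=False, dt_max=TEST_DT,
        )
        # independent oracle: direct NNLS on plain Lamm solutions
        mask = None
        cols = []
        for s_val in s_grid:
            chi = solve_lamm(
                SedimentingSpecies(s=s_val, loading_signal=1.0), geometry,
                scans.times, grid=scans.radii, dt_max=TEST_DT,
            )
            if mask is None:
                lo = geometry.meniscus_radius + 0.03
                hi = geometry.bottom_radius - 0.05
                mask = (scans.radii >= lo - 1e-12) & (scans.radii <= hi + 1e-12)
            cols.append(chi.values[:, mask].ravel())
        A = np.column_stack(cols)
        y = scans.to_matrix()[:, mask].ravel()
        coefs, _ = nnls(A, y)
        np.testing.assert_allclose(
            fit.distributions["c"].values, coefs, rtol=1e-6, atol=1e-9
        )

    def test_deterministic(self, mixture_noisy, mixture_components, geometry,
                           mixture_basis, mixture_fit):
        scans, _ = mixture_noisy
        again = fit_mcmc(
            scans, mixture_components, S_GRID, geometry=geometry,
            dt_max=TEST_DT, basis=mixture_basis,
        )
        assert again.rmsd == mixture_fit.rmsd
        np.testing.assert_array_equal(
            again.distributions["rsEGFP2"].values,
            mixture_fit.distributions["rsEGFP2"].values,
        )


class TestImpostorFit:
    def test_stable_data_unaffected_by_offsets(self, geometry, stable_switcher):
        cfg = SyntheticRunConfig(
            components=[
                SyntheticComponent(
                    SedimentingSpecies(s=3.5, loading_signal=1.0), stable_switcher
                )
            ],
            geometry=geometry,
            scan_times=default_scan_times(1200.0, 10800.0),
            dr=TEST_DR, dt_max=TEST_DT,
        )
        scans, _ = generate_synthetic(cfg)
        s_grid = np.arange(1.0, 6.01, 0.5)
        plain = fit_conventional(scans, s_grid, False, geometry=geometry,
                                 dt_max=TEST_DT)
        offs = fit_conventional(scans, s_grid, True, geometry=geometry,
                                dt_max=TEST_DT)
        assert np.max(np.abs(offs.per_scan_offsets)) < 1e-8
        assert offs.sw("conventional") == pytest.approx(
            plain.sw("conventional"), rel=1e-3
        )

    def test_impostor_misfit_on_switching_data(self, switching_scans, geometry,
                                               off_switcher):
        """Per-scan offsets cannot absorb the decaying boundary amplitude: the
        impostor rmsd is at least twice the matched model's."""
        matched = fit_mcmc(
            switching_scans, [ComponentSpec("rsEGFP2", off_switcher)], S_GRID,
            geometry=geometry, dt_max=TEST_DT,
        )
        impostor = fit_conventional(
            switching_scans, S_GRID, True, geometry=geometry, dt_max=TEST_DT
        )
        assert impostor.rmsd >= 2.0 * matched.rmsd
        # residuals are structured, not noise-like: the worst excursions far
        # exceed the acquisition noise the matched model fits down to
        resid = impostor.residual_matrix()
        assert np.abs(resid).max() > 5.0 * matched.rmsd

    def test_single_scan_offsets_warns(self, geometry, stable_switcher):
        cfg = SyntheticRunConfig(
            components=[
                SyntheticComponent(
                    SedimentingSpecies(s=3.5, loading_signal=1.0), stable_switcher
                )
            ],
            geometry=geometry, scan_times=np.array([3600.0]),
            dr=TEST_DR, dt_max=TEST_DT,
        )
        scans, _ = generate_synthetic(cfg)
        with pytest.warns(UserWarning, match="at least two scans"):
            fit_conventional(
                scans, np.arange(1.0, 6.01, 0.5), True, geometry=geometry,
                dt_max=TEST_DT,
            )


class TestSwIntegrate:
    def test_delta_distribution(self):
        grid = np.linspace(1.0, 5.0, 401)  # includes 2.58
        values = np.zeros(grid.size)
        values[np.argmin(np.abs(grid - 2.58))] = 3.0
        dist = ComponentDistribution(grid, values)
        assert sw_integrate(dist) == pytest.approx(2.58, abs=1e-9)

    def test_two_equal_peaks_average(self):
        """Equal-area peaks at 3.57 S and 5.11 S give sw = 4.34 S."""
        grid = np.round(np.arange(3.0, 6.01, 0.01), 10)
        values = np.zeros_like(grid)
        values[np.argmin(np.abs(grid - 3.57))] = 1.0
        values[np.argmin(np.abs(grid - 5.11))] = 1.0
        dist = ComponentDistribution(grid, values)
        assert sw_integrate(dist) == pytest.approx(4.34, abs=1e-9)

    def test_range_errors(self):
        grid = np.linspace(1.0, 5.0, 9)
        dist = ComponentDistribution(grid, np.ones(9))
        with pytest.raises(ValueError):
            sw_integrate(dist, (10.0, 12.0))
        empty = ComponentDistribution(grid, np.zeros(9))
        with pytest.raises(ValueError, match="zero integrated signal"):
            sw_integrate(empty)


class TestMonteCarlo:
    def test_same_seed_bit_identical(self, mixture_fit):
        mc1 = monte_carlo_errors(mixture_fit, n_iter=20, seed=5)
        mc2 = monte_carlo_errors(mixture_fit, n_iter=20, seed=5)
        assert mc1.sw_interval("rsEGFP2", 68) == mc2.sw_interval("rsEGFP2", 68)
        np.testing.assert_array_equal(
            mc1.cs_intervals["DL488"]["lower68"], mc2.cs_intervals["DL488"]["lower68"]
        )

    def test_width_vanishes_with_noise(self, mixture_fit):
        mc = monte_carlo_errors(mixture_fit, n_iter=10, seed=1, noise_sd=1e-12)
        lo, hi = mc.sw_interval("rsEGFP2", 68)
        assert hi - lo < 1e-6

    def test_width_scales_linearly_with_noise(self, mixture_fit):
        """Quadrupling the injected noise scales the sw interval ~4x."""
        mc1 = monte_carlo_errors(mixture_fit, n_iter=40, seed=5)
        mc4 = monte_carlo_errors(
            mixture_fit, n_iter=40, seed=5, noise_sd=4 * mixture_fit.rmsd
        )
        w1 = np.diff(mc1.sw_interval("rsEGFP2", 68))[0]
        w4 = np.diff(mc4.sw_interval("rsEGFP2", 68))[0]
        assert 2.5 < w4 / w1 < 5.5

    def test_requires_two_iterations(self, mixture_fit):
        with pytest.raises(ValueError):
            monte_carlo_errors(mixture_fit, n_iter=1, seed=0)


class TestRefinement:
    def test_beta_refinement_recovers_perturbed_rate(self, geometry, off_switcher):
        """Starting from a mis-specified switching rate, outer refinement
        recovers the true beta from noise-free single-component data."""
        cfg = SyntheticRunConfig(
            components=[
                SyntheticComponent(
                    SedimentingSpecies(s=2.5, loading_signal=1.0), off_switcher
                )
            ],
            geometry=geometry,
            scan_times=default_scan_times(1200.0, 14400.0),
            dr=TEST_DR, dt_max=TEST_DT,
        )
        scans, _ = generate_synthetic(cfg)
        wrong = Photoswitcher(
            name="rsEGFP2", epsilon0=1.0, alpha=off_switcher.alpha,
            beta=off_switcher.beta * 1.6,
        )
        comp = ComponentSpec("rsEGFP2", wrong, refine_beta=True)
        fit = fit_mcmc(
            scans, [comp], np.arange(1.5, 4.01, 0.25), geometry=geometry,
            regularization=0.0, dt_max=TEST_DT,
        )
        assert fit.refined_switchers["rsEGFP2"]["beta"] == pytest.approx(
            off_switcher.beta, rel=0.05
        )
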
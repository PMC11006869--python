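"""Lifetime-distribution analysis: grids, ridge inversion, L-curve, reduction."""

import numpy as np
import pytest

from ndqkit import kinetics_lda as lda
from ndqkit import synthetic_data as sd


class TestLifetimeGrid:
    def test_two_point_grid_is_endpoints(self):
        g = lda.build_lifetime_grid(1e-3, 1.0, 2)
        assert np.allclose(g.lifetimes, [1e-3, 1.0])

    def test_ultrafast_convention(self):
        """Ultrafast grid spans 0.03 to 5400 ps with constant log spacing."""
        g = lda.default_ultrafast_grid()
        assert g.n == 200
        assert g.lifetimes[0] == pytest.approx(0.03e-12)
        assert g.lifetimes[-1] == pytest.approx(5400e-12)
        ratios = g.lifetimes[1:] / g.lifetimes[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-12)

    def test_slow_grid_ends_at_three_times_last_point(self):
        times = np.geomspace(1e-6, 2.0, 50)
        g = lda.default_slow_grid(times)
        assert g.lifetimes[-1] == pytest.approx(6.0)
        assert g.lifetimes[0] == pytest.approx(0.0004e-3)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            lda.build_lifetime_grid(-1.0, 1.0)
        with pytest.raises(ValueError):
            lda.build_lifetime_grid(2.0, 1.0)


class TestDesignMatrix:
    def test_zero_time_row_is_ones(self):
        g = lda.build_lifetime_grid(0.1, 10.0, 5)
        A = lda.build_design_matrix(np.array([0.0, 1.0]), g)
        assert np.allclose(A[0], 1.0)

    def test_t_equals_tau_entry(self):
        g = lda.build_lifetime_grid(1.0, 10.0, 2)
        A = lda.build_design_matrix(np.array([1.0]), g)
        assert A[0, 0] == pytest.approx(np.exp(-1.0))

    def test_fuzz_against_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 5, 12))
        g = lda.build_lifetime_grid(0.01, 100.0, 7)
        A = lda.build_design_matrix(t, g)
        for i in range(len(t)):
            for j in range(g.n):
                assert A[i, j] == pytest.approx(np.exp(-t[i] / g.lifetimes[j]), rel=1e-14)

    def test_columns_strictly_decreasing(self):
        g = lda.build_lifetime_grid(0.1, 10.0, 4)
        t = np.linspace(0.0, 3.0, 10)
        A = lda.build_design_matrix(t, g)
        assert np.all(np.diff(A, axis=0) < 0)

    def test_negative_times_rejected(self):
        g = lda.build_lifetime_grid(0.1, 10.0, 3)
        with pytest.raises(ValueError):
            lda.build_design_matrix(np.array([-1.0]), g)


class TestTikhonovSolve:
    def test_large_alpha_limit(self):
        """As alpha grows, x -> A^T y / alpha^2 and its norm -> 0."""
        rng = np.random.default_rng(2)
        A = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        alpha = 1e6
        x = lda.tikhonov_solve(A, y, alpha)
        assert np.allclose(x, A.T @ y / alpha**2, rtol=1e-4)
        assert np.linalg.norm(x) < 1e-9

    def test_square_system_alpha_zero(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(6, 6)) + 3 * np.eye(6)
        y = rng.normal(size=6)
        x = lda.tikhonov_solve(A, y, 0.0)
        assert np.allclose(x, np.linalg.solve(A, y), atol=1e-8)

    def test_normal_equation_residual_on_random_systems(self):
        """Solutions satisfy (A^T A + alpha^2 I) x = A^T y to 1e-8."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            A = rng.normal(size=(20, 10))
            y = rng.normal(size=20)
            for alpha in np.geomspace(0.01, 5.0, 7):
                x = lda.tikhonov_solve(A, y, alpha)
                resid = (A.T @ A + alpha**2 * np.eye(10)) @ x - A.T @ y
                assert np.linalg.norm(resid) < 1e-8

    def test_rank_deficient_alpha_zero_falls_back_to_min_norm(self):
        A = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        y = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="rank-deficient"):
            x = lda.tikhonov_solve(A, y, 0.0)
        assert np.allclose(x, np.linalg.lstsq(A, y, rcond=None)[0])


class TestRegularizationPath:
    def test_default_alpha_grid(self):
        """200 log-spaced factors from 0.01 to 5."""
        rng = np.random.default_rng(5)
        A = rng.normal(size=(15, 8))
        y = rng.normal(size=15)
        p = lda.regularization_path(A, y)
        assert len(p.alphas) == 200
        assert p.alphas[0] == pytest.approx(0.01)
        assert p.alphas[-1] == pytest.approx(5.0)

    def test_norm_monotonicity(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(25, 12))
        y = rng.normal(size=25)
        p = lda.regularization_path(A, y)
        assert np.all(np.diff(p.residual_norms) >= -1e-10)
        assert np.all(np.diff(p.solution_norms) <= 1e-10)

    def test_norms_match_independent_recomputation(self):
        """Path norms equal a direct per-alpha normal-equation solve."""
        rng = np.random.default_rng(7)
        A = rng.normal(size=(18, 9))
        y = rng.normal(size=18)
        p = lda.regularization_path(A, y, m=25)
        for k, alpha in enumerate(p.alphas):
            x = lda.tikhonov_solve(A, y, alpha)
            assert p.residual_norms[k] == pytest.approx(np.linalg.norm(A @ x - y), rel=1e-8)
            assert p.solution_norms[k] == pytest.approx(np.linalg.norm(x), rel=1e-8)

    def test_invalid_alpha_min_rejected(self):
        with pytest.raises(ValueError):
            lda.regularization_path(np.eye(3), np.ones(3), alpha_min=0.0)


class TestLCurveCorner:
    def test_constructed_corner_found(self):
        """Two straight log-log segments meeting at one point: corner at the joint."""
        alphas = np.geomspace(1e-3, 1e3, 61)
        # residual flat then rising; solution falling then flat -> corner at idx 30
        lr = np.where(np.arange(61) < 30, 0.0, (np.arange(61) - 30) * 0.2)
        ls = np.where(np.arange(61) < 30, (30 - np.arange(61)) * 0.2, 0.0)
        path = lda.RegularizationPath(
            alphas=alphas, residual_norms=np.exp(lr), solution_norms=np.exp(ls)
        )
        a = lda.l_curve_corner(path)
        assert abs(path.chosen_index - 30) <= 1

    def test_matches_fine_grid_curvature_oracle(self):
        """Corner of an ill-posed single-exponential inversion matches a
        brute-force curvature maximization on the same path points."""
        t = np.geomspace(1e-3, 10.0, 80)
        g = lda.build_lifetime_grid(1e-4, 100.0, 60)
        A = lda.build_design_matrix(t, g)
        rng = np.random.default_rng(8)
        y = np.exp(-t / 0.5) + rng.normal(0, 0.01, t.size)
        p = lda.regularization_path(A, y, m=200)
        chosen = lda.l_curve_corner(p)
        # oracle: independent curvature computation on the discrete path
        lx, ly = np.log(p.residual_norms), np.log(p.solution_norms)
        tt = np.log(p.alphas)
        dx, dy = np.gradient(lx, tt), np.gradient(ly, tt)
        ddx, ddy = np.gradient(dx, tt), np.gradient(dy, tt)
        kappa = (dx * ddy - dy * ddx) / (dx**2 + dy**2) ** 1.5
        kappa[0] = kappa[-1] = -np.inf
        assert abs(p.chosen_index - int(np.argmax(kappa))) <= 1
        assert chosen == pytest.approx(p.alphas[p.chosen_index])

    def test_pure_noise_is_not_overfit(self):
        """On pure-noise data the corner never fits the noise.

        The exponential kernel's singular values decay geometrically, so a
        noise-only L-curve bends gently rather than forming a sharp corner;
        the location of the curvature maximum varies between realizations,
        but the chosen solution must leave the bulk of the noise in the
        residual rather than absorbing it.
        """
        t = np.geomspace(1e-3, 10.0, 60)
        g = lda.build_lifetime_grid(1e-4, 100.0, 50)
        A = lda.build_design_matrix(t, g)
        for seed in range(50):
            y = np.random.default_rng(seed).normal(0, 1.0, t.size)
            p = lda.regularization_path(A, y, m=60)
            lda.l_curve_corner(p)
            assert p.residual_norms[p.chosen_index] >= 0.7 * np.linalg.norm(y)

    def test_flat_curve_falls_back_to_median(self):
        alphas = np.geomspace(0.01, 5, 21)
        path = lda.RegularizationPath(
            alphas=alphas, residual_norms=np.ones(21), solution_norms=np.ones(21)
        )
        with pytest.warns(UserWarning, match="flat"):
            a = lda.l_curve_corner(path)
        assert a == pytest.approx(alphas[10])


def _single_exp_dataset(tau=1e-3, noise=0.0, seed=0):
    scheme = sd.PhotocycleScheme(
        intermediate_names=("I1",),
        lifetimes=(tau,),
        band_centers=(620.0,),
        band_widths=(35.0,),
        band_amplitudes=(1.0,),
        ground_center=535.5,
        ground_width=40.0,
        ground_amplitude=1.0,
    )
    cfg = sd.SimulationConfig(
        seed=seed, noise_sigma=noise, time_grid=(1e-5, 15, 1e-6, 1.0),
        wavelength_grid=(420, 660, 40),
    )
    return sd.simulate_transient_dataset(scheme, cfg)


class TestComputeLdm:
    def test_noise_free_single_exponential_peaks_at_planted_tau(self):
        """Every informative wavelength's distribution peaks within one grid
        step of the planted lifetime."""
        ds = _single_exp_dataset()
        ldm = lda.compute_ldm(ds)
        step = ldm.grid.log_step
        for i, w in enumerate(ds.wavelengths):
            if np.abs(ds.delta_A[:, i]).max() < 1e-9:
                continue
            j = np.argmax(np.abs(ldm.amplitudes[:, i]))
            assert abs(np.log10(ldm.grid.lifetimes[j] / 1e-3)) <= step

    def test_amplitude_signs_follow_difference_spectrum(self):
        """Ground-bleach wavelengths give negative lobes, photoproduct positive."""
        ds = _single_exp_dataset()
        ldm = lda.compute_ldm(ds)
        # 540 nm: near the parent band, S_i - S_g < 0 -> negative amplitude
        d_bleach = ldm.distribution(540.0)
        j = np.argmax(np.abs(d_bleach))
        assert d_bleach[j] < 0
        # 620 nm: photoproduct band dominates -> positive amplitude
        d_prod = ldm.distribution(620.0)
        j = np.argmax(np.abs(d_prod))
        assert d_prod[j] > 0

    def test_two_exponentials_resolved(self, two_state_scheme):
        """tau ratio 100 at SNR 100: two peaks at an informative wavelength."""
        cfg = sd.SimulationConfig(
            seed=1, noise_sigma=0.01, time_grid=(1e-5, 20, 1e-6, 2.0),
            wavelength_grid=(380, 660, 40),
        )
        ds = sd.simulate_transient_dataset(two_state_scheme, cfg)
        ldm = lda.compute_ldm(ds)
        step = ldm.grid.log_step
        for tau in two_state_scheme.lifetimes:
            hit = False
            for w in ds.wavelengths:
                for tp, _ in lda.peak_lifetimes(ldm, w):
                    if abs(np.log10(tp / tau)) <= step:
                        hit = True
            assert hit, f"lifetime {tau} not recovered"

    def test_reconstruction_residual_tracks_noise(self):
        """||Ax - y|| / ||y|| at the chosen alpha stays within 1.5x the noise."""
        ds = _single_exp_dataset(noise=0.01, seed=3)
        ldm = lda.compute_ldm(ds)
        keep = ds.times > 0
        i = int(np.argmin(np.abs(ds.wavelengths - 620.0)))
        y = ds.delta_A[keep, i]
        noise_level = 0.01 * np.sqrt(y.size)
        assert ldm.residuals[i] <= 1.5 * noise_level

    def test_global_mode_uses_one_alpha(self):
        ds = _single_exp_dataset(noise=0.005, seed=4)
        ldm = lda.compute_ldm(ds, mode="global")
        assert np.all(ldm.chosen_alphas == ldm.chosen_alphas[0])

    def test_all_nan_column_rejected(self):
        ds = _single_exp_dataset()
        ds.delta_A[:, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            lda.compute_ldm(ds)


class TestPeakLifetimes:
    def test_zero_distribution_gives_empty_list(self):
        g = lda.build_lifetime_grid(1e-4, 1.0, 30)
        ldm = lda.LifetimeDistributionMap(
            grid=g, wavelengths=np.array([500.0]),
            amplitudes=np.zeros((30, 1)), chosen_alphas=np.array([0.1]),
            residuals=np.array([0.0]),
        )
        assert lda.peak_lifetimes(ldm, 500.0) == []

    def test_double_peak_returned_sorted(self):
        g = lda.build_lifetime_grid(1e-4, 1.0, 50)
        x = np.zeros(50)
        x[10] = 1.0
        x[40] = -1.0
        ldm = lda.LifetimeDistributionMap(
            grid=g, wavelengths=np.array([500.0]),
            amplitudes=x[:, None], chosen_alphas=np.array([0.1]),
            residuals=np.array([0.0]),
        )
        peaks = lda.peak_lifetimes(ldm, 500.0)
        assert len(peaks) == 2
        assert peaks[0][0] < peaks[1][0]
        assert peaks[0][1] == 1.0 and peaks[1][1] == -1.0


class TestReduceTransient:
    def test_constant_signal_unchanged(self):
        t = np.geomspace(1e-6, 1.0, 500)
        v = np.full(500, 2.5)
        rt, rv = lda.reduce_transient(t, v, 1e-5, 10)
        assert np.allclose(rv, 2.5)

    def test_bin_average(self):
        """Three points in one log bin average to their mean."""
        t = np.array([0.5, 1.1, 1.2, 1.3])
        v = np.array([7.0, 1.0, 2.0, 3.0])
        rt, rv = lda.reduce_transient(t, v, 1.0, 1)
        assert rv[0] == 7.0          # linear segment passes through
        assert rv[1] == pytest.approx(2.0)
        assert rt[1] == pytest.approx(1.2)

    def test_reduction_preserves_lda_recovery(self):
        """Forward-averaged exponential still inverts to the planted lifetime."""
        rng = np.random.default_rng(9)
        t = np.sort(rng.uniform(1e-6, 2.0, 4000))
        y = np.exp(-t / 0.01) + rng.normal(0, 0.01, t.size)
        rt, ry = lda.reduce_transient(t, y, 1e-5, 15)
        assert rt.size < 400
        g = lda.default_slow_grid(rt)
        A = lda.build_design_matrix(rt, g)
        p = lda.regularization_path(A, ry)
        lda.l_curve_corner(p)
        x = p.solutions[p.chosen_index]
        j = np.argmax(np.abs(x))
        assert abs(np.log10(g.lifetimes[j] / 0.01)) <= g.log_step

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            lda.reduce_transient(np.array([1.0, 0.5]), np.array([1.0, 2.0]), 0.1, 5)


class TestNormalizeAtTime:
    def test_identical_transients_get_unit_factors(self):
        t = np.geomspace(1e-5, 1.0, 50)
        v = np.exp(-t / 0.01)
        scaled, factors = lda.normalize_at_time([(t, v), (t, v.copy())], 1e-4)
        assert np.allclose(factors, 1.0)

    def test_triple_amplitude_gets_one_third_factor(self):
        t = np.geomspace(1e-5, 1.0, 50)
        v = np.exp(-t / 0.01)
        scaled, factors = lda.normalize_at_time([(t, v), (t, 3 * v)], 1e-4)
        assert factors[1] == pytest.approx(1.0 / 3.0)
        assert np.allclose(scaled[1][1], v)

    def test_interpolation_matches_oracle(self):
        t = np.array([0.0, 1.0, 2.0])
        v = np.array([0.0, 10.0, 20.0])
        scaled, factors = lda.normalize_at_time([(t, v), (t, v * 2)], 0.5)
        # value at 0.5 by linear interpolation is 5 (first) and 10 (second)
        assert factors[1] == pytest.approx(0.5)

    def test_zero_at_reference_rejected(self):
        t = np.array([0.0, 1.0])
        with pytest.raises(ValueError, match="zero"):
            lda.normalize_at_time([(t, np.zeros(2))], 0.5)

    def test_uncovered_reference_rejected(self):
        t = np.array([1.0, 2.0])
        with pytest.raises(ValueError, match="cover"):
            lda.normalize_at_time([(t, np.ones(2))], 0.5)


class TestTransientIO:
    def test_csv_roundtrip(self, tmp_path):
        ds = _single_exp_dataset(noise=0.01, seed=5)
        path = tmp_path / "ta.csv"
        lda.write_transient_csv(ds, path)
        back = lda.read_transient_csv(path)
        assert np.allclose(back.times, ds.times)
        assert np.allclose(back.wavelengths, ds.wavelengths)
        assert np.allclose(back.delta_A, ds.delta_A)
        assert back.metadata["seed"] == 5
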
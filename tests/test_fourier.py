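import numpy as np
import pytest
from scipy import optimize

from gridfield.arena import ArenaConfig
from gridfield.fourier import (
    HEX_COEFFICIENTS,
    KLattice,
    alignment_distribution,
    degeneracy_counts,
    hex_objective,
    hex_wavevectors,
    k_dagger,
    pca_solutions,
    r_hat,
    scan_1d,
    spacing_bound,
    square_lattice_max,
)
from gridfield.steady_state import tuning_kernel


class TestTuningTransform:
    def test_zero_at_origin_and_infinity(self):
        assert r_hat(0.0, 2.0, 4.0) == pytest.approx(0.0)
        assert r_hat(1e3, 2.0, 4.0) == pytest.approx(0.0, abs=1e-12)

    def test_invalid_widths(self):
        with pytest.raises(ValueError):
            r_hat(1.0, 4.0, 2.0)
        with pytest.raises(ValueError):
            k_dagger(2.0, 2.0)

    def test_fft_of_rasterised_kernel_matches_closed_form(self):
        arena = ArenaConfig(side_length=100.0, boundary="periodic", grid_resolution=64)
        ker = tuning_kernel(arena, "dog", 3.75, 7.5)
        F = np.abs(np.fft.fft2(ker))
        kx = 2 * np.pi * np.fft.fftfreq(64, d=arena.pixel_size)
        kk = np.hypot(*np.meshgrid(kx, kx, indexing="ij"))
        mask = (kk > 0) & (kk < 0.8)
        pred = r_hat(kk[mask], 3.75, 7.5)
        corr = np.corrcoef(F[mask], pred)[0, 1]
        assert corr > 0.999  # proportional up to a constant factor


class TestKDagger:
    def test_closed_form_matches_brute_force(self):
        for s1, s2 in [(3.75, 7.5), (2.0, 9.0), (1.0, 1.5)]:
            ks = np.linspace(1e-4, 5.0 / s1, 400_001)
            brute = ks[np.argmax(r_hat(ks, s1, s2))]
            assert k_dagger(s1, s2) == pytest.approx(brute, abs=1e-5)

    def test_known_value(self):
        assert k_dagger(3.75, 7.5) == pytest.approx(
            np.sqrt(2 * np.log(4.0) / (7.5**2 - 3.75**2)), rel=1e-12
        )
        assert k_dagger(3.75, 7.5) == pytest.approx(0.2564, abs=1e-4)

    def test_scaling_with_width(self):
        base = k_dagger(3.0, 6.0)
        assert k_dagger(6.0, 12.0) == pytest.approx(base / 2.0, rel=1e-12)

    def test_spacing_bound_values(self):
        kd = k_dagger(3.75, 7.5)
        assert spacing_bound(kd) == pytest.approx(4 * np.pi / (np.sqrt(3) * kd), rel=1e-12)
        assert spacing_bound(kd) == pytest.approx(28.3, abs=0.05)
        assert spacing_bound(2 * kd) == pytest.approx(spacing_bound(kd) / 2, rel=1e-12)
        with pytest.raises(ValueError):
            spacing_bound(0.0)


class TestPcaSolutions:
    def test_generic_orbit_has_eight_points(self):
        # widths putting the peak nearest the (4,1)-type radius
        lat = KLattice(100.0, 0.5)
        pts, orbits = pca_solutions(lat, 3.75, 7.5)
        assert len(pts) == 8
        assert [len(o) for o in orbits] == [8]

    def test_axis_orbit_has_four_points(self):
        lat = KLattice(100.0, 0.5)
        pts, orbits = pca_solutions(lat, 3.9, 7.8)
        assert len(pts) == 4
        assert sorted(map(tuple, pts)) == [(-4, 0), (0, -4), (0, 4), (4, 0)]

    def test_degeneracy_always_multiple_of_four(self):
        counts = degeneracy_counts(KLattice(100.0, 1.0))
        assert len(counts) > 30  # exhaustive over all radii below k_max
        assert all(v % 4 == 0 for v in counts.values())


class TestScan1d:
    def test_single_component_closed_form(self):
        # optimum at 2*J1 = J0, norm 6 J1^2 = 1 -> objective 1/6
        res = scan_1d(1)
        assert res.objective == pytest.approx(1.0 / 6.0, abs=1e-6)
        a0, a1 = res.coefficients
        assert a0 == pytest.approx(2 * abs(a1), abs=1e-5)
        assert 6 * a1**2 == pytest.approx(1.0, abs=1e-5)

    def test_two_and_three_component_optima(self):
        assert scan_1d(2).objective == pytest.approx(0.2367, abs=2e-4)
        assert scan_1d(3).objective == pytest.approx(0.2457, abs=2e-4)

    def test_monotone_in_components_and_saturating(self):
        objs = [scan_1d(M).objective for M in (1, 2, 3, 4)]
        assert np.all(np.diff(objs) >= -1e-9)
        assert objs[3] - objs[2] < 1e-3  # extra harmonics contribute little

    def test_solutions_are_feasible(self):
        for M in (1, 2, 3):
            res = scan_1d(M)
            assert res.min_value > -1e-7
            a = res.coefficients
            assert a[0] ** 2 + 2 * np.sum(a[1:] ** 2) == pytest.approx(1.0, abs=1e-8)

    def test_invalid_component_count(self):
        with pytest.raises(ValueError):
            scan_1d(0)

    def test_non_harmonic_frequencies_do_not_beat_harmonic_scan(self):
        """Spot-check of the harmonic-form assumption: optimising the
        amplitudes at perturbed (non-harmonic) frequencies never improves
        on the harmonic M=3 optimum."""
        best_harmonic = scan_1d(3).objective
        x = np.linspace(0, 2 * np.pi * 6, 1024, endpoint=False)
        rng = np.random.default_rng(0)
        for _ in range(4):
            freqs = np.array([1.0, 2.0, 3.0]) + rng.uniform(0.1, 0.45, 3)

            def reconstruct(a):
                return a[0] + 2 * sum(a[m + 1] * np.cos(freqs[m] * x) for m in range(3))

            cons = [
                {"type": "eq", "fun": lambda a: a[0] ** 2 + 2 * np.sum(a[1:] ** 2) - 1},
                {"type": "ineq", "fun": reconstruct},
                {"type": "ineq", "fun": lambda a: a[0]},
            ]
            res = optimize.minimize(lambda a: -a[1] ** 2, [0.8, 0.3, 0.1, 0.1],
                                    method="SLSQP", constraints=cons,
                                    options={"maxiter": 300})
            if res.success and reconstruct(res.x).min() > -1e-8:
                assert -res.fun <= best_harmonic + 1e-3


class TestLatticeTypes:
    def test_printed_hexagonal_solution(self):
        sol = hex_objective()
        assert sol.objective == pytest.approx(0.2558, abs=5e-4)
        assert sol.norm_sq == pytest.approx(1.0, abs=5e-4)
        assert sol.nonnegative

    def test_hex_norm_identity_by_direct_sum(self):
        a = HEX_COEFFICIENTS
        direct = a[0] ** 2 + 2 * (3 * 0.292**2 + 3 * 0.0101**2 + 2 * 0.134**2)
        assert a[0] ** 2 + 2 * np.sum(a[1:] ** 2) == pytest.approx(direct, rel=1e-12)

    def test_dc_only_solution_scores_zero(self):
        sol = hex_objective(np.array([1.0] + [0.0] * 8))
        assert sol.objective == 0.0
        assert sol.nonnegative

    def test_hex_wavevector_geometry(self):
        # base hexagon at radius kd, second harmonics at 2 kd; the last two
        # cross terms fold back onto the base ring (k1+k2 = -k3 for a basis
        # 120 degrees apart)
        ks = hex_wavevectors(2.0)
        assert np.allclose(np.linalg.norm(ks[:3], axis=1), 2.0)
        assert np.allclose(np.linalg.norm(ks[3:6], axis=1), 4.0)
        assert np.allclose(ks[6], -ks[2]) and np.allclose(ks[7], -ks[1])

    def test_square_lattice_bounded_and_beaten_by_hexagon(self):
        sq = square_lattice_max(seed=0)
        assert sq.objective <= 0.25 + 1e-3
        assert sq.min_value > -1e-7
        assert hex_objective().objective > 0.25  # hexagon beats the bound
        # the 1D three-component optimum respects the same bound
        assert scan_1d(3).objective <= 0.25


class TestAlignmentDistribution:
    def test_uniform_draws_have_mean_near_midpoint(self, rng):
        a = rng.uniform(0, 15, 500)
        out = alignment_distribution(a)
        assert out["mean"] == pytest.approx(7.5, abs=0.8)
        assert out["ks_pvalue"] > 0.01

    def test_degenerate_sample_rejected_as_uniform(self):
        out = alignment_distribution(np.full(50, 7.5))
        assert out["ks_pvalue"] < 1e-6

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            alignment_distribution(np.arange(5))
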
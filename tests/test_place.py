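import numpy as np
import pytest

from gridfield.arena import ArenaConfig, Trajectory, generate_trajectory
from gridfield.place import (
    PlaceEnsemble,
    adaptation_filter,
    disk_outer_amplitude,
    eval_tuning,
    stream_from_trajectory,
    temporal_derivative,
)


class TestTuningCurves:
    def test_gaussian_peaks_at_one_on_centre(self, small_arena):
        ens = PlaceEnsemble(small_arena, centers=[[10.0, 10.0]], kind="gaussian", sigma1=2.0)
        act = eval_tuning(ens, [10.0, 10.0])
        assert act[0] == pytest.approx(1.0)
        assert np.all(ens.eval(np.random.default_rng(0).uniform(0, 40, (2, 50)).T) <= 1.0)

    def test_dog_raster_integral_is_zero(self, small_dog_ensemble):
        rasters = small_dog_ensemble.rasters()
        for r in rasters[:3]:
            assert abs(r.sum()) < 1e-6 * np.abs(r).sum()

    def test_dog_amplitude_ratio_matches_2d_zero_integral(self):
        # in 2D the zero-integral condition is c1 sigma1^2 = c2 sigma2^2
        arena = ArenaConfig(side_length=200.0, grid_resolution=128)
        ens = PlaceEnsemble(arena, centers=[[100.0, 100.0]], kind="dog",
                            sigma1=3.0, sigma2=6.0)
        c1, c2 = ens.amplitudes
        assert c1 / c2 == pytest.approx((6.0 / 3.0) ** 2, rel=1e-3)

    def test_dog_equal_widths_rejected(self, small_arena):
        with pytest.raises(ValueError):
            PlaceEnsemble(small_arena, centers=[[1.0, 1.0]], kind="dog",
                          sigma1=2.0, sigma2=2.0)

    def test_translation_invariance_periodic(self, small_arena):
        rng = np.random.default_rng(1)
        centers = rng.uniform(0, 40, (6, 2))
        pts = rng.uniform(0, 40, (9, 2))
        d = np.array([13.7, 29.2])
        a = PlaceEnsemble(small_arena, centers=centers, kind="gaussian", sigma1=3.0)
        b = PlaceEnsemble(small_arena, centers=(centers + d) % 40.0, kind="gaussian", sigma1=3.0)
        assert np.allclose(a.eval(pts), b.eval((pts + d) % 40.0), atol=1e-12)


class TestDisk:
    def test_outer_amplitude_solves_zero_integral(self):
        # inner radius r, outer R, inner amplitude 1 -> outer -r^2/(R^2-r^2)
        assert disk_outer_amplitude(1.0, 2.0) == pytest.approx(-1.0 / 3.0)
        r, R = 1.5, 3.7
        a_out = disk_outer_amplitude(r, R)
        assert a_out * np.pi * (R**2 - r**2) + np.pi * r**2 == pytest.approx(0.0)

    def test_disk_values(self, small_arena):
        ens = PlaceEnsemble(small_arena, centers=[[20.0, 20.0]], kind="disk",
                            sigma1=2.0, sigma2=4.0)
        assert eval_tuning(ens, [20.0, 20.0])[0] == pytest.approx(1.0)  # centre
        assert eval_tuning(ens, [23.0, 20.0])[0] == pytest.approx(-1.0 / 3.0)  # ring
        assert eval_tuning(ens, [30.0, 20.0])[0] == 0.0  # outside

    def test_degenerate_radii_rejected(self):
        with pytest.raises(ValueError):
            disk_outer_amplitude(2.0, 2.0)


class TestStreams:
    def test_stream_shape_and_values(self, small_dog_ensemble, small_arena):
        traj = generate_trajectory(small_arena, steps=40, seed=0)
        stream = stream_from_trajectory(small_dog_ensemble, traj)
        assert stream.activities.shape == (25, 40)
        col7 = small_dog_ensemble.eval(traj.positions[7:8])[:, 0]
        assert np.allclose(stream.activities[:, 7], col7)

    def test_stationary_agent_constant_activity(self, small_arena):
        ens = PlaceEnsemble(small_arena, centers=[[5.0, 5.0]], kind="gaussian", sigma1=2.0)
        traj = Trajectory(positions=np.tile([5.0, 5.0], (10, 1)))
        stream = stream_from_trajectory(ens, traj)
        assert np.allclose(stream.activities, 1.0)

    def test_dog_stream_mean_vanishes_on_long_walks(self, small_dog_ensemble, small_arena):
        traj = generate_trajectory(small_arena, steps=100_000, speed=1.0, seed=3)
        stream = stream_from_trajectory(small_dog_ensemble, traj)
        means = stream.activities.mean(axis=1)
        # tolerance scales as 1/sqrt(T_eff); the walk decorrelates in ~ sigma/speed steps
        assert np.abs(means).max() < 0.02


class TestTemporalDerivative:
    def test_constant_input_gives_zero(self):
        from gridfield.place import InputStream

        stream = InputStream(np.ones((3, 10)))
        out = temporal_derivative(stream)
        assert out.activities.shape == (3, 9)
        assert np.allclose(out.activities, 0.0)

    def test_needs_two_steps(self):
        from gridfield.place import InputStream

        with pytest.raises(ValueError):
            temporal_derivative(InputStream(np.ones((3, 1))))

    def test_zero_mean_for_isotropic_walk(self, small_dog_ensemble, small_arena):
        traj = generate_trajectory(small_arena, steps=50_000, speed=1.0, seed=5)
        stream = temporal_derivative(stream_from_trajectory(small_dog_ensemble, traj))
        means = stream.activities.mean(axis=1)
        se = stream.activities.std(axis=1) / np.sqrt(stream.activities.shape[1])
        assert np.all(np.abs(means) < 5 * np.maximum(se, 1e-12))


class TestAdaptationFilter:
    def test_delta_one_removes_everything(self, rng):
        psi = rng.uniform(0, 1, 200)
        assert np.allclose(adaptation_filter(psi, 1.0), 0.0)

    def test_small_delta_limit_passes_signal(self, rng):
        psi = rng.uniform(0, 1, 50)
        out = adaptation_filter(psi, 1e-9)
        assert np.allclose(out, psi, atol=1e-6)

    def test_iid_input_mean_tends_to_zero(self, rng):
        psi = rng.uniform(0, 1, 100_000)
        out = adaptation_filter(psi, 0.01)
        se = out.std() / np.sqrt(len(out) / (2 / 0.01))  # ~1/delta correlation time
        assert abs(out.mean()) < 3 * se + 1e-3

    def test_delta_out_of_range(self):
        with pytest.raises(ValueError):
            adaptation_filter(np.ones(5), 0.0)
        with pytest.raises(ValueError):
            adaptation_filter(np.ones(5), 1.5)
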
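import numpy as np
import pytest

from gridfield.arena import generate_trajectory
from gridfield.hebbian import (
    LearningSchedule,
    oja_step,
    output_activity,
    sanger_step,
    train,
)
from gridfield.place import InputStream, stream_from_trajectory


def gaussian_stream(cov_diag, T, seed):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((len(cov_diag), T)) * np.sqrt(np.asarray(cov_diag))[:, None]
    return InputStream(data)


class TestOutputActivity:
    def test_one_hot_selects_input(self):
        r = np.array([3.0, -1.0, 2.0])
        assert output_activity(np.array([0.0, 1.0, 0.0]), r) == pytest.approx(-1.0)

    def test_zero_input_gives_zero(self):
        assert output_activity(np.ones(4), np.zeros(4)) == 0.0
        assert output_activity(np.ones(4), np.zeros(4), "tanh") == 0.0

    def test_linear_arithmetic(self):
        assert output_activity(np.array([0.6, 0.8]), np.array([1.0, 1.0])) == pytest.approx(1.4)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            output_activity(np.ones(3), np.ones(4))


class TestOjaStep:
    def test_orthogonal_input_leaves_weights(self):
        J = np.array([1.0, 0.0])
        r = np.array([0.0, 2.0])
        assert np.allclose(oja_step(J, r, 0.1), J)

    def test_rectification_clips_at_zero(self):
        J = np.array([0.01, 0.5])
        r = np.array([-5.0, 1.0])
        out = oja_step(J, r, 0.5, nonneg=True)
        assert out.min() >= 0.0

    def test_eigenvector_is_stationary_in_expectation(self, rng):
        # E[dJ] = eps (Sigma J - (J' Sigma J) J) = 0 for a unit eigenvector
        cov = np.diag([2.0, 1.0])
        J = np.array([1.0, 0.0])
        r = rng.multivariate_normal([0, 0], cov, size=200_000)
        updates = np.array([oja_step(J, x, 1e-3) - J for x in r[:5_000]])
        assert np.abs(updates.mean(axis=0)).max() < 1e-4

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            oja_step(np.array([np.nan, 1.0]), np.ones(2), 0.1)


class TestSangerStep:
    def test_single_output_reduces_to_oja(self, rng):
        J = rng.random(6)
        r = rng.standard_normal(6)
        assert np.allclose(sanger_step(J, r, 0.05)[0], oja_step(J, r, 0.05))

    def test_rows_converge_to_ordered_eigenvectors(self):
        stream = gaussian_stream([3.0, 2.0, 1.0], 150_000, seed=2)
        res = train(stream, n_outputs=3, seed=0, schedule=LearningSchedule(0.05, 2e4))
        for i in range(3):
            e = np.zeros(3)
            e[i] = 1.0
            assert abs(res.J[i] @ e) > 0.98, f"row {i} not aligned with eigenvector {i}"

    def test_unconstrained_rows_span_top_eigenspace(self):
        # subspace angle between learned rows and the top-2 eigenspace < 5 deg
        stream = gaussian_stream([4.0, 3.0, 0.2, 0.1], 120_000, seed=3)
        res = train(stream, n_outputs=2, seed=1, schedule=LearningSchedule(0.05, 2e4))
        q, _ = np.linalg.qr(res.J.T)
        top = np.eye(4)[:, :2]
        sv = np.linalg.svd(q.T @ top, compute_uv=False)
        angle = np.degrees(np.arccos(np.clip(sv.min(), 0, 1)))
        assert angle < 5.0


class TestTrain:
    def test_zero_stream_leaves_weights(self):
        stream = InputStream(np.zeros((4, 100)))
        res = train(stream, seed=0)
        assert np.allclose(np.linalg.norm(res.J[0]), 1.0)

    def test_oja_finds_principal_component(self):
        # fast-decaying rate so the stationary fluctuation sqrt(eps) is
        # below the 0.05 tolerance of the eigendecomposition oracle
        stream = gaussian_stream([2.0, 1.0], 150_000, seed=4)
        res = train(stream, seed=2, schedule=LearningSchedule(0.05, 5e3))
        J = res.J[0]
        assert abs(abs(J[0]) - 1.0) < 0.05 and abs(J[1]) < 0.05

    def test_self_normalisation_from_off_norm_starts(self, rng):
        # Oja drives ||J|| -> 1 from 0.5 or 1.5
        cov = np.diag([2.0, 1.0])
        data = rng.multivariate_normal([0, 0], cov, size=60_000)
        for norm0 in (0.5, 1.5):
            J = rng.standard_normal(2)
            J *= norm0 / np.linalg.norm(J)
            for t, x in enumerate(data):
                J = oja_step(J, x, 0.05 / (1 + t / 1e4))
            assert np.linalg.norm(J) == pytest.approx(1.0, abs=0.05)

    def test_nonneg_invariant_holds_throughout(self, small_dog_ensemble, small_arena):
        traj = generate_trajectory(small_arena, steps=5000, seed=6)
        stream = stream_from_trajectory(small_dog_ensemble, traj)
        res = train(stream, nonneg=True, seed=3)
        assert res.J.min() >= 0.0

    def test_divergence_aborts(self):
        stream = InputStream(np.full((2, 5000), 10.0))
        with pytest.raises(RuntimeError, match="diverged"):
            train(stream, seed=0, schedule=LearningSchedule(5.0, 1e9))

    def test_fast_and_generic_paths_agree(self, small_dog_ensemble, small_arena):
        """The compiled separable-DoG trainer and the generic stream trainer
        implement the same update rule."""
        traj = generate_trajectory(small_arena, steps=3000, seed=8)
        fast = train(small_dog_ensemble, traj, nonneg=True, seed=5)
        stream = stream_from_trajectory(small_dog_ensemble, traj)
        slow = train(stream, nonneg=True, seed=5)
        assert np.allclose(fast.J, slow.J, atol=1e-10)

    def test_adaptation_keeps_constant_input_in_check(self):
        # with adaptation, a constant (non-zero-mean) stream yields psi -> 0
        stream = InputStream(np.ones((3, 20_000)))
        res = train(stream, seed=1, adaptation_delta=0.05,
                    schedule=LearningSchedule(0.01, 1e4))
        assert np.linalg.norm(res.J[0]) < 10.0  # no divergence
        assert res.delta_history[-1] < res.delta_history[0]


class TestCheckpointsAndShapedInit:
    def test_weight_checkpoint_round_trip(self, tmp_path, rng):
        from gridfield.hebbian import TrainResult, load_weights, save_weights

        J = rng.random((2, 9))
        res = TrainResult(J=J, norm_history=np.empty((0, 2)),
                          delta_history=np.empty(0), converged=True, steps_run=123)
        path = tmp_path / "weights.txt"
        save_weights(path, res, seed=7, eps0=0.05)
        assert np.allclose(load_weights(path), J, atol=1e-9)
        header = path.read_text().splitlines()[0]
        assert "seed=7" in header and "steps=123" in header

    def test_weights_from_map_encodes_the_pattern(self, small_dog_ensemble):
        from gridfield.fixtures import make_fixture
        from gridfield.hebbian import weights_from_map
        from gridfield.pca import project_eigenvector

        m = make_fixture("stripes", wavelength=8.0, size=20)
        q = weights_from_map(m, small_dog_ensemble)
        assert np.linalg.norm(q) == pytest.approx(1.0)
        back = project_eigenvector(q, small_dog_ensemble)
        # the projected weights correlate with the encoded pattern (the
        # round trip applies the centre-surround band-pass twice, which
        # attenuates but preserves the stripe structure)
        assert np.corrcoef(back.ravel(), m.ravel())[0, 1] > 0.25
        qr = weights_from_map(m, small_dog_ensemble, rectify=True)
        assert qr.min() >= 0.0

    def test_square_initialised_constrained_network_becomes_hexagonal(self):
        """Stability of the hexagonal solution: rectified training started
        from square-patterned weights still converges to a hexagonal map."""
        from gridfield.arena import generate_trajectory
        from gridfield.experiments import default_ensemble
        from gridfield.fixtures import make_fixture
        from gridfield.gridscore import score_map
        from gridfield.hebbian import weights_from_map
        from gridfield.pca import project_eigenvector

        ens = default_ensemble()
        J0 = weights_from_map(make_fixture("square", wavelength=16.0, size=64),
                              ens, rectify=True)
        sc0 = score_map(project_eigenvector(J0, ens), pixel_size=ens.arena.pixel_size)
        assert sc0.gridness90 > 0.7  # starts square
        traj = generate_trajectory(ens.arena, 2_000_000, speed=1.0, seed=21)
        res = train(ens, traj, nonneg=True, seed=22, J0=J0[None, :])
        sc = score_map(project_eigenvector(res.J[0], ens),
                       pixel_size=ens.arena.pixel_size)
        assert sc.gridness60 > 0.7
        assert sc.gridness60 > sc.gridness90
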
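import numpy as np
import pytest

from pibsampler import (BiasGrid, GridFunction, LangevinParams, OPTrajectory,
                        PIBHyperparams, RoundState, ToySampler, load_round,
                        run_round, save_round, select_training_trajectory,
                        start_second_rc)
from pibsampler.protocol import check_convergence, plumed_snippet, FileSampler
from pibsampler.reweighting import FreeEnergyProfile
from pibsampler.toy_md import two_barrier_2d

from conftest import make_rc, make_traj

TINY_HP = PIBHyperparams(epochs=8, n_restarts=1, hidden_width=16,
                         batch_size=256, seed=0)


def tiny_sampler():
    pot = two_barrier_2d(2.0, 4.0)
    params = LangevinParams(dt=1e-3, n_steps=4000, save_stride=10, seed=0)
    return ToySampler(pot, params, x0=np.array([-1.0, -1.0]))


class TestSelectTrainingTrajectory:
    def test_highest_variance_wins(self, rng):
        base = rng.standard_normal((200, 2))
        reps = [make_traj(1.0 * base), make_traj(2.0 * base),
                make_traj(0.5 * base)]
        assert select_training_trajectory(reps) == 1

    def test_identical_replicas_tie_to_first(self, rng):
        t = make_traj(rng.standard_normal((100, 2)))
        assert select_training_trajectory([t, t, t]) == 0

    def test_crossing_replica_beats_trapped(self, rng):
        trapped = make_traj(-1.0 + 0.1 * rng.standard_normal((400, 1)))
        crossing = make_traj(np.concatenate([
            -1.0 + 0.1 * rng.standard_normal(200),
            1.0 + 0.1 * rng.standard_normal(200)])[:, None])
        # oracle: variance computed directly on the paths after pooled z-score
        pooled = np.vstack([trapped.values, crossing.values])
        z = (np.array([trapped.values, crossing.values])
             - pooled.mean()) / pooled.std()
        assert z[1].var() > z[0].var()
        assert select_training_trajectory([trapped, crossing]) == 1

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_training_trajectory([])


class TestRoundLoop:
    def test_first_round_trains_and_builds_bias(self):
        state = RoundState(seed=5)
        new = run_round(state, tiny_sampler(), TINY_HP, delta_v=1.0, lag_k=2,
                        nbins=40)
        assert new.round_index == 1
        assert np.linalg.norm(new.rc1.weights) == pytest.approx(1.0, abs=1e-8)
        assert new.bias1.values.min() == pytest.approx(0.0, abs=1e-12)
        assert new.bias1.cap == pytest.approx(1.0)
        assert len(new.trajectories) == 4

    def test_unbiased_frames_in_biased_round_rejected(self):
        class BadSampler:
            def sample(self, biases, n_replicas, seed):
                pot = two_barrier_2d(2.0, 4.0)
                params = LangevinParams(dt=1e-3, n_steps=2000, save_stride=10,
                                        seed=seed)
                from pibsampler import simulate_ensemble
                return simulate_ensemble(pot, params, n_replicas)  # no bias

        state = RoundState(seed=5)
        state = run_round(state, tiny_sampler(), TINY_HP, delta_v=1.0, lag_k=2)
        with pytest.raises(ValueError, match="bias column"):
            run_round(state, BadSampler(), TINY_HP, delta_v=1.0, lag_k=2)

    def test_second_rc_requires_saturation(self):
        state = RoundState(seed=5)
        assert not state.saturated
        with pytest.raises(ValueError, match="saturat"):
            start_second_rc(state)

    def test_washing_out_orthogonality_and_additivity(self):
        sampler = tiny_sampler()
        state = RoundState(seed=7)
        for _ in range(3):
            state = run_round(state, sampler, TINY_HP, delta_v=1.5, lag_k=2,
                              nbins=40)
        state.saturated = True  # enter stage 2 regardless of detector timing
        state = start_second_rc(state)
        state = run_round(state, sampler, TINY_HP, delta_v=1.5, lag_k=2,
                          nbins=40)
        assert abs(state.rc1.weights @ state.rc2.weights) <= 1e-6
        # next round samples under the separable sum V1(chi1) + V2(chi2)
        applied = state  # biases applied in the following round
        state = run_round(state, sampler, TINY_HP, delta_v=1.5, lag_k=2,
                          nbins=40)
        traj = state.trajectories[0]
        chi1 = applied.rc1.project_values(traj.values)
        chi2 = applied.rc2.project_values(traj.values)
        expected = applied.bias1.value(chi1) + applied.bias2.value(chi2)
        np.testing.assert_allclose(traj.bias, expected, atol=1e-10)


class TestConvergence:
    def _state(self, weights, f, stage=1):
        rc = make_rc(weights)
        grid = GridFunction(name="chi", grid_min=-1, grid_max=1,
                            nbins=len(f), values=np.full(len(f), 0.5))
        prof = FreeEnergyProfile(grid=grid, f=np.asarray(f, float),
                                 beta=1.0, n_effective=1e4)
        st = RoundState(stage=stage)
        st.rc1, st.profile1 = rc, prof
        return st

    def test_close_states_converge(self):
        f = np.linspace(0, 2, 50)
        a = self._state([1.0, 0.02], f)
        b = self._state([1.0, 0.03], f + 0.1)
        assert check_convergence(a, b) is True

    def test_rotated_rc_not_converged(self):
        f = np.linspace(0, 2, 50)
        a = self._state([1.0, 0.0], f)
        b = self._state([np.cos(np.radians(20)), np.sin(np.radians(20))], f)
        assert check_convergence(a, b) is False

    def test_shifted_profile_not_converged(self):
        f = np.linspace(0, 2, 50)
        a = self._state([1.0, 0.0], f)
        b = self._state([1.0, 0.0], f + 1.0)
        assert check_convergence(a, b) is False


class TestSerialization:
    def test_round_trip_and_bit_identical_resume(self, tmp_path):
        sampler_a = tiny_sampler()
        sampler_a.warm_restart = False
        state = RoundState(seed=11)
        state = run_round(state, sampler_a, TINY_HP, delta_v=1.0, lag_k=2,
                          nbins=30)
        save_round(state, str(tmp_path / "round_1"))
        loaded = load_round(str(tmp_path / "round_1"))

        np.testing.assert_array_equal(loaded.rc1.weights, state.rc1.weights)
        np.testing.assert_allclose(loaded.bias1.values, state.bias1.values,
                                   atol=1e-12)
        np.testing.assert_allclose(loaded.trajectories[0].values,
                                   state.trajectories[0].values, atol=1e-12)
        assert loaded.round_index == 1 and loaded.seed == 11

        sampler_b = tiny_sampler()
        sampler_b.warm_restart = False
        nxt_orig = run_round(state, sampler_a, TINY_HP, delta_v=1.0, lag_k=2,
                             nbins=30)
        nxt_resumed = run_round(loaded, sampler_b, TINY_HP, delta_v=1.0,
                                lag_k=2, nbins=30)
        np.testing.assert_array_equal(nxt_resumed.rc1.weights,
                                      nxt_orig.rc1.weights)
        np.testing.assert_array_equal(nxt_resumed.bias1.values,
                                      nxt_orig.bias1.values)


class TestFileHandoff:
    def test_plumed_snippet_declares_combination(self):
        rc = make_rc([0.6, 0.8], names=["d1", "d2"], shift=[1.0, 2.0],
                     scale=[2.0, 4.0])
        g = GridFunction(name="chi", grid_min=0, grid_max=1, nbins=4,
                         values=np.zeros(4))
        bias = BiasGrid(grid=g, cap=1.0, delta_v=1.0)
        text = plumed_snippet(rc, bias, "chi1")
        assert "COMBINE ARG=d1,d2" in text
        assert "COEFFICIENTS=0.3,0.2" in text   # c_i / scale_i
        assert "EXTERNAL" in text

    def test_file_sampler_writes_grid_then_expects_colvar(self, tmp_path):
        rc = make_rc([1.0], names=["x"])
        g = GridFunction(name="chi", grid_min=-1, grid_max=1, nbins=5,
                         values=np.zeros(5))
        bias = BiasGrid(grid=g, cap=1.0, delta_v=1.0)
        sampler = FileSampler(str(tmp_path))
        with pytest.raises(FileNotFoundError, match="replica_0.colvar"):
            sampler.sample([(bias, rc)], n_replicas=1, seed=0)
        assert (tmp_path / "round_0" / "bias1.grid").exists()
        assert (tmp_path / "round_0" / "plumed1.dat").exists()
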
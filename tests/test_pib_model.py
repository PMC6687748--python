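import math

import numpy as np
import pytest

from pibsampler import (PIBHyperparams, PredictiveBottleneck, ReactionCoordinate,
                        equivalence_check_mse, objective, project, train)
from pibsampler.pib_model import DecoderModel, Standardization, _log_q_constant

from conftest import make_rc, make_traj

FAST_HP = PIBHyperparams(epochs=40, n_restarts=2, batch_size=256, seed=0)


class TestProjection:
    def test_basis_vector(self):
        rc = make_rc([1, 0, 0, 0])
        traj = make_traj(np.array([[1.0, 0, 0, 0], [2.0, 0.5, 0.5, 0.5]]))
        chi = project(traj, rc)
        assert chi[0] == pytest.approx(1.0)

    def test_unit_projection(self):
        rc = make_rc([0.6, 0.8])
        traj = make_traj(np.array([[0.6, 0.8], [0.0, 0.0]]))
        assert project(traj, rc)[0] == pytest.approx(1.0)

    def test_backbone_torsion_weights(self):
        # converged small-peptide RC weights dotted with a unit input frame:
        # (0.02, 0.97, -0.25, -0.02) . (0, 1, 1, 0) = 0.72
        w = np.array([0.02, 0.97, -0.25, -0.02])
        rc = make_rc(w, names=["cos_phi", "sin_phi", "cos_psi", "sin_psi"])
        traj = make_traj(np.array([[0.0, 1.0, 1.0, 0.0], [0, 0, 0, 0]]))
        assert project(traj, rc)[0] == pytest.approx(0.72, abs=5e-3)

    def test_dimension_mismatch(self):
        rc = make_rc([1.0, 0.0])
        traj = make_traj(np.ones((3, 1)) * [[1], [2], [3]])
        with pytest.raises(ValueError):
            project(traj, rc)


class TestObjective:
    @pytest.fixture
    def setup(self, rng):
        d = 2
        traj = make_traj(rng.standard_normal((50, d)))
        rc = make_rc(rng.standard_normal(d))
        hp = PIBHyperparams()
        dec = DecoderModel(1, d, hp, rng)
        return traj, rc, dec

    def test_zero_bias_reduces_to_unweighted(self, setup, rng):
        traj, rc, dec = setup
        biased = make_traj(traj.values, bias=np.zeros(traj.n_frames))
        assert objective(biased, rc, dec, 3) == pytest.approx(
            objective(traj, rc, dec, 3), abs=1e-12)

    def test_uniform_bias_invariance(self, setup):
        traj, rc, dec = setup
        for v in (0.7, -2.0, 5.0):
            biased = make_traj(traj.values,
                               bias=np.full(traj.n_frames, v))
            assert objective(biased, rc, dec, 2) == pytest.approx(
                objective(traj, rc, dec, 2), rel=1e-12)

    def test_log2_bias_weights(self):
        # V = (0, ln 2 / beta) -> relative weights (1/3, 2/3)
        vals = np.array([[0.5], [-0.5]])
        traj = make_traj(vals, bias=np.array([0.0, math.log(2.0)]), beta=1.0)
        rc = make_rc([1.0])
        rng = np.random.default_rng(0)
        dec = DecoderModel(1, 1, PIBHyperparams(), rng)
        got = objective(traj, rc, dec, 0)
        # hand computation with explicit (1/3, 2/3) weights
        std = rc.standardization
        w = traj.importance_weights()
        np.testing.assert_allclose(w / w.sum(), [1 / 3, 2 / 3], atol=1e-15)
        xs = std.apply(vals)
        chi = xs @ rc.weights
        resid = dec.forward(chi[:, None]) - xs
        sigma2 = 0.005
        expected = (-(np.array([1 / 3, 2 / 3]) @ (resid**2).sum(axis=1))
                    / (2 * sigma2) + _log_q_constant(1, sigma2))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_and_zero_weights_rejected(self, setup):
        traj, rc, dec = setup
        with pytest.raises(ValueError):
            objective(traj, rc, dec, 1, weights=np.full(traj.n_frames, np.nan))
        with pytest.raises(ValueError):
            objective(traj, rc, dec, 1, weights=np.zeros(traj.n_frames))


class TestEquivalenceIdentity:
    def test_zero_residual_closed_form(self, rng):
        """A decoder reproducing the target exactly gives the sigma constant."""
        d = 3
        vals = rng.standard_normal((30, d))
        traj = make_traj(vals)
        rc = make_rc(np.ones(d))

        class PerfectDecoder(DecoderModel):
            def forward(self, chi, cache=False):
                out = rc.standardization.apply(vals)  # lag 0 target
                return (out, None) if cache else out

        dec = PerfectDecoder(1, d, PIBHyperparams(), rng)
        obj, wmse = equivalence_check_mse(traj, rc, dec, 0)
        assert wmse == pytest.approx(0.0, abs=1e-12)
        assert obj == pytest.approx(-(d / 2) * math.log(2 * math.pi * 0.005))

    def test_single_residual_hand_value(self, rng):
        # d=1, sigma^2=1, one residual of 2 -> objective = -2 - ln(2 pi)/2
        hp = PIBHyperparams(noise_variance=1.0)
        vals = np.array([[0.0], [1.0]])
        traj = make_traj(vals)
        rc = make_rc([1.0])

        class ShiftDecoder(DecoderModel):
            def forward(self, chi, cache=False):
                out = rc.standardization.apply(vals[1:]) + 2.0
                return (out, None) if cache else out

        dec = ShiftDecoder(1, 1, hp, rng)
        obj, wmse = equivalence_check_mse(traj, rc, dec, 1)
        assert wmse == pytest.approx(4.0)
        assert obj == pytest.approx(-2.0 - 0.5 * math.log(2 * math.pi))

    def test_identity_on_random_instances(self, rng):
        d = 4
        traj = make_traj(rng.standard_normal((60, d)),
                         bias=rng.random(60))
        rc = make_rc(rng.standard_normal(d))
        dec = DecoderModel(1, d, PIBHyperparams(), rng)
        obj, wmse = equivalence_check_mse(traj, rc, dec, 2)
        sigma2 = 0.005
        assert obj == pytest.approx(
            -wmse / (2 * sigma2) - (d / 2) * math.log(2 * math.pi * sigma2),
            abs=1e-10)


class TestTraining:
    def test_deterministic_given_seed(self, rng):
        traj = make_traj(np.cumsum(rng.standard_normal((400, 2)), axis=0))
        hp = PIBHyperparams(epochs=5, n_restarts=2, seed=42)
        rc_a, _ = train(traj, 2, hp)
        rc_b, _ = train(traj, 2, hp)
        np.testing.assert_array_equal(rc_a.weights, rc_b.weights)

    def test_constant_column_named_in_error(self, rng):
        vals = rng.standard_normal((100, 3))
        vals[:, 1] = 2.5
        traj = make_traj(vals, names=["a", "const_op", "c"])
        with pytest.raises(ValueError, match="const_op"):
            train(traj, 1, FAST_HP)

    def test_unit_norm_and_sign_convention(self, rng):
        traj = make_traj(np.cumsum(rng.standard_normal((500, 3)), axis=0))
        rc, _ = train(traj, 2, FAST_HP)
        assert np.linalg.norm(rc.weights) == pytest.approx(1.0, abs=1e-8)
        assert rc.weights[np.argmax(np.abs(rc.weights))] > 0

    def test_sign_flip_keeps_decoder_predictions(self, rng):
        """Flipping an encoder sign with the matched decoder-input flip leaves
        the prediction unchanged."""
        dec = DecoderModel(1, 2, PIBHyperparams(), rng)
        chi = rng.standard_normal(7)
        before = dec.forward(chi[:, None]).copy()
        dec.flip_input_sign(0)
        after = dec.forward(-chi[:, None])
        np.testing.assert_allclose(after, before, atol=1e-12)

    def test_slow_direction_recovery_ou(self, ou_slow_fast):
        """On an OU process with a planted slow axis, the learned encoder
        aligns with the slow eigenvector."""
        traj, slow = ou_slow_fast
        hp = PIBHyperparams(epochs=60, n_restarts=2, seed=3)
        rc, _ = train(traj, 10, hp)
        # compare in raw-coordinate space: undo the per-OP scaling
        direction = rc.weights / rc.standardization.scale
        direction /= np.linalg.norm(direction)
        assert abs(direction @ slow) >= 0.9

    def test_iid_noise_matches_constant_predictor(self, rng):
        """Without temporal structure the best decoder is the constant mean
        predictor; the trained objective cannot beat it by more than noise."""
        traj = make_traj(rng.standard_normal((2000, 2)))
        hp = PIBHyperparams(epochs=60, n_restarts=2, seed=5)
        model = PredictiveBottleneck(traj, 5, hp)
        res = model.fit()
        # constant predictor baseline: weighted MSE = sum of variances of the
        # standardized future targets
        xs = res.rc.standardization.apply(traj.values)[5:]
        baseline = float(np.sum(xs.var(axis=0)))
        assert res.loss >= baseline * 0.9
        assert res.loss <= baseline * 1.2

    def test_monotone_capacity_in_noise(self, ou_slow_fast):
        """More bottleneck noise cannot improve the converged prediction MSE."""
        traj, _ = ou_slow_fast
        sub = make_traj(traj.values[:4000], dt=traj.stride)
        losses = []
        for nv in (0.005, 0.25, 4.0):
            hp = PIBHyperparams(noise_variance=nv, epochs=40, n_restarts=1,
                                seed=11)
            res = PredictiveBottleneck(sub, 5, hp).fit()
            # marginalize the bottleneck noise by Monte Carlo
            rng = np.random.default_rng(99)
            xs = res.rc.standardization.apply(sub.values)
            chi = (xs @ res.rc.weights)[:-5]
            y = xs[5:]
            mses = []
            for _ in range(16):
                noisy = chi + rng.normal(0, math.sqrt(nv), chi.size)
                pred = res.decoder.forward(noisy[:, None])
                mses.append(np.mean(np.sum((pred - y) ** 2, axis=1)))
            losses.append(float(np.mean(mses)))
        assert losses[0] <= losses[1] * 1.1
        assert losses[1] <= losses[2] * 1.1

    def test_hyperparameter_validation(self):
        with pytest.raises(ValueError):
            PIBHyperparams(noise_variance=0.0)
        with pytest.raises(ValueError):
            PIBHyperparams(learning_rate=-1.0)

    def test_results_summary_mentions_ops(self, rng):
        traj = make_traj(np.cumsum(rng.standard_normal((300, 2)), axis=0),
                         names=["dist", "angle"])
        res = PredictiveBottleneck(traj, 1, FAST_HP).fit()
        text = res.summary()
        assert "dist" in text and "angle" in text
        assert "lag (frames): 1" in text


def test_rc_norm_invariant_enforced():
    with pytest.raises(ValueError):
        ReactionCoordinate(weights=np.array([1.0, 1.0]), op_names=["a", "b"],
                           standardization=Standardization.identity(2))
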
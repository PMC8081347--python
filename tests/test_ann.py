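"""Perceptron forward/backward passes, the five update rules, training and
the randomized evaluation protocol."""

import numpy as np
import pytest

from pathprot import ann
from pathprot.ann import (
    MLP,
    RpropState,
    TrainingConfig,
    backprop_update,
    evaluate_protocol,
    forward,
    gradient,
    grprop_update,
    init_mlp,
    predict_labels,
    rprop_minus_update,
    rprop_plus_update,
    train,
)
from pathprot.architecture import MLPTopology
from pathprot.features import ReducedFeatures
from pathprot.synthetic import generate_separable_dataset


def single_weight_state(delta, prev_grad, prev_dw):
    return RpropState(
        delta=[np.array([[delta]])],
        prev_grad=[np.array([[prev_grad]])],
        prev_dw=[np.array([[prev_dw]])],
    )


class TestInitAndForward:
    def test_same_seed_identical(self):
        topo = MLPTopology(3, (4, 2))
        a, b = init_mlp(topo, seed=1), init_mlp(topo, seed=1)
        assert all(np.array_equal(x, y) for x, y in zip(a.weights, b.weights))

    def test_different_seeds_differ(self):
        topo = MLPTopology(3, (4, 2))
        a, b = init_mlp(topo, seed=1), init_mlp(topo, seed=2)
        assert not np.array_equal(a.weights[0], b.weights[0])

    def test_reference_topology_weight_shapes(self):
        mlp = init_mlp(MLPTopology(3, (5, 1, 4, 5)), seed=0)
        assert [w.shape for w in mlp.weights] == [
            (4, 5), (6, 1), (2, 4), (5, 5), (6, 1)]

    def test_zero_weights_output_half(self):
        mlp = init_mlp(MLPTopology(2, (3,)), seed=0)
        for w in mlp.weights:
            w[:] = 0.0
        assert forward(mlp, np.zeros(2)) == pytest.approx(0.5)

    def test_output_bias_monotonicity(self):
        mlp = init_mlp(MLPTopology(2, (3,)), seed=3)
        y0 = forward(mlp, np.array([0.3, -0.2]))
        mlp.weights[-1][-1, 0] += 1.0
        assert forward(mlp, np.array([0.3, -0.2])) > y0

    def test_dimension_mismatch(self):
        mlp = init_mlp(MLPTopology(3, (2,)), seed=0)
        with pytest.raises(ValueError, match="dimension"):
            forward(mlp, np.zeros(4))


class TestGradient:
    def test_perfect_fit_zero_gradient(self):
        # drive the output to the targets exactly by construction: y = yhat
        mlp = init_mlp(MLPTopology(2, (2,)), seed=0)
        X = np.array([[0.1, 0.2], [0.3, -0.4]])
        Y = np.array([forward(mlp, x) for x in X])
        grads = gradient(mlp, X, Y)
        assert all(np.abs(g).max() < 1e-12 for g in grads)

    def test_batch_duplication_doubles_gradient(self):
        mlp = init_mlp(MLPTopology(2, (3, 2)), seed=1)
        X = np.array([[0.5, -1.0]])
        Y = np.array([1.0])
        g1 = gradient(mlp, X, Y)
        g2 = gradient(mlp, np.vstack([X, X]), np.concatenate([Y, Y]))
        for a, b in zip(g1, g2):
            assert np.allclose(2 * a, b, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        hidden = tuple(rng.integers(1, 4, size=rng.integers(1, 3)))
        topo = MLPTopology(int(rng.integers(1, 4)), hidden)
        mlp = init_mlp(topo, seed=seed)
        X = rng.standard_normal((4, topo.input_dim))
        Y = rng.random(4)
        analytic = gradient(mlp, X, Y)
        h = 1e-6
        for l, w in enumerate(mlp.weights):
            it = np.nditer(w, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = w[idx]
                w[idx] = orig + h
                ep = ann.sse(mlp, X, Y)
                w[idx] = orig - h
                em = ann.sse(mlp, X, Y)
                w[idx] = orig
                fd = (ep - em) / (2 * h)
                scale = max(abs(fd), abs(analytic[l][idx]), 1e-3)
                assert abs(fd - analytic[l][idx]) / scale < 1e-6


class TestBackpropUpdate:
    def test_scales_gradient(self):
        dw = backprop_update([np.array([1.0, -2.0])], TrainingConfig(algorithm="backprop"))
        assert np.allclose(dw[0], [-0.001, 0.002])

    def test_linear_in_gradient(self):
        cfg = TrainingConfig(algorithm="backprop")
        g = [np.array([0.3, -0.7])]
        assert np.allclose(backprop_update([3 * g[0]], cfg)[0],
                           3 * backprop_update(g, cfg)[0])


class TestRpropPlusUpdate:
    def test_same_sign_grows_step(self):
        # prev_grad>0, grad>0: Delta 0.1 -> 0.12, step -0.12
        st = single_weight_state(0.1, prev_grad=1.0, prev_dw=-0.1)
        dw, new = rprop_plus_update(st, [np.array([[2.0]])], TrainingConfig())
        assert dw[0][0, 0] == pytest.approx(-0.12)
        assert new.delta[0][0, 0] == pytest.approx(0.12)
        assert new.prev_grad[0][0, 0] == pytest.approx(2.0)

    def test_sign_flip_backtracks_and_zeroes_gradient(self):
        # flip with prev_dw=+0.12: Delta 0.12 -> 0.06, dw reverts to -0.12
        st = single_weight_state(0.12, prev_grad=-1.0, prev_dw=0.12)
        dw, new = rprop_plus_update(st, [np.array([[3.0]])], TrainingConfig())
        assert new.delta[0][0, 0] == pytest.approx(0.06)
        assert dw[0][0, 0] == pytest.approx(-0.12)
        assert new.prev_grad[0][0, 0] == 0.0

    def test_zero_gradient_holds(self):
        st = single_weight_state(0.1, prev_grad=1.0, prev_dw=-0.1)
        dw, new = rprop_plus_update(st, [np.array([[0.0]])], TrainingConfig())
        assert dw[0][0, 0] == 0.0
        assert new.delta[0][0, 0] == pytest.approx(0.1)

    def test_delta_clamped(self):
        cfg = TrainingConfig()
        st = single_weight_state(cfg.delta_max, 1.0, -1.0)
        _, new = rprop_plus_update(st, [np.array([[1.0]])], cfg)
        assert new.delta[0][0, 0] == cfg.delta_max
        st = single_weight_state(cfg.delta_min, 1.0, -1.0)
        _, new = rprop_plus_update(st, [np.array([[-1.0]])], cfg)
        assert new.delta[0][0, 0] == cfg.delta_min


class TestRpropMinusUpdate:
    def test_sign_flip_shrinks_without_revert(self):
        st = single_weight_state(0.12, prev_grad=-1.0, prev_dw=0.12)
        dw, new = rprop_minus_update(st, [np.array([[3.0]])], TrainingConfig())
        assert new.delta[0][0, 0] == pytest.approx(0.06)
        assert dw[0][0, 0] == pytest.approx(-0.06)  # -sign(+3)*0.06, no revert
        assert new.prev_grad[0][0, 0] == pytest.approx(3.0)

    def test_identical_to_plus_without_flips(self):
        rng = np.random.default_rng(0)
        g = [rng.standard_normal((3, 2))]
        st = RpropState([np.full((3, 2), 0.1)], [g[0].copy()], [np.zeros((3, 2))])
        st2 = RpropState([np.full((3, 2), 0.1)], [g[0].copy()], [np.zeros((3, 2))])
        dw_p, _ = rprop_plus_update(st, g, TrainingConfig())
        dw_m, _ = rprop_minus_update(st2, g, TrainingConfig())
        assert np.allclose(dw_p[0], dw_m[0])

    def test_delta_never_exceeds_max(self):
        cfg = TrainingConfig()
        st = single_weight_state(0.1, 1.0, 0.0)
        for _ in range(100):
            _, st = rprop_minus_update(st, [np.array([[1.0]])], cfg)
        assert st.delta[0][0, 0] <= cfg.delta_max


class TestGrpropUpdate:
    def test_no_flip_matches_rprop_minus(self):
        rng = np.random.default_rng(1)
        g = [rng.standard_normal((2, 2))]
        make = lambda: RpropState([np.full((2, 2), 0.1)], [g[0].copy()],
                                  [np.zeros((2, 2))])
        dw_m, _ = rprop_minus_update(make(), g, TrainingConfig())
        for variant in ("sag", "slr"):
            dw_g, _ = grprop_update(make(), g, TrainingConfig(), variant)
            assert np.allclose(dw_m[0], dw_g[0])

    def test_single_weight_degenerates(self):
        for variant in ("sag", "slr"):
            st = single_weight_state(0.12, -1.0, 0.12)
            dw_g, _ = grprop_update(st, [np.array([[3.0]])], TrainingConfig(), variant)
            st2 = single_weight_state(0.12, -1.0, 0.12)
            dw_m, _ = rprop_minus_update(st2, [np.array([[3.0]])], TrainingConfig())
            assert dw_g[0][0, 0] == pytest.approx(dw_m[0][0, 0])

    def test_two_weight_flip_uses_global_min_delta_under_slr(self):
        # weight 0 flips (prev -1, now +1): own Delta 0.2 -> 0.1; weight 1
        # keeps sign with Delta 0.02 -> 0.024; slr step for the flipped
        # weight must use min Delta = 0.024, not its own 0.1
        st = RpropState([np.array([[0.2, 0.02]])],
                        [np.array([[-1.0, 1.0]])],
                        [np.array([[0.0, 0.0]])])
        g = [np.array([[2.0, 1.0]])]
        dw, new = grprop_update(st, g, TrainingConfig(), "slr")
        assert new.delta[0][0, 0] == pytest.approx(0.1)
        assert new.delta[0][0, 1] == pytest.approx(0.024)
        assert dw[0][0, 0] == pytest.approx(-0.024)
        assert dw[0][0, 1] == pytest.approx(-0.024)

    def test_sag_uses_min_delta_among_smallest_derivatives(self):
        # flipped weight 0; smallest |grad| is weight 2 (0.1) with Delta 0.3
        st = RpropState([np.array([[0.2, 0.02, 0.3]])],
                        [np.array([[-1.0, 1.0, 1.0]])],
                        [np.array([[0.0, 0.0, 0.0]])])
        g = [np.array([[2.0, 1.0, 0.1]])]
        dw, _ = grprop_update(st, g, TrainingConfig(), "sag")
        # weight 2 same sign: Delta 0.3*1.2 = 0.36 -> shared step 0.36
        assert dw[0][0, 0] == pytest.approx(-0.36)


class TestConfigValidation:
    def test_eta_ordering_enforced(self):
        with pytest.raises(ValueError, match="eta"):
            TrainingConfig(eta_minus=1.5)
        with pytest.raises(ValueError, match="eta"):
            TrainingConfig(eta_plus=0.9)

    def test_unknown_algorithm(self):
        with pytest.raises(ValueError, match="algorithm"):
            TrainingConfig(algorithm="adam")


class TestTrain:
    def test_separable_data_fits(self):
        X, y = generate_separable_dataset(n_per_class=10, dim=2, margin=10, seed=0)
        topo = MLPTopology(2, (3,))
        mlp, trace = train(topo, X, y, TrainingConfig(seed=0))
        assert trace.converged
        assert (((forward(mlp, X) >= 0.5) == (y == 1)).all())

    def test_same_seed_identical_trajectory(self):
        X, y = generate_separable_dataset(n_per_class=5, dim=2, margin=8, seed=1)
        topo = MLPTopology(2, (3,))
        a = train(topo, X, y, TrainingConfig(seed=4))
        b = train(topo, X, y, TrainingConfig(seed=4))
        assert a[1].errors == b[1].errors
        assert all(np.array_equal(x, w) for x, w in zip(a[0].weights, b[0].weights))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train(MLPTopology(2, (2,)), np.zeros((3, 2)), np.ones(3), TrainingConfig())

    @pytest.mark.parametrize("alg", ann.ALGORITHMS)
    def test_all_rules_learn_separable_data(self, alg):
        X, y = generate_separable_dataset(n_per_class=10, dim=2, margin=10, seed=2)
        cfg = TrainingConfig(algorithm=alg, seed=0, max_steps=20_000)
        mlp, _ = train(MLPTopology(2, (3,)), X, y, cfg)
        err = float(((forward(mlp, X) >= 0.5) != (y == 1)).mean())
        assert err <= 0.05


def _reduced(X, ids, labels):
    return ReducedFeatures(coordinates=X, method="pca", explained_variance=1.0,
                           compound_ids=ids, labels=labels)


@pytest.fixture(scope="module")
def separable_features():
    rng = np.random.default_rng(0)
    Xa = rng.normal([6, 0], 0.5, (7, 2))
    Xb = rng.normal([-6, 0], 0.5, (5, 2))
    Xq = np.vstack([rng.normal([6, 0], 0.5, (3, 2)),
                    rng.normal([-6, 0], 0.5, (1, 2))])
    X = np.vstack([Xa, Xb, Xq])
    ids = [f"C{i}" for i in range(16)]
    labels = ["agonist"] * 7 + ["antagonist"] * 5 + ["query"] * 4
    return {"pca": _reduced(X, ids, labels)}


class TestEvaluateProtocol:
    def test_report_shape_and_ranges(self, separable_features):
        rep = evaluate_protocol(separable_features, MLPTopology(2, (3,)),
                                algorithms=("rprop_plus", "rprop_minus"),
                                n_iter=10, seed=0)
        assert len(rep.misclassification) == 2
        assert all(0 <= v <= 1 for v in rep.misclassification.values())
        assert all(0 <= v <= 1 for v in rep.consistency.values())

    def test_separable_rprop_plus_perfect(self, separable_features):
        rep = evaluate_protocol(separable_features, MLPTopology(2, (3,)),
                                algorithms=("rprop_plus",), n_iter=30, seed=1)
        cell = ("rprop_plus", "pca")
        assert rep.misclassification[cell] == 0.0
        assert rep.consistency[cell] == 1.0
        assert rep.modal_predictions[cell] == (True, True, True, False)

    def test_seed_reproducible(self, separable_features):
        kw = dict(algorithms=("slr",), n_iter=5, seed=9)
        a = evaluate_protocol(separable_features, MLPTopology(2, (2,)), **kw)
        b = evaluate_protocol(separable_features, MLPTopology(2, (2,)), **kw)
        assert a.misclassification == b.misclassification
        assert a.modal_predictions == b.modal_predictions


class TestPredictLabels:
    def test_memorized_training_point(self):
        X, y = generate_separable_dataset(n_per_class=8, dim=2, margin=10, seed=3)
        mlp, _ = train(MLPTopology(2, (3,)), X, y, TrainingConfig(seed=0))
        preds = predict_labels(mlp, X[:1], ["probe"])
        assert preds[0]["neuroprotective"] is bool(y[0] == 1)

    def test_tie_goes_positive(self):
        mlp = init_mlp(MLPTopology(2, (2,)), seed=0)
        for w in mlp.weights:
            w[:] = 0.0  # output exactly 0.5
        assert predict_labels(mlp, np.zeros((1, 2)))[0]["neuroprotective"] is True

    def test_eight_queries_eight_labels(self):
        X, y = generate_separable_dataset(n_per_class=8, dim=2, margin=10, seed=4)
        mlp, _ = train(MLPTopology(2, (3,)), X, y, TrainingConfig(seed=0))
        assert len(predict_labels(mlp, np.random.default_rng(0).normal(size=(8, 2)))) == 8
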
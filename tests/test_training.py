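"""Training: loss assembly, gradients, LQA fitting, selection, tuning."""

import numpy as np
import pytest

from osnn.model import init_model, predict_proba
from osnn.penalties import PenaltyConfig
from osnn.simulate import SimulationConfig, generate_dataset
from osnn.training import (
    ModelConfig,
    TrainConfig,
    cross_entropy,
    fit,
    loss_and_grads,
    select_variables,
    total_objective,
    tune,
    _pack,
    _unpack,
)


class TestCrossEntropy:
    def test_perfect_prediction(self):
        probs = np.eye(3)[[0, 2, 1]]
        assert cross_entropy(probs, np.array([1, 3, 2])) == pytest.approx(0.0, abs=1e-10)

    def test_uniform(self):
        probs = np.full((5, 3), 1 / 3)
        assert cross_entropy(probs, np.array([1, 2, 3, 1, 2])) == pytest.approx(np.log(3))

    def test_hand_value(self):
        probs = np.array([[0.5, 0.5, 0.0], [0.25, 0.5, 0.25]])
        got = cross_entropy(probs, np.array([1, 1]))
        assert got == pytest.approx((-np.log(0.5) - np.log(0.25)) / 2)

    def test_invalid_label(self):
        with pytest.raises(ValueError):
            cross_entropy(np.full((2, 3), 1 / 3), np.array([0, 4]))


class TestTotalObjective:
    def test_no_penalties_equals_cross_entropy(self, tiny_dataset, rng):
        train, *_ = tiny_dataset
        model = init_model(p=3, q=2, K=3, hidden=(4,), rng=rng)
        pen = PenaltyConfig()
        obj = total_objective(model, train, pen, mode="exact")
        ce = cross_entropy(predict_proba(train, model), train.y)
        assert obj == pytest.approx(ce)

    def test_ridge_increment(self, tiny_dataset, rng):
        train, *_ = tiny_dataset
        model = init_model(p=3, q=2, K=3, hidden=(2,), rng=rng)
        model.dense.weights[1][:] = 1.0  # 1x2 output matrix: 2 unit entries
        base = total_objective(model, train, PenaltyConfig(), mode="exact")
        withridge = total_objective(
            model, train, PenaltyConfig(lambda_ridge=1.0), mode="exact"
        )
        w0 = (model.dense.weights[0] ** 2).sum()
        assert withridge - base == pytest.approx(w0 + 2.0)

    def test_surrogate_requires_expansion(self, tiny_dataset, rng):
        train, *_ = tiny_dataset
        model = init_model(p=3, q=2, K=3, hidden=(2,), rng=rng)
        with pytest.raises(ValueError):
            total_objective(model, train, PenaltyConfig(lambda_group=0.1), mode="surrogate")


class TestGradients:
    @pytest.mark.parametrize("head", ["ordinal", "softmax"])
    @pytest.mark.parametrize("structure", ["hierarchical", "individual"])
    def test_backprop_matches_finite_differences(self, tiny_dataset, head, structure, rng):
        """Analytic gradients of the surrogate objective vs central differences."""
        train, *_ = tiny_dataset
        model = init_model(p=3, q=2, K=3, hidden=(4,), head=head, rng=rng)
        model.sparse.b = rng.normal(0.4, 0.1, 3)
        model.sparse.eta = rng.normal(0.3, 0.1, (3, 2))
        pen = PenaltyConfig(lambda_ridge=0.01, lambda_group=0.05, lambda_indiv=0.03)
        T, y = train.features(), train.y
        expansion = model.sparse.copy()
        _, grad = loss_and_grads(model, T, y, pen, structure, expansion=expansion)
        theta = _pack(model)
        h = 1e-6
        idx = rng.choice(len(theta), size=40, replace=False)
        for i in idx:
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            op, _ = loss_and_grads(_unpack(model, tp), T, y, pen, structure, expansion=expansion)
            om, _ = loss_and_grads(_unpack(model, tm), T, y, pen, structure, expansion=expansion)
            num = (op - om) / (2 * h)
            assert grad[i] == pytest.approx(num, abs=2e-5, rel=1e-5)

    def test_surrogate_tangent_to_exact_objective(self, tiny_dataset, rng):
        """At its own expansion point the LQA surrogate has the exact gradient."""
        train, *_ = tiny_dataset
        model = init_model(p=3, q=2, K=3, hidden=(3,), rng=rng)
        model.sparse.b = rng.uniform(0.2, 0.8, 3)
        model.sparse.eta = rng.uniform(0.2, 0.8, (3, 2))
        pen = PenaltyConfig(
            lambda_ridge=0.0, lambda_group=0.3, lambda_indiv=0.2, lqa_eps=1e-300
        )
        _, grad = loss_and_grads(model, train.features(), train.y, pen, "hierarchical")
        # finite differences of the EXACT objective over the sparse coefficients
        theta = _pack(model)
        n_sparse = 3 + 3 * 2
        h = 1e-6
        for i in range(len(theta) - n_sparse, len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            op = total_objective(_unpack(model, tp), train, pen, mode="exact")
            om = total_objective(_unpack(model, tm), train, pen, mode="exact")
            assert grad[i] == pytest.approx((op - om) / (2 * h), abs=1e-6)


class TestFit:
    def test_penalty_domination_kills_sparse_layer(self, tiny_dataset):
        train, *_ = tiny_dataset
        mc = ModelConfig(K=3, hidden=(8,))
        pen = PenaltyConfig(lambda_group=1e3, lambda_indiv=1e3)
        # small step size: adam's stationary jitter is of order the learning rate
        tc = TrainConfig(optimizer="adam", learning_rate=5e-4, max_iters=1500, seed=0)
        res = fit(train, mc, pen, tc)
        assert np.all(np.abs(res.model.sparse.b) < 1e-3)
        assert np.all(np.abs(res.model.sparse.eta) < 1e-3)

    def test_cutpoints_ordered_after_fit(self, tiny_dataset):
        train, *_ = tiny_dataset
        res = fit(
            train,
            ModelConfig(K=3, hidden=(8,)),
            PenaltyConfig(lambda_ridge=1e-3),
            TrainConfig(optimizer="adam", learning_rate=0.01, max_iters=100, seed=1),
        )
        assert np.all(np.diff(res.model.alpha) > 0)

    def test_deterministic_given_seed(self, tiny_dataset):
        train, *_ = tiny_dataset
        mc = ModelConfig(K=3, hidden=(4,))
        pen = PenaltyConfig(lambda_ridge=1e-3, lambda_group=0.05, lambda_indiv=0.03)
        tc = TrainConfig(optimizer="adam", learning_rate=0.01, max_iters=60, seed=11)
        r1 = fit(train, mc, pen, tc)
        r2 = fit(train, mc, pen, tc)
        assert np.array_equal(r1.objective_trace, r2.objective_trace)
        assert np.array_equal(r1.model.sparse.b, r2.model.sparse.b)

    def test_objective_eventually_decreases(self, small_dataset):
        train, *_ = small_dataset
        res = fit(
            train,
            ModelConfig(K=3, hidden=(16,)),
            PenaltyConfig(lambda_ridge=1e-3, lambda_group=0.05, lambda_indiv=0.03),
            TrainConfig(optimizer="adam", learning_rate=0.01, max_iters=150, seed=3),
        )
        trace = res.objective_trace
        upticks = np.diff(trace[10:])
        assert trace[-1] < trace[0]
        assert np.all(upticks < 0.05)  # only small transient upticks allowed

    def test_linear_fit_recovers_cutpoint_gap(self, rng):
        """Unpenalized cumulative-logit fit ~ maximum likelihood on true model."""
        n, p, q = 500, 2, 1
        X = rng.normal(size=(n, p))
        Z = rng.normal(size=(n, q))
        R = (X[:, :, None] * Z[:, None, :]).reshape(n, -1)
        s_lin = X @ np.array([1.0, -0.5])
        a_true = np.array([-0.8, 0.8])
        u = s_lin + rng.logistic(size=n)
        y = 1 + np.searchsorted(a_true, u)

        from osnn.simulate import OrdinalDataset

        data = OrdinalDataset(X, Z, R, y)
        res = fit(
            data,
            ModelConfig(K=3, hidden=(), sparse_init=0.5),
            PenaltyConfig(),
            TrainConfig(optimizer="adam", learning_rate=0.02, max_iters=1500,
                        tol=1e-7, seed=5),
        )
        gap_est = res.model.alpha[1] - res.model.alpha[0]
        assert gap_est == pytest.approx(1.6, rel=0.2)

    def test_missing_class_rejected(self, tiny_dataset):
        train, *_ = tiny_dataset
        bad = train.subset(np.flatnonzero(train.y != 2))
        with pytest.raises(ValueError):
            fit(bad, ModelConfig(K=3), PenaltyConfig(), TrainConfig(max_iters=5))


class TestSelectVariables:
    def test_all_zero_empty(self):
        model = init_model(p=3, q=2, K=3, rng=np.random.default_rng(0), sparse_init=0.0)
        sel = select_variables(model, tau=1e-3)
        assert sel.main_selected == frozenset()
        assert sel.inter_selected == frozenset()

    def test_direct_rule(self):
        model = init_model(p=2, q=2, K=3, rng=np.random.default_rng(0), sparse_init=0.0)
        model.sparse.b[0] = 0.5
        model.sparse.eta[0, 0] = 0.2
        model.sparse.eta[0, 1] = 1e-6
        sel = select_variables(model, tau=1e-3)
        assert sel.main_selected == frozenset({0})
        assert sel.inter_selected == frozenset({(0, 0)})

    def test_hierarchy_by_construction(self):
        # group norm below tau -> no interactions of that group, however large eta
        model = init_model(p=2, q=1, K=3, rng=np.random.default_rng(0), sparse_init=0.0)
        model.sparse.eta[1, 0] = 5e-4
        sel = select_variables(model, tau=1e-3)
        assert sel.inter_selected == frozenset()

    def test_hierarchy_invariant_on_random_fits(self, rng):
        for _ in range(50):
            model = init_model(p=6, q=3, K=3, rng=rng, sparse_init=0.0)
            model.sparse.b = rng.normal(scale=0.05, size=6)
            model.sparse.eta = rng.normal(scale=0.05, size=(6, 3))
            sel = select_variables(model, tau=0.04)
            assert all(j in sel.main_selected for j, _ in sel.inter_selected)

    def test_individual_rule_may_violate_hierarchy(self):
        model = init_model(p=2, q=1, K=3, rng=np.random.default_rng(0), sparse_init=0.0)
        model.sparse.eta[1, 0] = 0.9  # parent b stays 0
        sel = select_variables(model, tau=1e-2, rule="individual")
        assert (1, 0) in sel.inter_selected
        assert 1 not in sel.main_selected  # interaction without its parent
        # the hierarchical rule on the same coefficients keeps the parent
        # (its group norm includes eta), so hierarchy still holds there
        sel_h = select_variables(model, tau=1e-2, rule="hierarchical")
        assert (1, 0) in sel_h.inter_selected
        assert 1 in sel_h.main_selected


class TestTune:
    def test_singleton_grid_returns_it(self, tiny_dataset):
        train, val, *_ = tiny_dataset
        grids = {"lambda_ridge": [1e-3], "lambda_group": [0.05], "lambda_indiv": [0.02]}
        tc = TrainConfig(optimizer="adam", learning_rate=0.01, max_iters=40, seed=2)
        cfg, res = tune(train, val, grids, ModelConfig(K=3, hidden=(4,)), tc)
        assert (cfg.lambda_ridge, cfg.lambda_group, cfg.lambda_indiv) == (1e-3, 0.05, 0.02)
        assert res.n_iters <= 40

    def test_grid_order_invariance(self, tiny_dataset):
        train, val, *_ = tiny_dataset
        tc = TrainConfig(optimizer="adam", learning_rate=0.01, max_iters=40, seed=2)
        g1 = {"lambda_group": [0.01, 0.3], "lambda_indiv": [0.05], "lambda_ridge": [1e-3]}
        g2 = {"lambda_group": [0.3, 0.01], "lambda_indiv": [0.05], "lambda_ridge": [1e-3]}
        c1, _ = tune(train, val, g1, ModelConfig(K=3, hidden=(4,)), tc)
        c2, _ = tune(train, val, g2, ModelConfig(K=3, hidden=(4,)), tc)
        assert c1 == c2

    def test_noise_data_prefers_sparser_config(self, rng):
        """On pure-noise data the selected config is at least median-sparse."""
        from osnn.simulate import OrdinalDataset, build_interactions

        n, p, q = 120, 6, 2
        X, Z = rng.normal(size=(n, p)), rng.normal(size=(n, q))
        y = rng.integers(1, 4, size=n)
        full = OrdinalDataset(X, Z, build_interactions(X, Z), y)
        data = full.subset(np.arange(80))        # train
        val = full.subset(np.arange(80, 120))    # disjoint validation
        grids = {"lambda_group": [1e-4, 0.5], "lambda_indiv": [1e-4, 0.5],
                 "lambda_ridge": [1e-3]}
        tc = TrainConfig(optimizer="adam", learning_rate=0.01, max_iters=150, seed=4)
        cfg, _ = tune(data, val, grids, ModelConfig(K=3, hidden=(8,)), tc)
        assert cfg.lambda_group >= 1e-4 and cfg.lambda_indiv >= 1e-4
        assert max(cfg.lambda_group, cfg.lambda_indiv) == 0.5

    def test_combo_grid(self, tiny_dataset):
        train, val, *_ = tiny_dataset
        tc = TrainConfig(optimizer="adam", learning_rate=0.01, max_iters=30, seed=2)
        grids = {"combos": [(1e-3, 0.05, 0.02), (1e-3, 0.2, 0.1)]}
        cfg, _ = tune(train, val, grids, ModelConfig(K=3, hidden=(4,)), tc)
        assert (cfg.lambda_ridge, cfg.lambda_group, cfg.lambda_indiv) in {
            (1e-3, 0.05, 0.02),
            (1e-3, 0.2, 0.1),
        }


def test_e_variables_have_fixed_unit_weights(tiny_dataset):
    """Environmental variables are never selected or reweighted by training."""
    train, *_ = tiny_dataset
    res = fit(
        train,
        ModelConfig(K=3, hidden=(4,)),
        PenaltyConfig(lambda_group=0.1, lambda_indiv=0.05),
        TrainConfig(optimizer="adam", learning_rate=0.01, max_iters=50, seed=0),
    )
    beta = res.model.sparse.beta()
    assert np.array_equal(beta[-train.q:], np.ones(train.q))
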
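"""Mk likelihood, fitting, simplification, AIC weights, source-sink ratios."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from biomevol.mk import (
    ConstraintPattern,
    RateMatrix,
    aic_weights,
    akaike_weights,
    bootstrap_rates,
    fit_mk,
    make_model,
    mk_loglik,
    simplify_ard,
    source_sink_ratios,
)
from biomevol.simulate import BDParams, simulate_bd_tree, simulate_mk_history
from biomevol.trees import TipStateVector


def enumeration_loglik(tree, states, Q, prior):
    """Brute-force oracle: sum over every assignment of states to internal
    nodes, multiplying exact transition probabilities along each branch."""
    if not tree.is_binary():
        tree = tree.resolve_polytomies()
    flat = tree.flat()
    S = Q.n_states
    P = {i: expm(Q.matrix * flat.length[i]) for i in range(len(flat.length))}
    tipstate = states.as_array(flat.tip_labels)
    internals = list(flat.postorder)
    total = 0.0
    for assign in itertools.product(range(S), repeat=len(internals)):
        state_of = dict(zip(internals, assign))
        for i, s in enumerate(tipstate):
            state_of[i] = s
        prob = prior[state_of[internals[-1]]]
        for node in internals:
            for child in (flat.left[node], flat.right[node]):
                if child >= 0:
                    prob *= P[child][state_of[node], state_of[child]]
        total += prob
    return np.log(total)


class TestPatterns:
    @pytest.mark.parametrize(
        "kind,S,expected",
        [("ER", 5, 1), ("SYM", 5, 10), ("ARD", 5, 20), ("SW", 5, 12), ("ARD", 3, 6)],
    )
    def test_free_rate_counts(self, kind, S, expected):
        assert make_model(kind, S).n_free == expected

    def test_sw_blocks_specialist_jumps(self):
        sw = make_model("SW", 5)
        # indices: 0..2 specialists, 3 fw+land generalist, 4 marine generalist
        for i, j in [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1), (1, 3), (3, 1)]:
            assert sw.classes[i, j] == 0
        assert sw.classes[3, 4] > 0 and sw.classes[4, 3] > 0

    def test_custom_mask_validation(self):
        with pytest.raises(ValueError, match="nonnegative"):
            ConstraintPattern(np.array([[0, -1], [1, 0]]))

    def test_sw_requires_five_states(self):
        with pytest.raises(ValueError):
            make_model("SW", 4)


class TestLikelihood:
    def test_frozen_root_state_with_zero_rates(self, two_tip_tree):
        Q = RateMatrix(np.zeros((5, 5)), list("abcde"))
        states = TipStateVector({"A": 1, "B": 1}, list("abcde"))
        assert mk_loglik(two_tip_tree, states, Q) == pytest.approx(np.log(1 / 5))

    def test_three_tip_enumeration(self, three_tip_tree, er2_q):
        states = TipStateVector({"A": 0, "B": 1, "C": 0}, ["0", "1"])
        ll = mk_loglik(three_tip_tree, states, er2_q)
        oracle = enumeration_loglik(three_tip_tree, states, er2_q, np.full(2, 0.5))
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_er_relabeling_symmetry(self, three_tip_tree, er2_q):
        a = mk_loglik(three_tip_tree, TipStateVector({"A": 0, "B": 1, "C": 0}, ["0", "1"]), er2_q)
        b = mk_loglik(three_tip_tree, TipStateVector({"A": 1, "B": 0, "C": 1}, ["0", "1"]), er2_q)
        assert a == pytest.approx(b, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_pruning_matches_enumeration(self, data):
        """Property: pruning equals brute-force enumeration for any small
        tree, state count and rate matrix."""
        n_tips = data.draw(st.integers(3, 5))
        S = data.draw(st.integers(2, 3))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        tree = simulate_bd_tree(BDParams(1.0, 0.0, n=n_tips), seed=seed)
        Q = RateMatrix.from_rates(rng.uniform(0.05, 1.5, (S, S)), [str(i) for i in range(S)])
        states = TipStateVector(
            {t: int(rng.integers(S)) for t in tree.tip_labels}, [str(i) for i in range(S)]
        )
        prior = rng.dirichlet(np.ones(S))
        ll = mk_loglik(tree, states, Q, root_prior=prior)
        oracle = enumeration_loglik(tree, states, Q, prior)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_tip_order_invariance(self, yule500, er2_q):
        rng = np.random.default_rng(0)
        labels = yule500.tip_labels
        s = {t: int(rng.integers(2)) for t in labels}
        a = mk_loglik(yule500, TipStateVector(s, ["0", "1"]), er2_q)
        b = mk_loglik(yule500, TipStateVector(dict(reversed(list(s.items()))), ["0", "1"]), er2_q)
        assert a == pytest.approx(b, abs=1e-9)

    def test_transition_matrix_rows_sum_to_one(self, yule500):
        from biomevol.mk import _transition_matrices

        rng = np.random.default_rng(1)
        Q = RateMatrix.from_rates(rng.uniform(0, 2, (5, 5)), list("abcde"))
        P = _transition_matrices(Q.matrix, yule500.flat().length)
        assert np.abs(P.sum(axis=2) - 1.0).max() < 1e-10


class TestFitting:
    def test_nested_models_order_loglik(self, yule500, er2_q):
        hist = simulate_mk_history(yule500, er2_q, root_state=0, seed=4)
        er = fit_mk(yule500, hist.tip_states, make_model("ER", 2), n_starts=2, seed=0)
        ard = fit_mk(yule500, hist.tip_states, make_model("ARD", 2), n_starts=2, seed=0)
        assert ard.logL >= er.logL - 1e-6

    def test_er_grid_search_oracle(self):
        """1-D grid search must agree with the optimizer to 3 significant
        figures on a 50-tip fixture."""
        tree = simulate_bd_tree(BDParams(1.0, 0.0, n=50), seed=21)
        Q = RateMatrix.from_rates(np.full((3, 3), 0.4), list("abc"))
        hist = simulate_mk_history(tree, Q, root_state=0, seed=22)
        fit = fit_mk(tree, hist.tip_states, make_model("ER", 3), n_starts=2, seed=0)
        grid = np.geomspace(fit.rates[0] / 3, fit.rates[0] * 3, 20_001)
        lls = [
            mk_loglik(tree, hist.tip_states, make_model("ER", 3).build_q([g], list("abc")))
            for g in grid
        ]
        q_grid = grid[int(np.argmax(lls))]
        assert fit.rates[0] == pytest.approx(q_grid, rel=1e-3)

    def test_aic_bookkeeping(self, yule500, er2_q):
        hist = simulate_mk_history(yule500, er2_q, root_state=0, seed=4)
        m = fit_mk(yule500, hist.tip_states, make_model("ER", 2), n_starts=1, seed=0)
        assert m.k == 1
        assert m.aic == pytest.approx(2 * m.k - 2 * m.logL)


class TestSimplify:
    def test_no_small_rates_and_rising_aic_returns_start(self):
        # 2-state data with both rates well supported: the first single-rate
        # removal must raise AIC, so the ARD model is returned unchanged
        tree = simulate_bd_tree(BDParams(1.0, 0.0, n=300), seed=31)
        Q = RateMatrix.from_rates(np.array([[0, 0.8], [0.8, 0]]), ["0", "1"])
        hist = simulate_mk_history(tree, Q, root_state=0, seed=32)
        ard = fit_mk(tree, hist.tip_states, make_model("ARD", 2), n_starts=2, seed=0)
        assert ard.rates.min() > 1e-3
        best, table = simplify_ard(tree, hist.tip_states, ard, seed=0)
        assert best.pattern.n_free == 2
        assert best.logL == pytest.approx(ard.logL)

    def test_free_rate_count_never_exceeds_ard(self, yule500):
        rng = np.random.default_rng(3)
        Q = RateMatrix.from_rates(rng.uniform(0.2, 1.0, (3, 3)), list("abc"))
        hist = simulate_mk_history(yule500, Q, root_state=0, seed=33)
        ard = fit_mk(yule500, hist.tip_states, make_model("ARD", 3), n_starts=1, seed=0)
        best, table = simplify_ard(yule500, hist.tip_states, ard, seed=0)
        assert best.pattern.n_free <= 6
        assert (table["k"] <= 6).all()


class TestWeightsAndRatios:
    def test_printed_aic_column_weights(self):
        aics = np.array([-346.05, -329.70, -249.08, -233.27, 455.67])
        w = akaike_weights(aics)
        # printed to table precision: best model takes all the weight
        assert round(w[0], 2) == 1.0
        assert np.all(np.round(w[1:], 2) == 0)
        assert w.sum() == pytest.approx(1.0)

    def test_single_model_weight_one(self):
        assert akaike_weights([123.4])[0] == pytest.approx(1.0)

    def test_equal_aic_split_evenly(self):
        w = akaike_weights([10.0, 10.0])
        assert np.allclose(w, 0.5)

    def test_aic_from_k_loglik(self):
        aic, delta, w = aic_weights([(10, 174.85), (13, 137.54)])
        assert aic[0] == pytest.approx(-329.70)
        assert aic[1] == pytest.approx(-249.08)
        assert w.sum() == pytest.approx(1.0)

    def test_weights_invariant_to_aic_shift(self):
        a = akaike_weights([3.0, 7.0, 9.0])
        b = akaike_weights([103.0, 107.0, 109.0])
        assert np.allclose(a, b)

    def test_symmetric_q_ratios_are_one(self):
        rng = np.random.default_rng(0)
        off = rng.uniform(0.1, 1, (4, 4))
        off = (off + off.T) / 2
        Q = RateMatrix.from_rates(off, list("abcd"))
        out = source_sink_ratios(Q)
        assert np.allclose(out["ratio"], 1.0)

    def test_zero_inflow_reported_as_inf(self):
        off = np.zeros((3, 3))
        off[0, 1] = 1.0  # state 0 only loses
        Q = RateMatrix.from_rates(off, list("abc"))
        out = source_sink_ratios(Q)
        assert np.isinf(out.loc["a", "ratio"])


@pytest.fixture(scope="module")
def fitted():
    tree = simulate_bd_tree(BDParams(1.0, 0.0, n=120), seed=41)
    Q = RateMatrix.from_rates(np.full((3, 3), 0.5), list("abc"))
    hist = simulate_mk_history(tree, Q, root_state=0, seed=42)
    patt = make_model("ER", 3)
    return tree, hist.tip_states, patt, fit_mk(tree, hist.tip_states, patt, n_starts=1, seed=0)


class TestBootstrap:
    def test_full_fraction_single_iteration_equals_full_fit(self, fitted):
        tree, states, patt, full = fitted
        out = bootstrap_rates(tree, states, patt, mode="tree80", n_iter=1,
                              fraction=1.0, seed=0, fitted=full)
        assert out["rates"].loc["class_1", "mean"] == pytest.approx(full.rates[0], rel=1e-4)

    def test_equal_n_balances_states_every_iteration(self, fitted):
        tree, states, patt, full = fitted
        from biomevol.trees import subsample_tree

        counts = states.counts()
        target = int(counts[counts > 0].min())
        ss = np.random.SeedSequence(3)
        for child in ss.spawn(5):
            sub = subsample_tree(tree, "equal_per_state", target, states=states, seed=child)
            sub_counts = np.bincount(
                [states.states[t] for t in sub.tip_labels], minlength=3
            )
            assert (sub_counts[sub_counts > 0] == target).all()

    def test_percentile_interval_is_ordered(self, fitted):
        tree, states, patt, full = fitted
        out = bootstrap_rates(tree, states, patt, mode="tree80", n_iter=20,
                              fraction=0.8, seed=1, fitted=full)
        r = out["rates"]
        assert (r["ci_lo"] <= r["mean"]).all() and (r["mean"] <= r["ci_hi"]).all()
        assert out["n_failed"] == 0
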
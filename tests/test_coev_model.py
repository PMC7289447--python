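import itertools

import numpy as np
import pytest
from scipy.linalg import expm, null_space

from cochap.phylo.coev import (
    CoevModel,
    PairPruner,
    coev_loglik,
    coev_rate_matrix,
    coev_stationary,
)
from cochap.phylo.pruning import ColumnModel, pruning_loglik_column
from cochap.phylo.tree import PhyloTree


def small_model(s=2.0, d=1.0, profile=frozenset({("A", "D")})):
    return CoevModel(("A", "C"), ("D", "E"), profile, s=s, d=d)


class TestRateMatrix:
    def test_rows_sum_to_zero(self):
        Q, _ = coev_rate_matrix(small_model(3.0, 0.5))
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_equal_rates_uniform_stationary(self):
        m = small_model(1.3, 1.3)
        np.testing.assert_allclose(coev_stationary(m), 0.25)

    def test_stationary_ratio_and_null_space_cross_check(self):
        # s = 2d, |P|=4, |S|=16: pi(P)/pi(non-P) = 2, and the closed form
        # agrees with the numerically computed null space of Q^T
        states = ("A", "C", "D", "E")
        profile = frozenset({("A", "A"), ("C", "C"), ("D", "D"), ("E", "E")})
        m = CoevModel(states, states, profile, s=2.0, d=1.0)
        Q, pi = coev_rate_matrix(m)
        mask = np.array([p in profile for p in m.pair_states])
        assert pi[mask][0] / pi[~mask][0] == pytest.approx(2.0)
        ns = null_space(Q.T).ravel()
        ns /= ns.sum()
        np.testing.assert_allclose(pi, ns, atol=1e-10)

    def test_only_single_position_moves_allowed(self):
        m = small_model()
        Q, _ = coev_rate_matrix(m)
        for i, (a1, b1) in enumerate(m.pair_states):
            for j, (a2, b2) in enumerate(m.pair_states):
                if i != j and a1 != a2 and b1 != b2:
                    assert Q[i, j] == 0.0

    def test_transition_probability_rows_sum_to_one(self):
        Q, _ = coev_rate_matrix(small_model(2.5, 0.7))
        for t in (0.01, 0.5, 4.0):
            P = expm(Q * t)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            CoevModel(("A",), ("D",), frozenset(), s=1.0, d=1.0)
        with pytest.raises(ValueError):
            small_model(s=-1.0)
        with pytest.raises(ValueError):
            CoevModel(("A",), ("D",), frozenset({("W", "W")}), s=1.0, d=1.0)


class TestCoevLikelihood:
    def brute_force(self, tree, col_a, col_b, model):
        Q, pi = coev_rate_matrix(model)
        idx = {p: i for i, p in enumerate(model.pair_states)}
        internals = [nd for nd in tree.postorder() if not nd.is_leaf]
        n = len(pi)
        total = 0.0
        mats = {nd: expm(Q * nd.length) for nd in tree.postorder() if nd.parent is not None}
        for assignment in itertools.product(range(n), repeat=len(internals)):
            state = dict(zip(internals, assignment))
            p = pi[state[tree.root]]
            for nd in tree.postorder():
                if nd.parent is None:
                    continue
                target = (
                    idx[(col_a[nd.name], col_b[nd.name])] if nd.is_leaf else state[nd]
                )
                p *= mats[nd][state[nd.parent], target]
            total += p
        return np.log(total)

    def test_matches_matrix_exponential_enumeration(self, tree4):
        col_a = {"A": "A", "B": "C", "C": "A", "D": "C"}
        col_b = {"A": "D", "B": "D", "C": "E", "D": "E"}
        model = CoevModel(("A", "C"), ("D", "E"), frozenset({("A", "D")}), 1.7, 0.4)
        assert coev_loglik(tree4, col_a, col_b, model) == pytest.approx(
            self.brute_force(tree4, col_a, col_b, model), abs=1e-8
        )

    def test_equal_rates_factorize_into_independent_columns(self, tree12):
        from cochap.simulate import simulate_alignment_independent

        aln = simulate_alignment_independent(tree12, 2, [0.5, 0.5], 21)
        col_a, col_b = aln.column(0), aln.column(1)
        pruner = PairPruner(tree12, col_a, col_b)
        s = 0.37
        ll = pruner.loglik(s, s)
        # matched rate multipliers: pairwise move rate r/(N-1) = s
        prod = pruning_loglik_column(
            tree12, col_a, ColumnModel(pruner.states_a, (pruner.na - 1) * s)
        ) + pruning_loglik_column(
            tree12, col_b, ColumnModel(pruner.states_b, (pruner.nb - 1) * s)
        )
        assert ll == pytest.approx(prod, abs=1e-8)

    def test_full_profile_equals_symmetric_product_chain(self, tree4):
        col_a = {"A": "A", "B": "C", "C": "A", "D": "C"}
        col_b = {"A": "D", "B": "E", "C": "E", "D": "D"}
        space = frozenset({(a, b) for a in "AC" for b in "DE"})
        model = CoevModel(("A", "C"), ("D", "E"), space, s=0.8, d=0.8)
        ll = coev_loglik(tree4, col_a, col_b, model)
        prod = pruning_loglik_column(
            tree4, col_a, ColumnModel(("A", "C"), 0.8)
        ) + pruning_loglik_column(tree4, col_b, ColumnModel(("D", "E"), 0.8))
        assert ll == pytest.approx(prod, abs=1e-8)

    def test_infinite_time_reaches_stationarity(self):
        tree = PhyloTree.from_newick("(A:60,B:60);")
        model = small_model(3.0, 0.6)
        col_a, col_b = {"A": "A", "B": "C"}, {"A": "D", "B": "E"}
        pi = coev_stationary(model)
        idx = {p: i for i, p in enumerate(model.pair_states)}
        expected = np.log(pi[idx[("A", "D")]]) + np.log(pi[idx[("C", "E")]])
        assert coev_loglik(tree, col_a, col_b, model) == pytest.approx(expected, abs=1e-6)

    def test_loglik_never_positive(self, tree12):
        from cochap.simulate import simulate_alignment_coev

        aln = simulate_alignment_coev(
            tree12, {("D", "K")}, 1.0, 0.3, 1, 5, states_a="DEK", states_b="KRD"
        )
        pruner = PairPruner(tree12, aln.column(0), aln.column(1))
        for s, d in [(0.1, 0.1), (1.0, 0.2), (5.0, 0.5)]:
            assert pruner.loglik(s, d) <= 1e-12

    def test_gap_pairs_are_missing_data(self, tree4):
        col_a = {"A": "A", "B": "-", "C": "A", "D": "C"}
        col_b = {"A": "D", "B": "D", "C": "E", "D": "E"}
        pruner = PairPruner(tree4, col_a, col_b)
        assert pruner.n_ungapped == 3
        ll = pruner.loglik(1.0, 0.5)
        # marginalizing the gapped leaf by hand over its pair states
        total = 0.0
        model = CoevModel(
            pruner.states_a, pruner.states_b, pruner.profile, 1.0, 0.5
        )
        for a in pruner.states_a:
            for b in pruner.states_b:
                filled_a = {**col_a, "B": a}
                filled_b = {**col_b, "B": b}
                total += np.exp(coev_loglik(tree4, filled_a, filled_b, model))
        assert ll == pytest.approx(np.log(total), abs=1e-8)
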
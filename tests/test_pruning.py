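import itertools

import numpy as np
import pytest

from cochap.phylo.pruning import (
    ColumnModel,
    ancestral_marginal,
    pruning_loglik_column,
    symmetric_transition_factors,
)
from cochap.phylo.tree import PhyloTree


def transition_matrix(n, rate, t):
    ps, pd = symmetric_transition_factors(n, rate, t)
    M = np.full((n, n), pd)
    np.fill_diagonal(M, ps)
    return M


def brute_force_loglik(tree, column, model):
    """Sum over all internal-node state assignments (exhaustive oracle)."""
    n = model.n
    idx = {s: i for i, s in enumerate(model.states)}
    internals = [nd for nd in tree.postorder() if not nd.is_leaf]
    total = 0.0
    for assignment in itertools.product(range(n), repeat=len(internals)):
        state = dict(zip(internals, assignment))
        p = 1.0 / n  # uniform root
        ok = True
        for nd in tree.postorder():
            if nd.parent is None:
                continue
            P = transition_matrix(n, model.rate, nd.length)
            target = idx[column[nd.name]] if nd.is_leaf else state[nd]
            p *= P[state[nd.parent], target]
        total += p
    return np.log(total)


class TestPruning:
    def test_two_leaves_zero_branches_same_state(self):
        tree = PhyloTree.from_newick("(A:0,B:0);")
        model = ColumnModel(("A", "C", "D"), 1.0)
        ll = pruning_loglik_column(tree, {"A": "A", "B": "A"}, model)
        assert ll == pytest.approx(np.log(1 / 3))

    def test_two_leaves_zero_branches_different_states_impossible(self):
        tree = PhyloTree.from_newick("(A:0,B:0);")
        model = ColumnModel(("A", "C", "D"), 1.0)
        assert pruning_loglik_column(tree, {"A": "A", "B": "C"}, model) == -np.inf

    @pytest.mark.parametrize("rate", [0.3, 1.0, 2.5])
    def test_matches_exhaustive_enumeration(self, tree4, rate):
        model = ColumnModel(("A", "C", "D", "E"), rate)
        column = {"A": "A", "B": "C", "C": "A", "D": "E"}
        assert pruning_loglik_column(tree4, column, model) == pytest.approx(
            brute_force_loglik(tree4, column, model), abs=1e-10
        )

    def test_gap_is_missing_data(self, tree4):
        model = ColumnModel(("A", "C"), 1.0)
        full = pruning_loglik_column(tree4, {"A": "A", "B": "-", "C": "A", "D": "-"}, model)
        # marginalizing the gapped leaves by hand: sum over their states
        total = 0.0
        for b in "AC":
            for d in "AC":
                total += np.exp(
                    brute_force_loglik(tree4, {"A": "A", "B": b, "C": "A", "D": d}, model)
                )
        assert full == pytest.approx(np.log(total), abs=1e-10)

    def test_transition_rows_sum_to_one(self):
        for n in (2, 4, 20):
            for t in (0.0, 0.1, 3.0):
                ps, pd = symmetric_transition_factors(n, 1.3, t)
                assert ps + (n - 1) * pd == pytest.approx(1.0, abs=1e-12)

    def test_likelihood_sums_to_one_over_all_observations(self):
        # 3-leaf tree, 3 states: sum of exp(logL) over all leaf data = 1
        tree = PhyloTree.from_newick("((A:0.2,B:0.4):0.3,C:0.6);")
        model = ColumnModel(("A", "C", "D"), 0.9)
        total = 0.0
        for obs in itertools.product("ACD", repeat=3):
            col = dict(zip("ABC", obs))
            total += np.exp(pruning_loglik_column(tree, col, model))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_state_outside_model_rejected(self, tree4):
        model = ColumnModel(("A", "C"), 1.0)
        with pytest.raises(ValueError):
            pruning_loglik_column(tree4, {"A": "W", "B": "A", "C": "A", "D": "A"}, model)


class TestAncestralMarginal:
    def test_zero_time_everywhere_pins_ancestors(self):
        tree = PhyloTree.from_newick("((A:0,B:0):0,(C:0,D:0):0);")
        model = ColumnModel(("D", "N", "E"), 1.0)
        post = ancestral_marginal(tree, dict.fromkeys("ABCD", "D"), model)
        for node, p in post.items():
            assert p[model.index("D")] == pytest.approx(1.0)

    def test_posteriors_normalized(self, tree4):
        model = ColumnModel(("A", "C", "D", "E"), 0.7)
        post = ancestral_marginal(tree4, {"A": "A", "B": "C", "C": "D", "D": "E"}, model)
        for p in post.values():
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_two_leaf_root_is_undecided(self):
        tree = PhyloTree.from_newick("(A:0.5,B:0.5);")
        model = ColumnModel(("D", "N"), 1.0)
        post = ancestral_marginal(tree, {"A": "D", "B": "N"}, model)
        root_p = post[tree.root]
        assert root_p[0] == pytest.approx(0.5, abs=1e-12)

    def test_root_posterior_consistent_with_likelihood(self, tree4):
        # posterior at the root uses the same partials as the likelihood:
        # P(state|data) must equal P(data|state)/N / P(data)
        model = ColumnModel(("A", "C", "D"), 1.2)
        column = {"A": "A", "B": "C", "C": "A", "D": "D"}
        post = ancestral_marginal(tree4, column, model)
        ll = pruning_loglik_column(tree4, column, model)
        direct = []
        for state in model.states:
            # condition the root by an auxiliary zero-length leaf
            aug = PhyloTree.from_newick("(((A:0.3,B:0.5):0.2,(C:0.1,D:0.7):0.4):0,R:0);")
            ll_joint = pruning_loglik_column(aug, {**column, "R": state}, model)
            direct.append(np.exp(ll_joint - ll))
        np.testing.assert_allclose(post[tree4.root], direct, atol=1e-10)

    def test_all_gap_column_warns_uniform(self, tree4):
        model = ColumnModel(("A", "C"), 1.0)
        with pytest.warns(UserWarning):
            post = ancestral_marginal(tree4, dict.fromkeys("ABCD", "-"), model)
        for p in post.values():
            np.testing.assert_allclose(p, 0.5)
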
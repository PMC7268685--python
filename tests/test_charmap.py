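"""Parsimony, Mk fitting, marginal reconstruction, and stochastic mapping."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from phyloscreen import charmap
from phyloscreen.charmap import (
    MkModel,
    fitch_count,
    marginal_ancestral,
    mk_fit,
    mk_model_select,
    sankoff,
    scm_sample,
)
from phyloscreen.errors import StateError
from phyloscreen.seqio import tree_from_newick
from phyloscreen.simulate import SimulationSpec, simulate_characters, simulate_tree


QUARTET = "((A:1,B:1):1,(C:1,D:1):1);"


class TestSankoff:
    def test_constant_character(self):
        t = tree_from_newick(QUARTET)
        r = sankoff(t, {"A": "0", "B": "0", "C": "0", "D": "0"}, states=("0", "1"))
        assert r.min_changes == 0
        assert all(s == frozenset({"0"}) for s in r.node_states.values())

    def test_two_cherries_one_change(self):
        t = tree_from_newick(QUARTET)
        r = sankoff(t, {"A": "0", "B": "0", "C": "1", "D": "1"})
        assert r.min_changes == 1
        root_label = [k for k in r.node_states if k.startswith("N")][-1]
        assert r.node_states[root_label] == frozenset({"0", "1"})

    def test_alternating_states_two_changes(self):
        t = tree_from_newick(QUARTET)
        r = sankoff(t, {"A": "0", "B": "1", "C": "0", "D": "1"})
        assert r.min_changes == 2

    def test_missing_tip_allows_all_states(self):
        t = tree_from_newick(QUARTET)
        r = sankoff(t, {"A": "0", "B": "0", "C": "0", "D": "?"}, states=("0", "1"))
        assert r.min_changes == 0

    def test_undeclared_state_rejected(self):
        t = tree_from_newick(QUARTET)
        with pytest.raises(StateError):
            sankoff(t, {"A": "0", "B": "2", "C": "0", "D": "0"}, states=("0", "1"))

    def test_unambiguous_changes_listed(self):
        t = tree_from_newick("((A:1,B:1):1,((C:1,D:1):1,E:1):1);")
        char = {"A": "0", "B": "0", "C": "1", "D": "1", "E": "0"}
        r = sankoff(t, char)
        assert r.min_changes == 1
        assert [(frm, to) for _, frm, to in r.changes] == [("0", "1")]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_fitch_on_binary_trees(self, seed):
        """Unit-cost Sankoff equals the Fitch pass count."""
        rng = np.random.default_rng(seed)
        spec = SimulationSpec(n_taxa=int(rng.integers(4, 12)), seed=seed)
        tree = simulate_tree(spec)
        taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
        char = {t: str(rng.integers(2)) for t in taxa}
        if len(set(char.values())) < 2:
            char[taxa[0]] = "1" if char[taxa[0]] == "0" else "0"
        assert sankoff(tree, char).min_changes == fitch_count(tree, char)


class TestMkFit:
    def test_grid_search_oracle(self):
        """ER rate MLE matches a fine 1-D grid search on the likelihood."""
        t = tree_from_newick(QUARTET)
        char = {"A": "0", "B": "1", "C": "0", "D": "1"}
        fit = mk_fit(t, char, "ER")
        grid = np.logspace(-4, 1, 600)
        best = max(
            np.log(marginal_likelihood(t, char, MkModel(("0", "1"), "ER",
                                                        np.array([q]))))
            for q in grid
        )
        assert fit.loglik >= best - 1e-9
        assert fit.loglik == pytest.approx(best, abs=1e-4)

    def test_two_leaf_er_closed_form(self):
        """Two tips in different states: L(q) = (1 - exp(-2 q T)) / 4."""
        t = tree_from_newick("(A:0.6,B:0.4);")
        char = {"A": "0", "B": "1"}
        fit = mk_fit(t, char, "ER")
        q = fit.rate_params[0]
        closed = np.log((1 - np.exp(-2 * q * 1.0)) / 4)
        assert fit.loglik == pytest.approx(closed, abs=1e-8)
        # likelihood is monotone increasing in q: the fit reaches the
        # saturation plateau L -> 1/4
        assert fit.loglik == pytest.approx(np.log(0.25), abs=1e-6)

    def test_constant_character_rate_at_lower_bound(self):
        t = tree_from_newick(QUARTET)
        fit = mk_fit(t, {x: "0" for x in "ABCD"}, "ER", states=("0", "1"))
        assert fit.at_bound
        assert fit.loglik == pytest.approx(np.log(0.5), abs=1e-4)

    def test_nested_loglik_ordering(self):
        """ARD logL >= SYM logL >= ER logL (nested models)."""
        spec = SimulationSpec(n_taxa=15, seed=13, tree_height=1.5)
        tree = simulate_tree(spec)
        mk_true = MkModel(("0", "1", "2"), "ER", np.array([0.6]))
        cm = simulate_characters(tree, mk_true, 12, seed=3)
        for name in cm.characters[:3]:
            char = cm.column(name)
            if len(set(char.values())) < 3:
                continue
            fits = mk_model_select(tree, char)
            assert fits["ARD"].loglik >= fits["SYM"].loglik - 1e-6
            assert fits["SYM"].loglik >= fits["ER"].loglik - 1e-6

    def test_aic_penalizes_parameters(self):
        t = tree_from_newick(QUARTET)
        fit = mk_fit(t, {"A": "0", "B": "1", "C": "0", "D": "1"}, "ER")
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.loglik)


def marginal_likelihood(tree, char, model):
    """Oracle: total tip likelihood by enumerating internal states."""
    ti = charmap.TreeIndex(tree, [lf.taxon.label for lf in tree.leaf_node_iter()])
    labels = [n.taxon.label if n.taxon else None for n in ti.nodes]
    internal = [i for i in range(ti.n_nodes) if ti.children[i]]
    k = model.k
    lookup = {s: i for i, s in enumerate(model.states)}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        state = dict(zip(internal, assign))
        term = model.root_prior[state[ti.root]]
        for p, c, t in ti.edge_list():
            P = model.transition(t)
            if ti.children[c]:
                term *= P[state[p], state[c]]
            else:
                term *= P[state[p], lookup[char[labels[c]]]]
        total += term
    return total


class TestMarginalAncestral:
    def test_tips_are_point_masses(self):
        t = tree_from_newick(QUARTET)
        model = MkModel(("0", "1"), "ER", np.array([0.4]))
        post = marginal_ancestral(t, {"A": "0", "B": "0", "C": "1", "D": "1"}, model)
        assert post.loc["A", "0"] == pytest.approx(1.0)
        assert post.loc["C", "1"] == pytest.approx(1.0)

    def test_low_rate_root_follows_tips(self):
        t = tree_from_newick(QUARTET)
        model = MkModel(("0", "1"), "ER", np.array([1e-8]))
        post = marginal_ancestral(t, {x: "0" for x in "ABCD"}, model)
        root = [ix for ix in post.index if ix.startswith("N")][-1]
        assert post.loc[root, "0"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_enumeration_oracle(self):
        """Node posteriors equal direct enumeration over internal states."""
        tree = tree_from_newick("((A:0.5,B:0.7):0.3,C:0.9);")
        char = {"A": "0", "B": "1", "C": "0"}
        model = MkModel(("0", "1"), "ARD", np.array([0.7, 0.3]))
        post = marginal_ancestral(tree, char, model)
        # oracle: P(internal node state | tips) by brute force
        ti = charmap.TreeIndex(tree, ["A", "B", "C"])
        labels = [n.taxon.label if n.taxon else None for n in ti.nodes]
        internal = [i for i in range(ti.n_nodes) if ti.children[i]]
        lookup = {"0": 0, "1": 1}
        joint = np.zeros((len(internal), 2))
        for assign in itertools.product(range(2), repeat=len(internal)):
            state = dict(zip(internal, assign))
            term = model.root_prior[state[ti.root]]
            for p, c, t in ti.edge_list():
                P = model.transition(t)
                if ti.children[c]:
                    term *= P[state[p], state[c]]
                else:
                    term *= P[state[p], lookup[char[labels[c]]]]
            for row, i in enumerate(internal):
                joint[row, state[i]] += term
        joint /= joint.sum(axis=1, keepdims=True)
        post_internal = post.loc[[ix for ix in post.index if ix.startswith("N")]]
        assert np.allclose(post_internal.to_numpy(), joint, atol=1e-10)


@pytest.fixture(scope="module")
def fixture_tree_char():
    spec = SimulationSpec(n_taxa=10, seed=11, tree_height=1.0)
    tree = simulate_tree(spec)
    mk_true = MkModel(("0", "1"), "ER", np.array([0.8]))
    cm = simulate_characters(tree, mk_true, 5, seed=4)
    return tree, cm.column(cm.characters[0])


class TestSCM:
    def test_same_seed_same_summaries(self, fixture_tree_char):
        tree, char = fixture_tree_char
        model = MkModel(("0", "1"), "ER", np.array([0.8]))
        a = scm_sample(tree, char, model, n_histories=300, seed=5)
        b = scm_sample(tree, char, model, n_histories=300, seed=5)
        assert a.node_freqs.equals(b.node_freqs)
        assert a.transitions.equals(b.transitions)
        assert a.dwell.equals(b.dwell)

    def test_near_zero_rate_constant_histories(self):
        t = tree_from_newick(QUARTET)
        model = MkModel(("0", "1"), "ER", np.array([1e-9]))
        r = scm_sample(t, {x: "0" for x in "ABCD"}, model, n_histories=100, seed=1)
        assert np.allclose(r.node_freqs["0"].to_numpy(), 1.0)
        assert r.expected_changes == 0.0

    def test_node_freqs_match_marginal_within_mc_error(self, fixture_tree_char):
        tree, char = fixture_tree_char
        model = mk_fit(tree, char, "ER")
        n = 4000
        r = scm_sample(tree, char, model, n_histories=n, seed=7)
        marg = marginal_ancestral(tree, char, model)
        for node in marg.index:
            for s in model.states:
                p = marg.loc[node, s]
                se = np.sqrt(max(p * (1 - p), 1e-12) / n)
                assert abs(r.node_freqs.loc[node, s] - p) <= max(3 * se, 5e-3)

    def test_expected_changes_at_least_parsimony(self, fixture_tree_char):
        tree, char = fixture_tree_char
        model = mk_fit(tree, char, "ER")
        r = scm_sample(tree, char, model, n_histories=500, seed=9)
        assert r.expected_changes >= sankoff(tree, char).min_changes - 1e-9

    def test_dwell_times_sum_to_tree_length(self, fixture_tree_char):
        tree, char = fixture_tree_char
        model = MkModel(("0", "1"), "ER", np.array([0.8]))
        r = scm_sample(tree, char, model, n_histories=400, seed=3)
        total = sum(e.length or 0.0 for e in tree.preorder_edge_iter())
        assert r.dwell.sum() == pytest.approx(total, rel=1e-9)

    def test_uniformization_bridge_agrees_with_rejection(self):
        """Forcing the fallback gives the same endpoint-conditioned moments."""
        t = tree_from_newick(QUARTET)
        char = {"A": "0", "B": "1", "C": "0", "D": "1"}
        model = MkModel(("0", "1"), "ER", np.array([0.5]))
        rej = scm_sample(t, char, model, n_histories=3000, seed=2)
        uni = scm_sample(
            t, char, model, n_histories=3000, seed=2, rejection_cap=0
        )
        assert uni.n_fallback > 0 and rej.n_fallback == 0
        assert uni.expected_changes == pytest.approx(rej.expected_changes, rel=0.1)
        assert np.allclose(
            uni.dwell.to_numpy(), rej.dwell.to_numpy(), rtol=0.1
        )
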
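"""Substitution models, gamma rates, and pruning likelihoods vs oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from phyloscreen import models
from phyloscreen.errors import UnknownTaxonError
from phyloscreen.models import (
    SubstitutionModel,
    discrete_gamma_rates,
    empirical_freqs,
    jc_model,
    poisson_model,
    pruning_loglik,
    read_paml_rates,
    transition_matrix,
)
from phyloscreen.seqio import Alphabet, tree_from_newick

from conftest import aln_from_strings


def brute_force_loglik(tree, aln, model, root_freqs=None) -> float:
    """Independent oracle: enumerate every internal-state assignment."""
    ti = models.TreeIndex(tree, aln.taxa)
    codes = aln.encode()
    pi = np.asarray(root_freqs if root_freqs is not None else model.freqs)
    k = len(pi)
    internal = [i for i in range(ti.n_nodes) if ti.children[i]]
    rates = model.rates()
    total = 0.0
    for site in range(aln.n_sites):
        site_lik = 0.0
        for rate in rates:
            Ps = {}
            for p, c, t in ti.edge_list():
                Ps[(p, c)] = model.transition(t, rate)
            lik = 0.0
            for assign in itertools.product(range(k), repeat=len(internal)):
                state = {n: s for n, s in zip(internal, assign)}
                term = pi[state[ti.root]]
                for p, c, t in ti.edge_list():
                    if ti.children[c]:
                        term *= Ps[(p, c)][state[p], state[c]]
                    else:
                        obs = codes[ti.leaf_rows[c], site]
                        if obs < 0:
                            term *= 1.0
                        else:
                            term *= Ps[(p, c)][state[p], obs]
                lik += term
            site_lik += lik / len(rates)
        total += np.log(site_lik)
    return total


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        m = jc_model()
        assert np.allclose(transition_matrix(m, 0.0), np.eye(4), atol=1e-12)

    def test_long_time_reaches_stationarity(self):
        m = jc_model()
        assert np.allclose(transition_matrix(m, 1e4), np.full((4, 4), 0.25))

    def test_jc_closed_form(self):
        m = jc_model()
        expected = (1 - np.exp(-4 * 0.1 / 3)) / 4
        P = transition_matrix(m, 0.1)
        off = P[~np.eye(4, dtype=bool)]
        assert np.allclose(off, expected, atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        S = rng.random((4, 4))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0)
        pi = rng.dirichlet(np.ones(4))
        m = SubstitutionModel(Alphabet.NT, S, pi)
        for t in (0.01, 0.5, 3.0):
            assert np.allclose(m.transition(t).sum(axis=1), 1.0, atol=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            jc_model().transition(-0.1)

    def test_detailed_balance(self):
        rng = np.random.default_rng(1)
        S = rng.random((4, 4))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0)
        pi = rng.dirichlet(np.ones(4))
        Q = SubstitutionModel(Alphabet.NT, S, pi).Q
        assert np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-12)


class TestDiscreteGamma:
    def test_single_category(self):
        assert discrete_gamma_rates(0.7, 1).tolist() == [1.0]

    def test_large_alpha_collapses_to_one(self):
        rates = discrete_gamma_rates(1e6, 4)
        assert np.allclose(rates, 1.0, atol=1e-2)

    def test_mean_is_one(self):
        for alpha in (0.2, 0.5, 1.0, 3.0):
            assert discrete_gamma_rates(alpha, 4).mean() == pytest.approx(
                1.0, abs=1e-8
            )

    def test_alpha_one_matches_quadrature_oracle(self):
        """Category means of quartile segments of a mean-1 gamma(1) = Exp(1)."""
        k, alpha = 4, 1.0
        edges = gamma_dist.ppf(np.arange(k + 1) / k, alpha, scale=1 / alpha)
        edges[-1] = np.inf
        expected = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            val, _ = quad(
                lambda x: x * gamma_dist.pdf(x, alpha, scale=1 / alpha), lo,
                min(hi, 60.0),
            )
            expected.append(val * k)
        assert np.allclose(discrete_gamma_rates(alpha, k), expected, atol=1e-6)


class TestModelConstruction:
    def test_empirical_freqs_with_pseudocount(self):
        aln = aln_from_strings({"x": "AAAA", "y": "AAAC"}, Alphabet.NT)
        f = empirical_freqs(aln, pseudocount=1.0)
        assert f.sum() == pytest.approx(1.0)
        assert f[0] == pytest.approx(8 / 12)  # (7 A + 1) / (8 + 4)
        assert np.all(f > 0)

    def test_paml_rate_file(self, tmp_path):
        p = tmp_path / "toy.dat"
        p.write_text("1.0\n2.0 3.0\n4.0 5.0 6.0\n\n0.1 0.2 0.3 0.4\n")
        m = read_paml_rates(p, Alphabet.NT)
        assert m.exchangeability[1, 0] == 1.0
        assert m.exchangeability[3, 1] == 5.0
        assert np.allclose(m.freqs, [0.1, 0.2, 0.3, 0.4])


class TestPruning:
    def test_zero_branch_identical_sequences(self, balanced_quartet_tree):
        tree = tree_from_newick("((A:0,B:0):0,(C:0,D:0):0);")
        aln = aln_from_strings(
            {"A": "A", "B": "A", "C": "A", "D": "A"}, Alphabet.NT
        )
        res = pruning_loglik(tree, aln, jc_model(alpha=None, n_cat=1))
        assert res.loglik == pytest.approx(np.log(0.25), abs=1e-12)

    def test_all_missing_site_contributes_zero(self, balanced_quartet_tree):
        aln = aln_from_strings(
            {"A": "-A", "B": "-A", "C": "-A", "D": "-A"}, Alphabet.NT
        )
        res = pruning_loglik(balanced_quartet_tree, aln, jc_model())
        assert res.site_logliks[0] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_leaf_rejected(self, balanced_quartet_tree):
        aln = aln_from_strings({"A": "A", "B": "A", "C": "A"}, Alphabet.NT)
        with pytest.raises(UnknownTaxonError):
            pruning_loglik(balanced_quartet_tree, aln, jc_model())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_enumeration(self, seed):
        """Pruning equals exhaustive internal-state enumeration, 5 taxa."""
        rng = np.random.default_rng(seed)
        newick = "((A:{}, B:{}):{}, (C:{}, (D:{}, E:{}):{}):{});".format(
            *rng.uniform(0.05, 0.6, size=8)
        )
        tree = tree_from_newick(newick)
        rows = {
            t: "".join(rng.choice(list("ACGT-"), size=30, p=[0.23] * 4 + [0.08]))
            for t in "ABCDE"
        }
        aln = aln_from_strings(rows, Alphabet.NT)
        S = rng.random((4, 4))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0)
        model = SubstitutionModel(
            Alphabet.NT, S, rng.dirichlet(np.ones(4)), alpha=0.8, n_cat=3
        )
        fast = pruning_loglik(tree, aln, model).loglik
        slow = brute_force_loglik(tree, aln, model)
        assert fast == pytest.approx(slow, abs=1e-6)

    def test_root_placement_invariance(self):
        """Reversible models give the same likelihood for any rooting of the
        same unrooted tree."""
        rng = np.random.default_rng(3)
        rows = {t: "".join(rng.choice(list("ACGT"), size=40)) for t in "ABCD"}
        aln = aln_from_strings(rows, Alphabet.NT)
        model = jc_model(alpha=1.0, n_cat=4)
        t1 = tree_from_newick("((A:0.1,B:0.2):0.15,(C:0.3,D:0.1):0.05);")
        t2 = tree_from_newick("(A:0.1,B:0.2,(C:0.3,D:0.1):0.2);")
        l1 = pruning_loglik(t1, aln, model).loglik
        l2 = pruning_loglik(t2, aln, model).loglik
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_likelihood_prefers_generating_branch_lengths(self):
        """On average, logL at the true branch lengths beats a doubled tree."""
        from phyloscreen.simulate import SimulationSpec, simulate_alignment, simulate_tree

        spec = SimulationSpec(
            n_taxa=6, n_partitions=1, partition_length=400, seed=5,
            tree_height=0.4, alphabet=Alphabet.NT, gamma_alpha=None,
        )
        tree = simulate_tree(spec)
        model = poisson_model(Alphabet.NT, alpha=None, n_cat=1)
        aln = simulate_alignment(tree, spec, model=model)
        l_true = pruning_loglik(tree, aln, model).loglik
        doubled = tree.clone(depth=1)
        for e in doubled.preorder_edge_iter():
            if e.length:
                e.length *= 3.0
        l_far = pruning_loglik(doubled, aln, model).loglik
        assert l_true > l_far
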
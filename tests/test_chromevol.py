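"""Chromosome-number CTMC: generator, likelihood, fitting, ancestry."""

import itertools

import numpy as np
import pytest

from karyoevol._ctmc import Propagator
from karyoevol.chromevol import (
    ChromModel,
    ancestral_marginal,
    build_q,
    default_bounds,
    fit,
    likelihood,
)
from karyoevol.simulate import sim_bd_tree, sim_discrete
from karyoevol.trees import read_newick


class TestGenerator:
    @pytest.mark.parametrize("seed", range(10))
    def test_rows_sum_to_zero_for_random_models(self, seed):
        rng = np.random.default_rng(seed)
        g, l, rho, d = rng.uniform(0, 3, size=4)
        model = ChromModel(gain=g, loss=l, dupl=rho, demi=d,
                           gain_linear=rng.normal(scale=0.1),
                           loss_linear=rng.normal(scale=0.1),
                           n_min=1, n_max=int(rng.integers(10, 30)))
        Q = build_q(model)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-10)
        off = Q[~np.eye(Q.shape[0], dtype=bool)]
        assert (off >= 0).all()

    def test_demi_duplication_targets(self):
        model = ChromModel(gain=0.0, loss=0.0, demi=1.0, n_min=1, n_max=20)
        Q = build_q(model)
        # even state: single target at 1.5n
        assert Q[10 - 1, 15 - 1] == pytest.approx(1.0)
        # odd state: equal split between floor and ceil of 1.5n
        assert Q[11 - 1, 16 - 1] == pytest.approx(0.5)
        assert Q[11 - 1, 17 - 1] == pytest.approx(0.5)

    def test_transition_rows_are_proper_distributions(self):
        model = ChromModel(gain=1.5, loss=0.5, dupl=0.3, demi=0.2,
                           n_min=1, n_max=25)
        prop = Propagator(build_q(model))
        for b in (0.01, 0.5, 3.0):
            np.testing.assert_allclose(prop(b).sum(axis=1), 1.0, atol=1e-9)

    def test_default_bounds_allow_one_duplication(self):
        assert default_bounds({"a": 7, "b": 11}) == (1, 24)


class TestLikelihood:
    def test_zero_branches_give_log_prior(self):
        tree = read_newick("(A:0,B:0);")
        model = ChromModel(gain=1.0, loss=1.0, n_min=1, n_max=10)
        lnl = likelihood(tree, {"A": 4, "B": 4}, model)
        assert lnl == pytest.approx(np.log(1 / 10))

    def test_matches_enumeration_oracle_three_tips(self):
        tree = read_newick("((A:0.3,B:0.5):0.4,C:0.9);")
        tips = {"A": 5, "B": 6, "C": 4}
        model = ChromModel(gain=1.0, loss=0.7, dupl=0.2, demi=0.1,
                           n_min=1, n_max=12)
        Q = build_q(model)
        prop = Propagator(Q)
        k = Q.shape[0]
        PA, PB = prop(0.3), prop(0.5)
        PI, PC = prop(0.4), prop(0.9)
        total = sum(
            (1 / k) * PI[r, i] * PA[i, 4] * PB[i, 5] * PC[r, 3]
            for r, i in itertools.product(range(k), repeat=2))
        assert likelihood(tree, tips, model) == pytest.approx(
            np.log(total), abs=1e-10)

    def test_invariant_to_tip_order(self):
        tree = read_newick("((A:0.3,B:0.5):0.4,C:0.9);")
        model = ChromModel(gain=1.0, loss=0.7, n_min=1, n_max=12)
        a = likelihood(tree, {"A": 5, "B": 6, "C": 4}, model)
        b = likelihood(tree, {"C": 4, "B": 6, "A": 5}, model)
        assert a == b

    def test_all_rates_zero_on_variable_data_is_minus_inf(self):
        tree = read_newick("(A:1,B:1);")
        model = ChromModel(gain=0.0, loss=0.0, n_min=1, n_max=10)
        assert likelihood(tree, {"A": 3, "B": 7}, model) == -np.inf

    def test_state_out_of_bounds_rejected(self):
        tree = read_newick("(A:1,B:1);")
        model = ChromModel(gain=1.0, loss=1.0, n_min=1, n_max=5)
        with pytest.raises(ValueError, match="outside"):
            likelihood(tree, {"A": 3, "B": 7}, model)


class TestFit:
    def test_nested_family_never_beats_superset(self):
        model = ChromModel(gain=1.0, loss=0.5, demi=0.6, n_min=1, n_max=24)
        tree = sim_bd_tree(40, 1.0, seed=31)
        tips, _ = sim_discrete(tree, build_q(model), root_state=7, seed=32)
        states = {k: v + 1 for k, v in tips.items()}
        small = fit(tree, states, "dysploidy", n_starts=1, seed=0)
        large = fit(tree, states, "dysploidy_demi", n_starts=1, seed=0,
                    bounds=(small.model.n_min, small.model.n_max))
        assert large.lnl >= small.lnl - 1e-4
        assert large.k == small.k + 1


class TestAncestral:
    def test_probabilities_sum_to_one(self):
        model = ChromModel(gain=1.2, loss=0.8, n_min=1, n_max=16)
        tree = sim_bd_tree(15, 1.0, seed=33)
        tips, _ = sim_discrete(tree, build_q(model), root_state=6, seed=34)
        recon = ancestral_marginal(tree, {k: v + 1 for k, v in tips.items()},
                                   model)
        for node, p in recon.probs.items():
            assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_two_state_root_is_uniform(self):
        # two states, symmetric rates, one tip in each state
        tree = read_newick("(A:1,B:1);")
        model = ChromModel(gain=0.7, loss=0.7, n_min=1, n_max=2)
        recon = ancestral_marginal(tree, {"A": 1, "B": 2}, model)
        root = tree.root
        np.testing.assert_allclose(recon.probs[root], [0.5, 0.5], atol=1e-12)

    def test_true_states_fall_in_credible_sets(self):
        """95% marginal credible sets should cover the true (simulated)
        internal states at roughly their nominal rate."""
        model = ChromModel(gain=1.0, loss=0.8, n_min=1, n_max=24)
        Q = build_q(model)
        coverages = []
        for rep in range(20):
            tree = sim_bd_tree(100, 1.0, seed=800 + rep)
            tips, truth = sim_discrete(tree, Q, root_state=8, seed=900 + rep)
            recon = ancestral_marginal(
                tree, {k: v + 1 for k, v in tips.items()}, model)
            hits = total = 0
            for node, p in recon.probs.items():
                total += 1
                hits += (truth[node] + 1) in recon.credible_set(node, 0.95)
            coverages.append(hits / total)
        assert np.mean(coverages) >= 0.90
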
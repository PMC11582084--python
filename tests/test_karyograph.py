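"""Karyograph SSE model: state space, generator, likelihood, LRT."""

import numpy as np
import pytest

from karyoevol._ctmc import marginal_ancestral, pruning_loglik
from karyoevol.karyograph import (
    LrtResult,
    SseParams,
    ancestral_karyograph,
    build_q,
    enumerate_states,
    fit_sse,
    lrt_statistic,
    musse_loglik,
)
from karyoevol.simulate import sim_bd_tree, sim_discrete
from karyoevol.trees import read_newick


class TestStates:
    def test_counts_and_boundaries(self):
        assert len(enumerate_states(3)) == 9  # 2 + 3 + 4
        assert enumerate_states(1) == [(1, 1), (1, 2)]
        assert enumerate_states(5) == enumerate_states(5)  # stable order
        with pytest.raises(ValueError):
            enumerate_states(0)

    def test_all_states_satisfy_arm_constraint(self):
        for y, x in enumerate_states(12):
            assert y <= x <= 2 * y


class TestGenerator:
    def test_rate_laws_at_example_states(self):
        states = enumerate_states(6)
        idx = {s: i for i, s in enumerate(states)}
        p = SseParams(k1=0.7, k2=0.3, k3=0.2, k4=0.1, k5=0.05)
        Q = build_q(states, p)
        # (2,2): two telocentrics -> fusion at 2*k1; no fission (no
        # bi-armed chromosome to split), so outflow is only fusion,
        # arm gain at 2*k3 and polyploidy
        assert Q[idx[(2, 2)], idx[(1, 2)]] == pytest.approx(2 * 0.7)
        targets = {states[j] for j in np.nonzero(Q[idx[(2, 2)]] > 0)[0]}
        assert targets == {(1, 2), (2, 3), (4, 4)}
        # (1,2): one metacentric -> fission at k2, no fusion possible
        assert Q[idx[(1, 2)], idx[(2, 2)]] == pytest.approx(0.3)
        # polyploidy doubles both coordinates
        assert Q[idx[(2, 3)], idx[(4, 6)]] == pytest.approx(0.05)

    def test_transitions_never_leave_valid_region(self):
        states = enumerate_states(8)
        Q = build_q(states, SseParams(k1=1, k2=1, k3=1, k4=1, k5=1))
        for i, j in zip(*np.nonzero(Q > 0)):
            y, x = states[j]
            assert y <= x <= 2 * y
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-10)

    def test_m1_has_no_polyploidy_structurally(self):
        p = SseParams(k1=1, k2=1, k3=1, k4=1, k5=None)
        assert p.n_free == 6
        assert SseParams(k1=1, k2=1, k3=1, k4=1, k5=0.0).n_free == 7


@pytest.fixture(scope="module")
def sse_dataset():
    tree = sim_bd_tree(15, 1.0, seed=5)
    states = enumerate_states(8)
    Q = build_q(states, SseParams(k1=0.5, k2=0.3, k3=0.2, k4=0.1))
    tips, _ = sim_discrete(tree, Q, root_state=states.index((4, 6)), seed=6)
    return tree, {name: states[i] for name, i in tips.items()}


class TestLikelihood:
    def test_reduces_to_ctmc_pruning_without_diversification(self, sse_dataset):
        tree, tip_states = sse_dataset
        p = SseParams(k1=0.5, k2=0.3, k3=0.2, k4=0.1, lam=0.0, mu=0.0)
        states = enumerate_states(8)
        lnl = musse_loglik(tree, tip_states, p, y_max=8, root="flat")
        idx = {s: i for i, s in enumerate(states)}
        oracle = pruning_loglik(tree, {n: idx[s] for n, s in
                                       tip_states.items()},
                                build_q(states, p))
        assert lnl == pytest.approx(oracle, abs=1e-8)

    def test_ode_integration_agrees_with_closed_form(self, sse_dataset):
        tree, tip_states = sse_dataset
        p = SseParams(k1=0.5, k2=0.3, k3=0.2, k4=0.1, lam=0.8, mu=0.3)
        exact = musse_loglik(tree, tip_states, p, y_max=8, method="exact")
        ode = musse_loglik(tree, tip_states, p, y_max=8, method="ode")
        assert ode == pytest.approx(exact, abs=1e-6)

    def test_two_tip_analytic_solution_no_transitions(self):
        # both tips in the same state, q = 0, mu = 0: each branch only
        # contributes exp(-lam*t) and the node contributes lam, so
        # L(flat root) = lam * exp(-2 lam t) / n_states
        lam, t = 0.6, 1.3
        tree = read_newick(f"(A:{t},B:{t});")
        p = SseParams(lam=lam, mu=0.0)
        n_states = len(enumerate_states(4))
        expected = np.log(lam) - 2 * lam * t - np.log(n_states)
        for method in ("exact", "ode"):
            lnl = musse_loglik(tree, {"A": (3, 4), "B": (3, 4)}, p,
                               y_max=4, root="flat", method=method)
            assert lnl == pytest.approx(expected, abs=1e-7)

    def test_pure_fission_fusion_chain_reduction(self):
        # k3 = k4 = 0 conserves the arm count x, so with all tips at a
        # common x the dynamics is a birth-death chain in y alone
        tree = sim_bd_tree(10, 1.0, seed=9)
        x0, k1, k2 = 6, 0.4, 0.3
        y_states = list(range((x0 + 1) // 2, x0 + 1))  # y with y<=x0<=2y
        chain = np.zeros((len(y_states), len(y_states)))
        for i, y in enumerate(y_states):
            if i + 1 < len(y_states):
                chain[i, i + 1] = k2 * (x0 - y)        # fission
            if i > 0 and 2 * y - x0 >= 2:
                chain[i, i - 1] = k1 * (2 * y - x0)    # fusion
        np.fill_diagonal(chain, -chain.sum(axis=1))
        rng = np.random.default_rng(1)
        tip_y = {name: int(rng.choice(y_states[1:-1]))
                 for name in tree.tip_labels}
        lnl_chain = pruning_loglik(
            tree, {n: y_states.index(y) for n, y in tip_y.items()}, chain)
        full_states = enumerate_states(x0)
        p = SseParams(k1=k1, k2=k2, k3=0.0, k4=0.0)
        lnl_full = musse_loglik(tree, {n: (y, x0) for n, y in tip_y.items()},
                                p, y_max=x0, root="flat")
        # flat root priors differ only by the state-space size
        correction = np.log(len(y_states) / len(full_states))
        assert lnl_full == pytest.approx(lnl_chain + correction, abs=1e-8)


class TestLrt:
    def test_statistic_arithmetic(self):
        assert lrt_statistic(-342.2464, -331.4004) == pytest.approx(21.692)

    def test_identical_lnls_give_p_one(self):
        res = LrtResult.from_lnls(-10.0, -10.0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_boundary_p_is_half_the_standard_p(self):
        res = LrtResult.from_lnls(-12.0, -10.0)
        assert res.p_value_boundary == pytest.approx(res.p_value / 2)


class TestAncestral:
    def test_marginals_match_ctmc_factorization(self, sse_dataset):
        tree, tip_states = sse_dataset
        p = SseParams(k1=0.5, k2=0.3, k3=0.2, k4=0.1, lam=0.9, mu=0.4)
        recon = ancestral_karyograph(tree, tip_states, p, y_max=8,
                                     root="flat")
        states = enumerate_states(8)
        idx = {s: i for i, s in enumerate(states)}
        oracle = marginal_ancestral(
            tree, {n: idx[s] for n, s in tip_states.items()},
            build_q(states, p))
        for node, probs in oracle.items():
            np.testing.assert_allclose(recon.probs[node], probs, atol=1e-6)
            assert recon.probs[node].sum() == pytest.approx(1.0, abs=1e-9)

    def test_true_states_fall_in_credible_sets(self):
        p = SseParams(k1=0.4, k2=0.4, k3=0.5, k4=0.5)
        states = enumerate_states(8)
        Q = build_q(states, p)
        coverages = []
        for rep in range(20):
            tree = sim_bd_tree(50, 1.0, seed=700 + rep)
            tips, truth = sim_discrete(tree, Q,
                                       root_state=states.index((4, 6)),
                                       seed=750 + rep)
            recon = ancestral_karyograph(
                tree, {n: states[i] for n, i in tips.items()}, p,
                y_max=8, root="flat")
            hits = total = 0
            for node, probs in recon.probs.items():
                total += 1
                order = np.argsort(probs)[::-1]
                mass, cred = 0.0, set()
                for j in order:
                    cred.add(j)
                    mass += probs[j]
                    if mass >= 0.95:
                        break
                hits += truth[node] in cred
            coverages.append(hits / total)
        assert np.mean(coverages) >= 0.90


def test_fit_nesting_holds_on_small_dataset(sse_dataset):
    tree, tip_states = sse_dataset
    m1 = fit_sse(tree, tip_states, with_polyploidy=False, y_max=8,
                 n_starts=1, maxiter=40, seed=0)
    x0 = np.log(np.clip([m1.params.k1, m1.params.k2, m1.params.k3,
                         m1.params.k4, 1e-8, m1.params.lam, m1.params.mu],
                        1e-12, None))
    m2 = fit_sse(tree, tip_states, with_polyploidy=True, y_max=8,
                 n_starts=1, maxiter=40, seed=0, x0_extra=x0)
    assert m2.lnl >= m1.lnl - 1e-6
    assert m1.params.k5 is None and m2.params.k5 is not None
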
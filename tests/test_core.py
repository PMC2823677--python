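"""Unit and property tests for the plain link-component sampler."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icmodels import (
    Hyperparameters,
    InteractionNetwork,
    crisp_clusters,
    gibbs_sweep,
    init_assignments,
    joint_log_prob,
    link_conditional,
    node_memberships,
    run_chain,
)
from icmodels.core import run_chain_best
from icmodels.exceptions import DataError

from oracles import icm_enumerate, icm_joint_prob


def small_network(n_nodes: int, edges: list[tuple[int, int]]) -> InteractionNetwork:
    nodes = [f"n{i}" for i in range(n_nodes)]
    return InteractionNetwork(nodes=nodes, links=np.array(edges).reshape(-1, 2))


class TestInitAssignments:
    def test_no_links_gives_zero_counts(self):
        net = small_network(3, [])
        state = init_assignments(net, Hyperparameters(C=5), seed=0)
        assert np.array_equal(state.n, np.zeros(5, dtype=int))
        assert not state.q.any()

    def test_single_component_forces_all_zero(self, rng):
        edges = [(int(a), int(b)) for a, b in rng.integers(0, 4, size=(7, 2))]
        net = small_network(4, edges)
        state = init_assignments(net, Hyperparameters(C=1), seed=3)
        assert np.array_equal(state.z_links, np.zeros(7, dtype=int))
        assert state.n[0] == 7
        assert state.q.sum() == 14

    def test_deterministic_given_seed(self, rng):
        edges = [(int(a), int(b)) for a, b in rng.integers(0, 10, size=(100, 2))]
        net = small_network(10, edges)
        h = Hyperparameters(C=4)
        a = init_assignments(net, h, seed=11)
        b = init_assignments(net, h, seed=11)
        c = init_assignments(net, h, seed=12)
        assert np.array_equal(a.z_links, b.z_links)
        assert not np.array_equal(a.z_links, c.z_links)

    def test_empty_network_rejected(self):
        with pytest.raises(DataError, match="empty network"):
            InteractionNetwork(nodes=[], links=np.empty((0, 2), dtype=int))


class TestLinkConditional:
    def test_single_component_is_certain(self, triangle):
        state = init_assignments(triangle, Hyperparameters(C=1), seed=0)
        p = link_conditional(state, triangle, Hyperparameters(C=1), 0)
        assert p == pytest.approx([1.0])

    def test_only_link_in_data_is_uniform(self):
        net = small_network(2, [(0, 1)])
        h = Hyperparameters(C=3, alpha=2.0, beta=0.7)
        state = init_assignments(net, h, seed=0)
        p = link_conditional(state, net, h, 0)
        assert p == pytest.approx(np.full(3, 1 / 3))

    def test_matches_enumeration_on_triangle(self, triangle):
        """Conditional equals the exact ratio of enumerated collapsed joints."""
        h = Hyperparameters(C=2, alpha=1.0, beta=0.5)
        links = [tuple(l) for l in triangle.links]
        state = init_assignments(triangle, h, seed=4)
        for held in range(3):
            z = state.z_links.copy()
            probs = []
            for c in range(2):
                z[held] = c
                probs.append(icm_joint_prob(z, links, 3, 2, h.alpha, h.beta))
            expected = np.array(probs) / sum(probs)
            got = link_conditional(state, triangle, h, held)
            assert got == pytest.approx(expected, abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_sums_to_one_and_positive(self, seed):
        rng = np.random.default_rng(seed)
        edges = [(int(a), int(b)) for a, b in rng.integers(0, 5, size=(6, 2))]
        net = small_network(5, edges)
        h = Hyperparameters(C=3, alpha=0.5, beta=0.05)
        state = init_assignments(net, h, seed=seed)
        p = link_conditional(state, net, h, int(rng.integers(0, 6)))
        assert p.sum() == pytest.approx(1.0)
        assert (p > 0).all()


class TestJointLogProb:
    def test_empty_network_is_zero(self):
        net = small_network(3, [])
        state = init_assignments(net, Hyperparameters(C=4), seed=0)
        assert joint_log_prob(state, net, Hyperparameters(C=4)) == pytest.approx(0.0)

    def test_polya_urn_single_link(self):
        """One link on two nodes, C=1, alpha=beta=1: p = (1/2) * (1/3)."""
        net = small_network(2, [(0, 1)])
        h = Hyperparameters(C=1, alpha=1.0, beta=1.0)
        state = init_assignments(net, h, seed=0)
        assert joint_log_prob(state, net, h) == pytest.approx(np.log(1 / 6))

    def test_polya_urn_self_link(self):
        """A self-link's second endpoint repeats: p = (1/2) * (2/3)."""
        net = small_network(2, [(0, 0)])
        h = Hyperparameters(C=1, alpha=1.0, beta=1.0)
        state = init_assignments(net, h, seed=0)
        assert joint_log_prob(state, net, h) == pytest.approx(np.log(1 / 3))

    def test_matches_sequential_oracle(self, rng):
        """Gamma-function form equals the sequential Polya-urn product."""
        for _ in range(10):
            M = int(rng.integers(2, 6))
            N = int(rng.integers(1, 7))
            edges = [(int(a), int(b)) for a, b in rng.integers(0, M, size=(N, 2))]
            net = small_network(M, edges)
            h = Hyperparameters(C=3, alpha=1.7, beta=0.3)
            state = init_assignments(net, h, seed=int(rng.integers(1 << 20)))
            links = [tuple(l) for l in net.links]
            expected = np.log(
                icm_joint_prob(state.z_links, links, M, 3, h.alpha, h.beta)
            )
            assert joint_log_prob(state, net, h) == pytest.approx(expected)

    def test_invariant_to_component_relabeling(self, two_triangles, rng):
        h = Hyperparameters(C=3, alpha=2.0, beta=0.1)
        state = init_assignments(two_triangles, h, seed=9)
        base = joint_log_prob(state, two_triangles, h)
        for perm in itertools.permutations(range(3)):
            inv = np.argsort(perm)  # rows of n and q move with the labels
            permuted = state.copy()
            permuted.z_links = np.array([perm[z] for z in state.z_links])
            permuted.n = state.n[inv]
            permuted.q = state.q[inv]
            assert joint_log_prob(permuted, two_triangles, h) == pytest.approx(base)


class TestGibbsSweep:
    def test_single_component_leaves_state_unchanged(self, triangle):
        h = Hyperparameters(C=1)
        state = init_assignments(triangle, h, seed=0)
        before = state.z_links.copy()
        gibbs_sweep(state, triangle, h)
        assert np.array_equal(state.z_links, before)

    def test_counts_conserved_over_sweeps(self, two_triangles):
        h = Hyperparameters(C=3, alpha=1.0, beta=0.1)
        state = init_assignments(two_triangles, h, seed=1)
        for _ in range(20):
            gibbs_sweep(state, two_triangles, h)
            state.check()  # sum(n)=N and sum_i q_zi = 2 n_z

    def test_kernel_agrees_with_python_conditional(self, four_cycle):
        """One compiled sweep reproduces a manual replay that samples each
        link from link_conditional with the same uniform variates."""
        h = Hyperparameters(C=3, alpha=1.0, beta=0.5)
        state = init_assignments(four_cycle, h, seed=7)
        manual = state.copy()  # deep-copies the generator
        u = manual.rng.random(four_cycle.n_links)  # the stream the kernel uses
        for l in range(four_cycle.n_links):
            p = link_conditional(manual, four_cycle, h, l)
            znew = int(np.searchsorted(np.cumsum(p), u[l], side="right"))
            zl = manual.z_links[l]
            i, j = four_cycle.links[l]
            manual.n[zl] -= 1
            manual.q[zl, i] -= 1
            manual.q[zl, j] -= 1
            manual.z_links[l] = znew
            manual.n[znew] += 1
            manual.q[znew, i] += 1
            manual.q[znew, j] += 1
        gibbs_sweep(state, four_cycle, h)
        assert np.array_equal(state.z_links, manual.z_links)

    def test_marginals_match_enumeration(self, four_cycle):
        """Empirical Gibbs assignment frequencies converge to the exact
        enumerated posterior marginals on a fully enumerable instance."""
        h = Hyperparameters(C=2, alpha=1.0, beta=0.5)
        links = [tuple(l) for l in four_cycle.links]
        _, exact = icm_enumerate(links, 4, 2, h.alpha, h.beta)
        state = init_assignments(four_cycle, h, seed=123)
        for _ in range(500):
            gibbs_sweep(state, four_cycle, h)
        counts = np.zeros((4, 2))
        kept = 20_000
        for _ in range(kept):
            gibbs_sweep(state, four_cycle, h)
            counts[np.arange(4), state.z_links] += 1
        tv = 0.5 * np.abs(counts / kept - exact).sum(axis=1)
        assert tv.max() < 0.02


class TestRunChain:
    def test_invalid_schedule_rejected(self, triangle):
        h = Hyperparameters(C=2)
        with pytest.raises(DataError):
            run_chain(triangle, h, burn_in=-1, n_samples=1, interval=1)
        with pytest.raises(DataError):
            run_chain(triangle, h, burn_in=0, n_samples=0, interval=1)
        with pytest.raises(DataError):
            run_chain(triangle, h, burn_in=0, n_samples=1, interval=0)

    def test_minimal_schedule_yields_one_sample(self, triangle):
        h = Hyperparameters(C=2)
        samples = run_chain(triangle, h, burn_in=0, n_samples=1, interval=1, seed=0)
        assert len(samples) == 1
        samples[0].check()

    def test_log_prob_finite_at_every_sample(self, two_triangles):
        h = Hyperparameters(C=2, alpha=1.0, beta=0.1)
        samples = run_chain(
            two_triangles, h, burn_in=50, n_samples=5, interval=5, seed=0
        )
        assert len(samples) == 5
        for s in samples:
            assert np.isfinite(joint_log_prob(s, two_triangles, h))

    def test_chain_improves_over_random_init(self, planted):
        """On the planted network the sampler must find higher-probability
        states than random assignment -- a failing run indicates broken
        bookkeeping."""
        network, _ = planted
        h = Hyperparameters(C=10)
        for seed in range(3):
            init_lp = joint_log_prob(
                init_assignments(network, h, seed), network, h
            )
            samples = run_chain(
                network, h, burn_in=500, n_samples=5, interval=10, seed=seed
            )
            mean_lp = np.mean([joint_log_prob(s, network, h) for s in samples])
            assert mean_lp > init_lp


class TestNodeMemberships:
    def test_single_component_rows_are_one(self, triangle):
        h = Hyperparameters(C=1)
        samples = run_chain(triangle, h, burn_in=0, n_samples=2, interval=1, seed=0)
        memb = node_memberships(samples, h)
        assert memb == pytest.approx(np.ones((3, 1)))

    def test_empty_sample_list_rejected(self):
        with pytest.raises(DataError, match="empty sample"):
            node_memberships([], Hyperparameters(C=2))

    def test_rows_sum_to_one(self, two_triangles):
        h = Hyperparameters(C=3, alpha=1.0, beta=0.1)
        samples = run_chain(
            two_triangles, h, burn_in=100, n_samples=5, interval=5, seed=2
        )
        memb = node_memberships(samples, h)
        assert memb.sum(axis=1) == pytest.approx(np.ones(6), abs=1e-9)
        assert (memb >= 0).all()

    def test_two_cliques_separate_cleanly(self, two_triangles):
        """A converged chain puts >0.9 membership of each node on its own
        clique's component."""
        h = Hyperparameters(C=2, alpha=1.0, beta=0.01)
        samples = run_chain_best(
            two_triangles, h, burn_in=500, n_samples=10, interval=10,
            seed=5, n_init=3,
        )
        memb = node_memberships(samples, h)
        first = crisp_clusters(memb)[:3]
        second = crisp_clusters(memb)[3:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]
        assert (memb.max(axis=1) > 0.9).all()


class TestCrispClusters:
    def test_argmax_assignment(self):
        assert crisp_clusters(np.array([[0.2, 0.7, 0.1]]))[0] == 1

    def test_tie_breaks_to_lowest_index(self):
        assert crisp_clusters(np.array([[0.5, 0.5]]))[0] == 0
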
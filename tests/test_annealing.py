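"""QUBO encoding, SA sampling, and epsilon-controlled enumeration."""

import itertools

import numpy as np
import pytest

import cliquemap as cm
from cliquemap.annealing import (
    PenaltyParameterError,
    SAParams,
    build_qubo,
    enumerate_max_cliques_sa,
    qubo_energy,
    sa_sample,
    stopping_threshold,
)
from cliquemap.clique import brute_force_max_cliques, enumerate_max_cliques

from conftest import complement_of_matching, random_adjacency


def exhaustive_ground_states(qubo):
    """Oracle: evaluate the energy of every assignment (N <= ~16)."""
    n = qubo.n
    best, states = np.inf, []
    for bits in itertools.product((0, 1), repeat=n):
        e = qubo.energy(np.array(bits))
        if e < best - 1e-12:
            best, states = e, []
        if abs(e - best) <= 1e-12:
            states.append(frozenset(i for i, b in enumerate(bits) if b))
    return best, set(states)


class TestQubo:
    def test_coefficients(self, enol):
        product = cm.build_modular_product(enol)
        qubo = build_qubo(product, A=2.0)
        assert np.all(qubo.linear == -1)
        off_diag = ~np.eye(qubo.n, dtype=bool)
        assert np.all(qubo.quadratic[product.adjacency] == 0)
        assert np.all(qubo.quadratic[off_diag & ~product.adjacency] == 2.0)
        assert np.all(qubo.quadratic.diagonal() == 0)

    def test_penalty_floor(self, enol):
        product = cm.build_modular_product(enol)
        with pytest.raises(PenaltyParameterError):
            build_qubo(product, A=1.0)

    def test_energy_examples(self, enol):
        product = cm.build_modular_product(enol)
        qubo = build_qubo(product, A=2.0)
        x = np.zeros(5)
        assert qubo_energy(qubo, x) == 0
        x[0] = 1
        assert qubo_energy(qubo, x) == -1
        # the maximum clique {v1, v4, v5} at zero penalty
        clique = np.zeros(5)
        clique[[0, 3, 4]] = 1
        assert qubo_energy(qubo, clique) == -3
        # a non-adjacent pair is never better than a single vertex
        pair = np.zeros(5)
        pair[[0, 1]] = 1
        assert qubo_energy(qubo, pair) == 0
        # all-ones: -5 + A * (number of non-adjacent pairs)
        n_nonedges = (~product.adjacency[np.triu_indices(5, 1)[0], np.triu_indices(5, 1)[1]]).sum()
        assert qubo_energy(qubo, np.ones(5)) == -5 + 2.0 * n_nonedges

    def test_length_mismatch(self, enol):
        qubo = build_qubo(cm.build_modular_product(enol))
        with pytest.raises(ValueError):
            qubo_energy(qubo, np.zeros(3))

    @pytest.mark.parametrize("seed", range(15))
    def test_ground_states_are_exactly_the_maximum_cliques(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        adj = random_adjacency(n, float(rng.uniform(0.2, 0.8)), seed + 3000)
        qubo = build_qubo(adj, A=2.0)
        best, states = exhaustive_ground_states(qubo)
        want = brute_force_max_cliques(adj)
        assert best == -want.max_size
        assert states == want.as_sets()


class TestSASample:
    def test_single_vertex(self):
        qubo = build_qubo(np.zeros((1, 1), dtype=bool))
        x, e = sa_sample(qubo, SAParams(seed=0))
        assert (list(x), e) == ([1], -1.0)

    def test_complete_graph_all_ones(self):
        adj = ~np.eye(4, dtype=bool)
        x, e = sa_sample(build_qubo(adj), SAParams(seed=1))
        assert list(x) == [1, 1, 1, 1] and e == -4.0

    def test_seeded_determinism(self, enol):
        qubo = build_qubo(cm.build_modular_product(enol))
        a = sa_sample(qubo, SAParams(seed=42))
        b = sa_sample(qubo, SAParams(seed=42))
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    def test_reaches_optimum_on_small_product(self, enol):
        qubo = build_qubo(cm.build_modular_product(enol))
        hits = sum(
            sa_sample(qubo, SAParams(seed=s))[1] == -3.0 for s in range(100)
        )
        assert hits >= 99


class TestStoppingRule:
    def test_threshold_formula(self):
        import math

        for m in (1, 2, 5, 128):
            r = stopping_threshold(m, 0.01)
            assert r == math.ceil(math.log(0.01 / (m + 1)) / math.log(m / (m + 1)))
        assert stopping_threshold(1, 0.01) == 8

    def test_threshold_grows_with_m_and_shrinks_with_epsilon(self):
        assert stopping_threshold(10, 0.01) > stopping_threshold(2, 0.01)
        assert stopping_threshold(5, 0.001) > stopping_threshold(5, 0.05)


class TestEnumeration:
    def test_enol_product_single_clique(self, enol):
        product = cm.build_modular_product(enol)
        run = enumerate_max_cliques_sa(product, epsilon=0.01, params=SAParams(seed=7))
        assert run.found.as_sets() == {frozenset({0, 3, 4})}
        assert run.stopped_by == "stopping-rule"
        assert run.epsilon == 0.01

    def test_empty_graph(self):
        run = enumerate_max_cliques_sa(np.zeros((0, 0), dtype=bool))
        assert run.found.m == 0 and run.total_samples == 0

    def test_epsilon_validated(self, enol):
        with pytest.raises(ValueError):
            enumerate_max_cliques_sa(cm.build_modular_product(enol), epsilon=1.5)

    def test_matching_complement_k6_matches_exact(self):
        adj = complement_of_matching(6)
        exact = enumerate_max_cliques(adj).as_sets()
        hits = sum(
            enumerate_max_cliques_sa(
                adj, params=SAParams(seed=s, reads_per_call=64)
            ).found.as_sets()
            == exact
            for s in range(20)
        )
        assert hits == 20

    def test_sample_cap_flags_unguaranteed_run(self):
        adj = complement_of_matching(5)
        run = enumerate_max_cliques_sa(adj, params=SAParams(seed=0), sample_cap=10)
        assert run.stopped_by == "sample-cap"
        assert run.total_samples == 10

    def test_seeded_determinism(self):
        adj = complement_of_matching(4)
        runs = [
            enumerate_max_cliques_sa(adj, params=SAParams(seed=5)) for _ in range(2)
        ]
        assert runs[0].found.as_sets() == runs[1].found.as_sets()
        assert runs[0].total_samples == runs[1].total_samples
        assert runs[0].samples_per_solution == runs[1].samples_per_solution

    def test_every_reported_clique_is_a_clique_at_best_energy(self):
        adj = random_adjacency(30, 0.5, 123)
        qubo = build_qubo(adj)
        run = enumerate_max_cliques_sa(adj, params=SAParams(seed=9))
        for clique in run.found.cliques:
            members = sorted(clique.vertex_ids)
            for i, u in enumerate(members):
                for v in members[i + 1 :]:
                    assert adj[u, v]
            x = np.zeros(30)
            x[members] = 1
            assert qubo.energy(x) == run.best_energy

    def test_uniformity_diagnostic_reported(self):
        run = enumerate_max_cliques_sa(
            complement_of_matching(4), params=SAParams(seed=3)
        )
        assert run.uniformity_pvalue is not None
        assert 0 <= run.uniformity_pvalue <= 1


class TestSamplingCostTrend:
    def test_total_samples_scale_near_m_log_m(self):
        """On graphs with m = 2^k maximum cliques the sampling cost should
        track O(m ln m): log-log regression slope within a factor-2 band."""
        ms, samples = [], []
        for k in range(2, 8):
            adj = complement_of_matching(k)
            run = enumerate_max_cliques_sa(
                adj, params=SAParams(seed=k, reads_per_call=64)
            )
            assert run.stopped_by == "stopping-rule"
            assert run.found.m == 2**k
            ms.append(2**k)
            samples.append(run.total_samples)
        x = np.log(np.array(ms) * np.log(ms))
        slope = np.polyfit(x, np.log(samples), 1)[0]
        assert 0.5 <= slope <= 2.0
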
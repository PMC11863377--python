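"""Molecular automorphisms and symmetry clustering of complete mappings."""

import itertools

import pytest

import cliquemap as cm
from cliquemap.clique import enumerate_max_cliques
from cliquemap.mapping import make_complete_mapping, mappings_from_cliques
from cliquemap.symmetry import automorphisms, cluster_mappings, equivalent


def brute_force_automorphisms(graph):
    """Oracle: try every permutation (n <= ~7)."""
    n = graph.n_atoms
    mult = graph.bond_multiplicity()
    out = []
    for perm in itertools.permutations(range(n)):
        if any(graph.elements[i] != graph.elements[perm[i]] for i in range(n)):
            continue
        if any(graph.implicit_h[i] != graph.implicit_h[perm[i]] for i in range(n)):
            continue
        ok = True
        for key, m in mult.items():
            i, j = tuple(key)
            if mult.get(frozenset((perm[i], perm[j]))) != m:
                ok = False
                break
        if ok:
            out.append(perm)
    return set(out)


class TestAutomorphisms:
    def test_benzene_ring_dihedral_symmetry(self):
        graph = cm.parse_reaction("c1ccccc1>>c1ccccc1").reactants
        group = automorphisms(graph)
        assert group.order == 12
        assert set(group.generators) == brute_force_automorphisms(graph)

    def test_enol_reactant_is_asymmetric(self, enol):
        assert automorphisms(enol.reactants).order == 1

    def test_single_atom(self):
        graph = cm.parse_reaction("C>>C").reactants
        assert automorphisms(graph).order == 1

    def test_symmetric_reactant_methyl_swap(self, symmetric_rxn):
        group = automorphisms(symmetric_rxn.reactants)
        assert group.order == 2
        assert (2, 1, 0, 3) in set(group.generators)

    @pytest.mark.parametrize(
        "smiles", ["CC(C)O", "CC=CO", "CC(C)(C)C", "OCCO", "C1CCC1"]
    )
    def test_matches_brute_force(self, smiles):
        graph = cm.parse_reaction(f"{smiles}>>{smiles}").reactants
        group = automorphisms(graph)
        want = brute_force_automorphisms(graph)
        assert set(group.generators) == want
        assert group.order == len(want)

    def test_multiplicity_and_h_blind_mode_is_coarser(self):
        # propene: chemically asymmetric, but the bare C-C-C chain (the
        # modular product's abstraction) has an end-to-end flip
        graph = cm.parse_reaction("C=CC>>C=CC").reactants
        assert automorphisms(graph).order == 1
        blind = automorphisms(graph, respect_h=False, respect_multiplicity=False)
        assert blind.order == 2

    def test_generators_closed_under_composition(self, symmetric_rxn):
        group = automorphisms(symmetric_rxn.reactants)
        perms = set(group.generators)
        for a in perms:
            for b in perms:
                assert tuple(a[b[i]] for i in range(len(a))) in perms


class TestClusterMappings:
    def test_symmetric_example_two_patterns(self, symmetric_rxn):
        product = cm.build_modular_product(symmetric_rxn)
        maps = mappings_from_cliques(enumerate_max_cliques(product).cliques, product)
        assert len(maps) == 4
        clusters = cluster_mappings(
            maps,
            automorphisms(symmetric_rxn.reactants),
            automorphisms(symmetric_rxn.products),
        )
        assert len(clusters) == 2
        assert sorted(c.size for c in clusters) == [2, 2]

    def test_asymmetric_reaction_every_mapping_its_own_cluster(self, enol):
        maps = [make_complete_mapping((0, 1, 2, 3), enol)]
        clusters = cluster_mappings(
            maps, automorphisms(enol.reactants), automorphisms(enol.products)
        )
        assert len(clusters) == 1 and clusters[0].size == 1

    def test_benzene_equivalent_positions_merge(self):
        # identity vs the ring rotation: related by a reactant automorphism
        rxn = cm.parse_reaction("c1ccccc1>>c1ccccc1")
        ident = make_complete_mapping(tuple(range(6)), rxn)
        rotated = make_complete_mapping((1, 2, 3, 4, 5, 0), rxn)
        clusters = cluster_mappings(
            [ident, rotated],
            automorphisms(rxn.reactants),
            automorphisms(rxn.products),
        )
        assert len(clusters) == 1

    def test_cluster_count_invariant_under_input_order(self, symmetric_rxn):
        product = cm.build_modular_product(symmetric_rxn)
        maps = mappings_from_cliques(enumerate_max_cliques(product).cliques, product)
        aut_r = automorphisms(symmetric_rxn.reactants)
        aut_p = automorphisms(symmetric_rxn.products)
        a = cluster_mappings(maps, aut_r, aut_p)
        b = cluster_mappings(list(reversed(maps)), aut_r, aut_p)
        assert [c.representative.atom_map for c in a] == [
            c.representative.atom_map for c in b
        ]

    def test_orbit_size_divides_group_order_product(self, symmetric_rxn):
        product = cm.build_modular_product(symmetric_rxn)
        maps = mappings_from_cliques(enumerate_max_cliques(product).cliques, product)
        aut_r = automorphisms(symmetric_rxn.reactants)
        aut_p = automorphisms(symmetric_rxn.products)
        for cluster in cluster_mappings(maps, aut_r, aut_p):
            assert (aut_r.order * aut_p.order) % cluster.size == 0

    def test_equivalence_relation_sanity(self, symmetric_rxn):
        product = cm.build_modular_product(symmetric_rxn)
        maps = mappings_from_cliques(enumerate_max_cliques(product).cliques, product)
        aut_r = automorphisms(symmetric_rxn.reactants)
        aut_p = automorphisms(symmetric_rxn.products)
        for m in maps:
            assert equivalent(m, m, aut_r, aut_p)
        for m1 in maps:
            for m2 in maps:
                assert equivalent(m1, m2, aut_r, aut_p) == equivalent(
                    m2, m1, aut_r, aut_p
                )
        # pairwise equivalence agrees with the cluster partition
        clusters = cluster_mappings(maps, aut_r, aut_p)
        label = {}
        for k, c in enumerate(clusters):
            for m in c.members:
                label[m.atom_map] = k
        for m1 in maps:
            for m2 in maps:
                assert equivalent(m1, m2, aut_r, aut_p) == (
                    label[m1.atom_map] == label[m2.atom_map]
                )

    def test_representative_is_lexicographic_minimum(self, symmetric_rxn):
        product = cm.build_modular_product(symmetric_rxn)
        maps = mappings_from_cliques(enumerate_max_cliques(product).cliques, product)
        for cluster in cluster_mappings(
            maps,
            automorphisms(symmetric_rxn.reactants),
            automorphisms(symmetric_rxn.products),
        ):
            assert cluster.representative.atom_map == min(
                m.atom_map for m in cluster.members
            )
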
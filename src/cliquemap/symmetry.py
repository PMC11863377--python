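"""Molecular-graph automorphisms and symmetry clustering of mappings.

Two complete mappings m1, m2 describe the same chemical transformation when
m2 = sigma_P ∘ m1 ∘ sigma_R for automorphisms sigma_R of the reactant graph
and sigma_P of the product graph: the atoms they treat differently are
chemically indistinguishable.  Clustering by this double-coset equivalence
and returning one representative per class yields the nonequivalent
mappings, i.e. the distinct reaction patterns.

Automorphisms are found by colour-refinement-seeded backtracking.  By
default they respect element labels, implicit-H counts, formal charge and
bond multiplicity (full chemical equivalence); a multiplicity/H-blind mode
matching the modular product's coarser abstraction is available via flags.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .mapping import CompleteMapping
from .reactions import MolecularGraph


@dataclass
class AutomorphismGroup:
    """A (full) list of automorphisms; each is a tuple perm with perm[i] = image."""

    generators: list[tuple[int, ...]]
    order: int

    def __iter__(self):
        return iter(self.generators)


def _initial_colors(graph: MolecularGraph, respect_h: bool, respect_multiplicity: bool):
    return [
        (
            graph.elements[i],
            graph.implicit_h[i] if respect_h else None,
            graph.formal_charge[i],
        )
        for i in range(graph.n_atoms)
    ]


def _refine(graph: MolecularGraph, colors, respect_multiplicity: bool):
    """1-WL colour refinement to a fixpoint; returns integer colours."""
    mult = graph.bond_multiplicity()
    adj = graph.neighbors()
    ids = {c: k for k, c in enumerate(sorted(set(colors), key=repr))}
    colors = [ids[c] for c in colors]
    while True:
        sigs = []
        for i in range(graph.n_atoms):
            nb = sorted(
                (colors[j], mult[frozenset((i, j))] if respect_multiplicity else 0)
                for j in adj[i]
            )
            sigs.append((colors[i], tuple(nb)))
        ids = {s: k for k, s in enumerate(sorted(set(sigs)))}
        new = [ids[s] for s in sigs]
        if new == colors:
            return colors
        colors = new


def automorphisms(
    graph: MolecularGraph,
    respect_h: bool = True,
    respect_multiplicity: bool = True,
) -> AutomorphismGroup:
    """Full automorphism group of a molecular graph (explicit enumeration).

    Adequate for reaction-benchmark-sized molecules: colour refinement
    shrinks the candidate sets sharply, and heavy-atom symmetry groups of
    typical organic molecules are small.
    """
    n = graph.n_atoms
    if n == 0:
        return AutomorphismGroup([()], 1)
    colors = _refine(graph, _initial_colors(graph, respect_h, respect_multiplicity),
                     respect_multiplicity)
    mult = graph.bond_multiplicity()
    adj = graph.neighbors()
    candidates = [
        [j for j in range(n) if colors[j] == colors[i]] for i in range(n)
    ]
    # assign most-constrained atoms first
    order = sorted(range(n), key=lambda i: len(candidates[i]))
    perms: list[tuple[int, ...]] = []

    def consistent(i: int, j: int, perm: dict[int, int]) -> bool:
        for k in adj[i]:
            if k in perm:
                jk = perm[k]
                key = frozenset((j, jk))
                if key not in mult:
                    return False
                if respect_multiplicity and mult[key] != mult[frozenset((i, k))]:
                    return False
        # non-edges must map to non-edges (degree equality via colours helps,
        # but check explicitly for mapped atoms)
        for k in perm:
            if k not in adj[i] and frozenset((j, perm[k])) in mult:
                return False
        return True

    def backtrack(pos: int, perm: dict[int, int], used: set[int]) -> None:
        if pos == n:
            perms.append(tuple(perm[i] for i in range(n)))
            return
        i = order[pos]
        for j in candidates[i]:
            if j in used or not consistent(i, j, perm):
                continue
            perm[i] = j
            used.add(j)
            backtrack(pos + 1, perm, used)
            del perm[i]
            used.discard(j)

    backtrack(0, {}, set())
    return AutomorphismGroup(perms, len(perms))


@dataclass
class MappingCluster:
    members: list[CompleteMapping]  # sorted by atom_map
    representative: CompleteMapping  # lexicographically smallest member

    @property
    def size(self) -> int:
        return len(self.members)


def cluster_mappings(
    mappings,
    aut_r: AutomorphismGroup,
    aut_p: AutomorphismGroup,
) -> list[MappingCluster]:
    """Partition complete mappings into equivalence classes under
    m ~ sigma_P ∘ m ∘ sigma_R, sorted by (bond changes, representative)."""
    by_map = {m.atom_map: m for m in mappings}
    unassigned = dict(by_map)
    clusters = []
    while unassigned:
        seed_key = min(unassigned)
        seed = unassigned.pop(seed_key)
        members = {seed_key: seed}
        for sr, sp in itertools.product(aut_r.generators, aut_p.generators):
            image = tuple(sp[seed.atom_map[sr[i]]] for i in range(len(seed_key)))
            if image in unassigned:
                members[image] = unassigned.pop(image)
        keys = sorted(members)
        clusters.append(
            MappingCluster(
                members=[members[k] for k in keys], representative=members[keys[0]]
            )
        )
    clusters.sort(key=lambda c: (c.representative.bond_changes, c.representative.atom_map))
    return clusters


def equivalent(
    m1, m2, aut_r: AutomorphismGroup, aut_p: AutomorphismGroup
) -> bool:
    """Whether two total mappings are related by molecular symmetry."""
    a1 = m1.atom_map if hasattr(m1, "atom_map") else tuple(m1)
    a2 = m2.atom_map if hasattr(m2, "atom_map") else tuple(m2)
    n = len(a1)
    for sr in aut_r.generators:
        for sp in aut_p.generators:
            if all(sp[a1[sr[i]]] == a2[i] for i in range(n)):
                return True
    return False
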
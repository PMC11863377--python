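"""From maximum cliques to complete atom-to-atom mappings.

A clique of the modular product is a one-to-one correspondence between
reactant and product bonds.  Matching the endpoints of each corresponded
bond pair induces a partial atom mapping; atoms left out of the clique
("residual" atoms) are then assigned by every per-element bijection between
the residual reactant and product atoms, yielding the complete mappings.

For a homonuclear bond pair (e.g. C-C ↔ C-C) the endpoint matching can be
oriented two ways; all orientations consistent with the rest of the clique
are emitted and exact duplicates are merged downstream, so no minimum-change
mapping is ever lost.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .clique import Clique
from .product_graph import ModularProduct
from .reactions import ReactionInstance


class InconsistentCliqueError(Exception):
    """The clique admits no atom-level bijection (split/merge pathology)."""


class CompletionCapError(Exception):
    """The number of residual-permutation completions exceeds the cap."""

    def __init__(self, count: int, cap: int):
        super().__init__(
            f"{count} completions exceed cap {cap}; raise the cap or reduce symmetry"
        )
        self.count = count
        self.cap = cap


@dataclass(frozen=True)
class PartialMapping:
    """Injective partial atom map induced by one clique orientation."""

    atom_pairs: tuple[tuple[int, int], ...]  # (reactant atom, product atom), sorted
    preserved_bonds: tuple[tuple[int, int], ...]  # (reactant bond idx, product bond idx)

    @property
    def unchanged_bond_count(self) -> int:
        return len(self.preserved_bonds)

    def as_dict(self) -> dict[int, int]:
        return dict(self.atom_pairs)


@dataclass(frozen=True)
class CompleteMapping:
    """Total heavy-atom bijection with its bond-change and filter scores."""

    atom_map: tuple[int, ...]  # atom_map[i] = product atom for reactant atom i
    cleavages: int
    formations: int
    h_move_score: int
    multiplicity_change_score: float

    @property
    def bond_changes(self) -> int:
        return self.cleavages + self.formations


def bond_change_counts(atom_map, reaction: ReactionInstance) -> tuple[int, int]:
    """(cleavages, formations) of a total mapping, multiplicity-blind.

    A reactant bond (i, j) is preserved iff (map(i), map(j)) is a product
    bond of any multiplicity.
    """
    if isinstance(atom_map, dict):
        atom_map = tuple(atom_map[i] for i in range(len(atom_map)))
    p_bonds = reaction.products.bond_set()
    preserved = sum(
        1
        for i, j, _ in reaction.reactants.bonds
        if frozenset((atom_map[i], atom_map[j])) in p_bonds
    )
    return (reaction.reactants.n_bonds - preserved, reaction.products.n_bonds - preserved)


def make_complete_mapping(atom_map, reaction: ReactionInstance) -> CompleteMapping:
    """Attach all derived scores to a total bijection."""
    from .filters import hydrogen_move_score, multiplicity_change_score

    if isinstance(atom_map, dict):
        atom_map = tuple(atom_map[i] for i in range(len(atom_map)))
    atom_map = tuple(atom_map)
    n_r, n_p = reaction.reactants.n_atoms, reaction.products.n_atoms
    if len(atom_map) != n_r or sorted(atom_map) != list(range(n_p)):
        raise ValueError("atom_map must be a total bijection")
    for i, j in enumerate(atom_map):
        if reaction.reactants.elements[i] != reaction.products.elements[j]:
            raise ValueError(f"mapping sends {reaction.reactants.elements[i]} to "
                             f"{reaction.products.elements[j]}")
    cleav, form = bond_change_counts(atom_map, reaction)
    return CompleteMapping(
        atom_map=atom_map,
        cleavages=cleav,
        formations=form,
        h_move_score=hydrogen_move_score(atom_map, reaction),
        multiplicity_change_score=multiplicity_change_score(atom_map, reaction),
    )


def clique_to_partial_mappings(
    clique: Clique, product: ModularProduct
) -> list[PartialMapping]:
    """All atom-level partial mappings induced by a clique's bond pairs.

    Backtracks over the two orientations of each bond pair, keeping the map
    injective and element-preserving.  Raises InconsistentCliqueError if no
    orientation assignment works (the clique demands an atom split/merge,
    which compatibility condition (2) does not fully exclude, e.g. when a
    triangle is matched against a 3-star).
    """
    reaction = product.reaction
    r_el = reaction.reactants.elements
    p_el = reaction.products.elements
    pairs = []
    for vid in sorted(clique.vertex_ids):
        rb, pb = product.vertex_bonds(vid)
        v = product.vertices[vid]
        pairs.append(((rb[0], rb[1]), (pb[0], pb[1]), (v.reactant_bond, v.product_bond)))

    results: dict[tuple, PartialMapping] = {}

    def backtrack(k: int, fwd: dict[int, int], bwd: dict[int, int]) -> None:
        if k == len(pairs):
            key = tuple(sorted(fwd.items()))
            results[key] = PartialMapping(
                atom_pairs=key, preserved_bonds=tuple(p[2] for p in pairs)
            )
            return
        (ra, rb_), (pa, pb_), _ = pairs[k]
        for pu, pv in ((pa, pb_), (pb_, pa)):
            if r_el[ra] != p_el[pu] or r_el[rb_] != p_el[pv]:
                continue
            added = []
            ok = True
            for r_atom, p_atom in ((ra, pu), (rb_, pv)):
                if fwd.get(r_atom, p_atom) != p_atom or bwd.get(p_atom, r_atom) != r_atom:
                    ok = False
                    break
                if r_atom not in fwd:
                    fwd[r_atom] = p_atom
                    bwd[p_atom] = r_atom
                    added.append((r_atom, p_atom))
            if ok:
                backtrack(k + 1, fwd, bwd)
            for r_atom, p_atom in added:
                del fwd[r_atom]
                del bwd[p_atom]

    backtrack(0, {}, {})
    if not results:
        raise InconsistentCliqueError(
            f"clique {sorted(clique.vertex_ids)} admits no consistent atom mapping"
        )
    return [results[k] for k in sorted(results)]


def count_completions(partial: PartialMapping, reaction: ReactionInstance) -> int:
    """Number of residual per-element bijections completing a partial mapping."""
    mapped_r = {i for i, _ in partial.atom_pairs}
    residual_r = [i for i in range(reaction.reactants.n_atoms) if i not in mapped_r]
    counts: dict[str, int] = {}
    for i in residual_r:
        el = reaction.reactants.elements[i]
        counts[el] = counts.get(el, 0) + 1
    return math.prod(math.factorial(c) for c in counts.values())


def complete_mappings(
    partial: PartialMapping, reaction: ReactionInstance, cap: int = 100_000
) -> list[CompleteMapping]:
    """Every completion of a partial mapping by residual per-element bijections."""
    mapped_r = {i for i, _ in partial.atom_pairs}
    mapped_p = {j for _, j in partial.atom_pairs}
    residual_r: dict[str, list[int]] = {}
    residual_p: dict[str, list[int]] = {}
    for i in range(reaction.reactants.n_atoms):
        if i not in mapped_r:
            residual_r.setdefault(reaction.reactants.elements[i], []).append(i)
    for j in range(reaction.products.n_atoms):
        if j not in mapped_p:
            residual_p.setdefault(reaction.products.elements[j], []).append(j)
    if {el: len(v) for el, v in residual_r.items()} != {
        el: len(v) for el, v in residual_p.items()
    }:
        raise ValueError("residual element counts differ: reaction is unbalanced")

    n_comp = math.prod(math.factorial(len(v)) for v in residual_r.values())
    if n_comp > cap:
        raise CompletionCapError(n_comp, cap)

    elements = sorted(residual_r)
    per_element = [
        list(itertools.permutations(residual_p[el])) for el in elements
    ]
    base = partial.as_dict()
    out = []
    for combo in itertools.product(*per_element):
        atom_map = dict(base)
        for el, perm in zip(elements, combo):
            for i, j in zip(residual_r[el], perm):
                atom_map[i] = j
        out.append(make_complete_mapping(atom_map, reaction))
    return out


def mappings_from_cliques(
    cliques,
    product: ModularProduct,
    cap: int = 100_000,
    skip_inconsistent: bool = False,
) -> list[CompleteMapping]:
    """All distinct complete mappings derived from a set of maximum cliques.

    An empty clique set (no bonds preserved, e.g. a bond-less side) falls
    back to the empty partial mapping, i.e. pure residual permutation.
    With ``skip_inconsistent`` the unrealisable cliques are dropped instead
    of raising; callers must handle the everything-dropped case (see
    ``realizable_mappings``).
    """
    reaction = product.reaction
    clique_list = list(cliques) or [Clique(frozenset())]
    seen: dict[tuple[int, ...], CompleteMapping] = {}
    for clique in clique_list:
        try:
            partials = clique_to_partial_mappings(clique, product)
        except InconsistentCliqueError:
            if skip_inconsistent:
                continue
            raise
        for partial in partials:
            for cm in complete_mappings(partial, reaction, cap=cap):
                seen.setdefault(cm.atom_map, cm)
    return [seen[k] for k in sorted(seen)]


def realizable_mappings(
    cliques, max_size: int, product: ModularProduct, cap: int = 100_000
) -> tuple[list[CompleteMapping], int]:
    """Complete mappings from the largest *realisable* bond correspondence.

    Usually that is the maximum-clique set itself.  When every maximum
    clique is atom-inconsistent (triangle-vs-star pathology), the clique
    size is lowered one step at a time — enumerating ALL cliques of that
    size, non-maximal included — until consistent correspondences appear;
    every completion then still attains the global minimum of bond changes
    over all element-preserving bijections.

    Returns (mappings, realized_clique_size).
    """
    from .clique import enumerate_cliques_of_size

    out = mappings_from_cliques(cliques, product, cap=cap, skip_inconsistent=True)
    k = max_size
    while not out and k > 0:
        k -= 1
        lower = enumerate_cliques_of_size(product, k) if k > 0 else []
        out = mappings_from_cliques(lower, product, cap=cap, skip_inconsistent=True)
    return out, k


def brute_force_min_bond_changes(reaction: ReactionInstance) -> int:
    """Oracle: minimum cleavages+formations over ALL element-preserving
    bijections (exhaustive; intended for small reactions, n <= ~8)."""
    by_el_r: dict[str, list[int]] = {}
    by_el_p: dict[str, list[int]] = {}
    for i, el in enumerate(reaction.reactants.elements):
        by_el_r.setdefault(el, []).append(i)
    for j, el in enumerate(reaction.products.elements):
        by_el_p.setdefault(el, []).append(j)
    if {e: len(v) for e, v in by_el_r.items()} != {e: len(v) for e, v in by_el_p.items()}:
        raise ValueError("unbalanced heavy-atom element counts")
    elements = sorted(by_el_r)
    best = math.inf
    for combo in itertools.product(
        *(itertools.permutations(by_el_p[el]) for el in elements)
    ):
        atom_map = [0] * reaction.reactants.n_atoms
        for el, perm in zip(elements, combo):
            for i, j in zip(by_el_r[el], perm):
                atom_map[i] = j
        c, f = bond_change_counts(tuple(atom_map), reaction)
        best = min(best, c + f)
    return int(best)
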
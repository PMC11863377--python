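"""Modular product of the reactant and product molecular graphs.

Each vertex of the modular product pairs one reactant bond with one product
bond of the same type, where a bond's type is the unordered pair of element
symbols of its endpoints — bond multiplicity is deliberately ignored so that
order shifts (e.g. in pericyclic reactions) do not break the correspondence.
Two vertices are adjacent iff the bond pairs they represent are compatible:

  (1) they do not reuse a reactant bond or a product bond, and
  (2) the reactant bonds share an atom exactly when the product bonds do.

Maximum cliques of this graph are the maximum common edge subgraphs of the
two sides, i.e. the largest sets of bonds that can be preserved through the
reaction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .reactions import MolecularGraph, ReactionInstance


@dataclass(frozen=True)
class BondPairVertex:
    """A candidate correspondence between one reactant and one product bond."""

    vertex_id: int
    reactant_bond: int  # index into reaction.reactants.bonds
    product_bond: int  # index into reaction.products.bonds


@dataclass
class ModularProduct:
    vertices: list[BondPairVertex]
    adjacency: np.ndarray  # symmetric boolean N x N, False diagonal
    reaction: ReactionInstance

    @property
    def N(self) -> int:
        return len(self.vertices)

    def vertex_bonds(self, vid: int) -> tuple[tuple[int, int, float], tuple[int, int, float]]:
        v = self.vertices[vid]
        return (
            self.reaction.reactants.bonds[v.reactant_bond],
            self.reaction.products.bonds[v.product_bond],
        )


def bond_type(bond: tuple[int, int, float], graph: MolecularGraph) -> frozenset[str] | tuple:
    """Unordered element pair of a bond's endpoints; multiplicity is ignored.

    Returned as a sorted tuple so that homonuclear bonds (e.g. C-C) compare
    equal regardless of orientation.
    """
    i, j, _ = bond
    return tuple(sorted((graph.elements[i], graph.elements[j])))


def compatible(u: BondPairVertex, v: BondPairVertex, reaction: ReactionInstance) -> bool:
    """Whether two bond-pair vertices may belong to one bond correspondence."""
    if u.reactant_bond == v.reactant_bond or u.product_bond == v.product_bond:
        return False  # not one-to-one between bonds
    ri, rj, _ = reaction.reactants.bonds[u.reactant_bond]
    si, sj, _ = reaction.reactants.bonds[v.reactant_bond]
    pi, pj, _ = reaction.products.bonds[u.product_bond]
    qi, qj, _ = reaction.products.bonds[v.product_bond]
    share_r = len({ri, rj} & {si, sj}) > 0
    share_p = len({pi, pj} & {qi, qj}) > 0
    # sharing on exactly one side would split or merge the shared atom
    return share_r == share_p


def build_modular_product(reaction: ReactionInstance) -> ModularProduct:
    """All same-type cross bond pairs, with the compatibility adjacency.

    Vertex order is deterministic: reactant bond index, then product bond
    index (bonds themselves are stored sorted by endpoint ids).
    """
    r_bonds = reaction.reactants.bonds
    p_bonds = reaction.products.bonds
    r_types = [bond_type(b, reaction.reactants) for b in r_bonds]
    p_types = [bond_type(b, reaction.products) for b in p_bonds]

    vertices = []
    for rb, rt in enumerate(r_types):
        for pb, pt in enumerate(p_types):
            if rt == pt:
                vertices.append(BondPairVertex(len(vertices), rb, pb))

    n = len(vertices)
    if n == 0:
        return ModularProduct(vertices, np.zeros((0, 0), dtype=bool), reaction)

    rb_idx = np.array([v.reactant_bond for v in vertices])
    pb_idx = np.array([v.product_bond for v in vertices])
    r_ends = np.array([(b[0], b[1]) for b in r_bonds])
    p_ends = np.array([(b[0], b[1]) for b in p_bonds])

    ru, rv = r_ends[rb_idx, 0], r_ends[rb_idx, 1]
    pu, pv = p_ends[pb_idx, 0], p_ends[pb_idx, 1]

    def shares(a0, a1):
        return (
            (a0[:, None] == a0[None, :])
            | (a0[:, None] == a1[None, :])
            | (a1[:, None] == a0[None, :])
            | (a1[:, None] == a1[None, :])
        )

    share_r = shares(ru, rv)
    share_p = shares(pu, pv)
    distinct = (rb_idx[:, None] != rb_idx[None, :]) & (pb_idx[:, None] != pb_idx[None, :])
    adjacency = distinct & (share_r == share_p)
    np.fill_diagonal(adjacency, False)
    return ModularProduct(vertices, adjacency, reaction)


def dump_product(product: ModularProduct, prefix: str | Path) -> None:
    """Debug dump: edge list ('u v' per line) plus a vertex legend CSV."""
    prefix = Path(prefix)
    lines = []
    for u in range(product.N):
        for v in range(u + 1, product.N):
            if product.adjacency[u, v]:
                lines.append(f"{u} {v}")
    prefix.with_suffix(".edges.txt").write_text("\n".join(lines) + "\n")
    with open(prefix.with_suffix(".vertices.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vertex_id", "reactant_bond", "product_bond", "bond_type"])
        for v in product.vertices:
            rb = product.reaction.reactants.bonds[v.reactant_bond]
            w.writerow(
                [
                    v.vertex_id,
                    v.reactant_bond,
                    v.product_bond,
                    "-".join(bond_type(rb, product.reaction.reactants)),
                ]
            )
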
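"""Synthetic balanced reactions with known ground-truth mappings.

The generator grows a random connected, valence-respecting molecular graph,
copies it, and applies a chosen number of bond *migrations*: each edit
removes one bond and forms one new valence-legal bond, so bond count — and
hence, under the valence-filling hydrogen model, total hydrogen count — is
conserved and the reaction stays balanced by construction.  The identity
permutation is the ground-truth mapping, reaching the edited structure with
at most 2 bond changes per edit (a symmetric molecule may admit an even
cheaper mapping).

Reactions are serialized to atom-mapped SMILES and re-parsed, so every
generated fixture exercises the real I/O path and carries its ground truth
as ``reference_mapping``.

``worked_examples`` packages two tiny desk-checkable reactions: the enol →
aldehyde tautomerisation used throughout the docs, and a symmetric
isopropanol-skeleton rearrangement whose mapping census (6 bijections, 4
MCES-optimal, 2 nonequivalent) exercises the symmetry clustering.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from rdkit import Chem

from .mapping import CompleteMapping, make_complete_mapping
from .reactions import ReactionInstance, parse_reaction

VALENCE = {"C": 4, "N": 3, "O": 2}
DEFAULT_PALETTE = ("C", "C", "C", "N", "O")


class EditRetryError(Exception):
    """No valence-legal bond migration could be found."""


@dataclass
class SyntheticReaction:
    reaction: ReactionInstance
    true_mapping: CompleteMapping
    edits: list[tuple[str, tuple[int, int]]]  # ("break"|"form", (atom, atom))
    seed: int
    smiles: str


def _valence(el: str) -> int:
    return VALENCE.get(el, 1)


def _to_smiles(elements, bonds, map_offset=True) -> str:
    rw = Chem.RWMol()
    for k, el in enumerate(elements):
        atom = Chem.Atom(el)
        atom.SetAtomMapNum(k + 1)
        rw.AddAtom(atom)
    for i, j in bonds:
        rw.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def generate_reaction(
    n_atoms: int,
    n_edits: int,
    element_palette=DEFAULT_PALETTE,
    seed: int = 0,
    max_tries: int = 200,
    ensure_optimal: bool | None = None,
) -> SyntheticReaction:
    """One random balanced reaction with ``n_edits`` bond migrations.

    ``ensure_optimal`` rejects edit sequences whose planted identity mapping
    does not attain the minimum bond-change count over all element-preserving
    bijections (a random migration can be undone more cheaply by a symmetric
    relabelling, in which case the plant is not a usable ground truth).  The
    check is exhaustive, so it defaults to on only for n_atoms <= 10.
    """
    if n_atoms < 2:
        raise ValueError("need at least 2 heavy atoms")
    if n_edits < 1:
        raise ValueError("need at least 1 edit")
    if ensure_optimal is None:
        ensure_optimal = n_atoms <= 10
    rng = random.Random(seed)

    for _attempt in range(max_tries):
        # random connected tree respecting valences, plus occasional ring bond
        elements = [rng.choice(element_palette) for _ in range(n_atoms)]
        # a tree needs internal nodes: force atom 0 to be carbon
        elements[0] = "C"
        degree = [0] * n_atoms
        bonds: set[tuple[int, int]] = set()
        ok = True
        for k in range(1, n_atoms):
            hosts = [i for i in range(k) if degree[i] < _valence(elements[i])]
            if not hosts:
                ok = False
                break
            host = rng.choice(hosts)
            bonds.add((host, k))
            degree[host] += 1
            degree[k] += 1
        if not ok:
            continue
        if n_atoms >= 4 and rng.random() < 0.3:
            free = [i for i in range(n_atoms) if degree[i] < _valence(elements[i])]
            rng.shuffle(free)
            for i in free:
                for j in free:
                    if i < j and (i, j) not in bonds:
                        bonds.add((i, j))
                        degree[i] += 1
                        degree[j] += 1
                        break
                else:
                    continue
                break

        # bond migrations on a copy
        p_bonds = set(bonds)
        p_degree = list(degree)
        edits: list[tuple[str, tuple[int, int]]] = []
        feasible = True
        for _ in range(n_edits):
            moved = False
            for _try in range(50):
                old = rng.choice(sorted(p_bonds))
                cand_new = [
                    (i, j)
                    for i in range(n_atoms)
                    for j in range(i + 1, n_atoms)
                    if (i, j) not in p_bonds or (i, j) == old
                ]
                cand_new = [
                    (i, j)
                    for (i, j) in cand_new
                    if (i, j) != old
                    and p_degree[i] - (i in old) < _valence(elements[i])
                    and p_degree[j] - (j in old) < _valence(elements[j])
                ]
                if not cand_new:
                    continue
                new = rng.choice(cand_new)
                p_bonds.remove(old)
                p_degree[old[0]] -= 1
                p_degree[old[1]] -= 1
                p_bonds.add(new)
                p_degree[new[0]] += 1
                p_degree[new[1]] += 1
                edits.append(("break", old))
                edits.append(("form", new))
                moved = True
                break
            if not moved:
                feasible = False
                break
        if not feasible or p_bonds == bonds:
            continue

        r_smi = _to_smiles(elements, sorted(bonds))
        p_smi = _to_smiles(elements, sorted(p_bonds))
        smiles = f"{r_smi}>>{p_smi}"
        reaction = parse_reaction(smiles, source_id=f"synthetic-{seed}")
        assert reaction.reference_mapping is not None
        true_mapping = make_complete_mapping(reaction.reference_mapping, reaction)
        if ensure_optimal:
            from .mapping import brute_force_min_bond_changes

            if true_mapping.bond_changes > brute_force_min_bond_changes(reaction):
                continue
        return SyntheticReaction(reaction, true_mapping, edits, seed, smiles)

    raise EditRetryError(
        f"no valence-legal reaction found for n_atoms={n_atoms}, n_edits={n_edits}"
    )


#: Desk-checkable packaged examples with their expected pipeline census.
WORKED_EXAMPLES: dict[str, dict] = {
    # enol -> aldehyde tautomerisation: unique MCES, no residual atoms
    "enol_to_aldehyde": {
        "smiles": "CC=CO>>CCC=O",
        "modular_product_N": 5,
        "max_clique_size": 3,
        "num_max_cliques": 1,
        "nonequivalent_mappings": 1,
        "h_move_score": 2,
        "multiplicity_change_score": 2.0,
    },
    # symmetric branched -> linear C3O skeleton: two equivalent methyls in
    # the reactant generate equivalent mappings
    "symmetric_rearrangement": {
        "smiles": "CC(C)O>>CCCO",
        "total_mappings": 6,
        "mces_mappings": 4,
        "mces_bond_changes": 2,  # 1 cleavage + 1 formation
        "nonequivalent_mappings": 2,
    },
}


def worked_examples() -> dict[str, ReactionInstance]:
    """Parse and return the packaged example reactions by name."""
    return {
        name: parse_reaction(info["smiles"], source_id=name)
        for name, info in WORKED_EXAMPLES.items()
    }
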
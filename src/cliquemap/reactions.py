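"""Reaction SMILES I/O: hydrogen-suppressed molecular graphs and balance checks.

A reaction is modelled as two element-labelled multigraph-free graphs (one
bond per atom pair, bond order stored as a multiplicity in {1, 1.5, 2, 3}).
Explicit hydrogens are folded into per-atom implicit-H counts; bonds to
hydrogen are never represented as graph edges.  Atom-map numbers present in
the input are captured as a reference mapping for benchmarking and stripped
from the working graphs.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # rdkit is chatty on benchmark-style SMILES


class ReactionError(Exception):
    """Base class for reaction I/O failures."""


class ReactionParseError(ReactionError):
    """The SMILES string could not be parsed."""


class UnsupportedReactionError(ReactionError):
    """Chemically valid input outside the supported model (e.g. H-only species)."""


@dataclass(frozen=True)
class MolecularGraph:
    """Hydrogen-suppressed molecular graph of one side of a reaction.

    Atom ids are contiguous from 0.  ``bonds`` holds one entry per unordered
    atom pair as ``(i, j, multiplicity)`` with ``i < j``.  Multi-molecule
    sides are merged into a single disconnected graph; ``component_ids``
    records which molecule each atom came from.
    """

    elements: tuple[str, ...]
    implicit_h: tuple[int, ...]
    formal_charge: tuple[int, ...]
    bonds: tuple[tuple[int, int, float], ...]
    component_ids: tuple[int, ...]

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def bond_multiplicity(self) -> dict[frozenset[int], float]:
        return {frozenset((i, j)): m for i, j, m in self.bonds}

    def bond_set(self) -> frozenset[frozenset[int]]:
        return frozenset(frozenset((i, j)) for i, j, _ in self.bonds)

    def neighbors(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for i, j, _ in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def element_counts(self, include_h: bool = True) -> Counter:
        counts = Counter(self.elements)
        if include_h:
            counts["H"] += sum(self.implicit_h)
            counts += Counter()  # drop zero entries
        return counts

    def __post_init__(self) -> None:
        n = len(self.elements)
        if not (len(self.implicit_h) == len(self.formal_charge) == len(self.component_ids) == n):
            raise ValueError("per-atom field lengths disagree")
        seen: set[frozenset[int]] = set()
        for i, j, m in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references unknown atom")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(f"duplicate bond between atoms {i} and {j}")
            seen.add(key)
            if m not in (1.0, 1.5, 2.0, 3.0):
                raise ValueError(f"unsupported bond multiplicity {m}")


@dataclass
class ReactionInstance:
    """A parsed, balanced-or-not reaction with optional reference mapping."""

    reactants: MolecularGraph
    products: MolecularGraph
    reference_mapping: Optional[dict[int, int]] = None
    source_id: str = ""
    # RDKit side mols (H-suppressed, map numbers cleared); kept for SMILES output.
    rd_reactants: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)
    rd_products: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)


def _mol_to_graph(mol: Chem.Mol) -> MolecularGraph:
    frag_ids = [0] * mol.GetNumAtoms()
    for ci, frag in enumerate(Chem.GetMolFrags(mol)):
        for a in frag:
            frag_ids[a] = ci
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    implicit_h = tuple(a.GetTotalNumHs() for a in mol.GetAtoms())
    charge = tuple(a.GetFormalCharge() for a in mol.GetAtoms())
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        bonds.append((i, j, b.GetBondTypeAsDouble()))
    bonds.sort()
    return MolecularGraph(elements, implicit_h, charge, tuple(bonds), tuple(frag_ids))


def _parse_side(smiles: str) -> tuple[Chem.Mol, list[int]]:
    """Parse one reaction side; returns (heavy-atom mol, per-atom map numbers)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ReactionParseError(f"cannot parse SMILES fragment {smiles!r}")
    for frag in Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False):
        if all(a.GetAtomicNum() == 1 for a in frag.GetAtoms()):
            raise UnsupportedReactionError(
                f"species consisting only of hydrogen atoms in {smiles!r} is unsupported"
            )
    mol = Chem.RemoveHs(mol)
    map_nums = [a.GetAtomMapNum() for a in mol.GetAtoms()]
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    return mol, map_nums


def parse_reaction(smiles: str, source_id: str = "") -> ReactionInstance:
    """Parse a reaction SMILES ``reactants>>products`` into a ReactionInstance.

    Agents between the two ``>`` separators are discarded with a warning.
    Atom-map numbers, when they fully annotate both sides, are captured as
    ``reference_mapping`` (reactant atom id -> product atom id) and stripped
    from the working graphs.
    """
    parts = smiles.strip().split(">")
    if len(parts) == 2:
        r_smi, p_smi = parts
    elif len(parts) == 3:
        r_smi, agents, p_smi = parts
        if agents:
            logger.warning("discarding agents %r in %r", agents, smiles)
    else:
        raise ReactionParseError(
            f"expected 'reactants>>products' with a single '>>': {smiles!r}"
        )
    if not r_smi or not p_smi:
        raise ReactionParseError(f"empty reaction side in {smiles!r}")

    r_mol, r_maps = _parse_side(r_smi)
    p_mol, p_maps = _parse_side(p_smi)
    r_graph = _mol_to_graph(r_mol)
    p_graph = _mol_to_graph(p_mol)

    reference = None
    if (
        r_graph.n_atoms == p_graph.n_atoms
        and all(m > 0 for m in r_maps)
        and all(m > 0 for m in p_maps)
        and len(set(r_maps)) == len(r_maps)
        and set(r_maps) == set(p_maps)
    ):
        p_by_num = {num: j for j, num in enumerate(p_maps)}
        reference = {i: p_by_num[num] for i, num in enumerate(r_maps)}

    return ReactionInstance(
        reactants=r_graph,
        products=p_graph,
        reference_mapping=reference,
        source_id=source_id,
        rd_reactants=r_mol,
        rd_products=p_mol,
    )


def check_balance(reaction: ReactionInstance) -> tuple[dict[str, tuple[int, int]], bool]:
    """Per-element atom counts (implicit H included) on each side, plus balance flag."""
    r_counts = reaction.reactants.element_counts()
    p_counts = reaction.products.element_counts()
    table = {
        el: (r_counts.get(el, 0), p_counts.get(el, 0))
        for el in sorted(set(r_counts) | set(p_counts))
    }
    return table, all(r == p for r, p in table.values())


def graph_to_rdkit(graph: MolecularGraph) -> Chem.Mol:
    """Rebuild an RDKit mol from a molecular graph (fixes H counts explicitly)."""
    rw = Chem.RWMol()
    for k in range(graph.n_atoms):
        atom = Chem.Atom(graph.elements[k])
        atom.SetFormalCharge(graph.formal_charge[k])
        atom.SetNumExplicitHs(graph.implicit_h[k])
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    order = {
        1.0: Chem.BondType.SINGLE,
        1.5: Chem.BondType.AROMATIC,
        2.0: Chem.BondType.DOUBLE,
        3.0: Chem.BondType.TRIPLE,
    }
    for i, j, m in graph.bonds:
        rw.AddBond(i, j, order[m])
        if m == 1.5:
            rw.GetAtomWithIdx(i).SetIsAromatic(True)
            rw.GetAtomWithIdx(j).SetIsAromatic(True)
            rw.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def write_mapped_smiles(reaction: ReactionInstance, mapping) -> str:
    """Serialize a reaction with atom-map numbers carrying a complete mapping.

    Reactant atom ``i`` gets map number ``i + 1`` and product atom
    ``mapping[i]`` the same number, so parsing the output recovers the
    mapping as ``reference_mapping``.
    """
    atom_map = getattr(mapping, "atom_map", mapping)
    n = reaction.reactants.n_atoms
    if isinstance(atom_map, dict):
        atom_map = tuple(atom_map[i] for i in range(len(atom_map)))
    if len(atom_map) != n or sorted(atom_map) != list(range(reaction.products.n_atoms)):
        raise ValueError("mapping must be a total bijection over heavy atoms")

    r_mol = reaction.rd_reactants or graph_to_rdkit(reaction.reactants)
    p_mol = reaction.rd_products or graph_to_rdkit(reaction.products)
    r_mol = Chem.Mol(r_mol)
    p_mol = Chem.Mol(p_mol)
    for i, atom in enumerate(r_mol.GetAtoms()):
        atom.SetAtomMapNum(i + 1)
    inverse = {atom_map[i]: i for i in range(n)}
    for j, atom in enumerate(p_mol.GetAtoms()):
        atom.SetAtomMapNum(inverse[j] + 1)
    return f"{Chem.MolToSmiles(r_mol)}>>{Chem.MolToSmiles(p_mol)}"


@dataclass
class DatasetLoadResult:
    instances: list[ReactionInstance]
    errors: list[dict]

    def write_error_report(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.errors, indent=2))


def load_dataset(path: str | Path) -> DatasetLoadResult:
    """Load a reaction dataset (CSV with header, or one reaction SMILES per line).

    CSV columns: ``reaction_smiles`` (required), ``id`` and ``reference_smiles``
    (optional).  Rows failing to parse or failing the balance check are
    collected in the error report instead of being dropped silently.
    """
    import pandas as pd

    path = Path(path)
    rows: list[tuple[str, str, Optional[str]]] = []
    text = path.read_text()
    first_line = text.splitlines()[0] if text.strip() else ""
    if path.suffix.lower() in (".csv", ".tsv") or "reaction_smiles" in first_line:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, dtype=str)
        if "reaction_smiles" not in df.columns:
            raise ValueError(f"{path}: missing required column 'reaction_smiles'")
        for k, row in df.iterrows():
            rid = str(row["id"]) if "id" in df.columns and not pd.isna(row["id"]) else str(k)
            ref = row.get("reference_smiles")
            rows.append((rid, row["reaction_smiles"], None if pd.isna(ref) else ref))
    else:
        for k, line in enumerate(text.splitlines()):
            line = line.strip()
            if line and not line.startswith("#"):
                rows.append((str(k), line, None))

    instances, errors = [], []
    for rid, smi, ref_smi in rows:
        try:
            inst = parse_reaction(smi, source_id=rid)
        except ReactionError as exc:
            errors.append({"id": rid, "smiles": smi, "error": str(exc)})
            continue
        table, balanced = check_balance(inst)
        if not balanced:
            errors.append(
                {
                    "id": rid,
                    "smiles": smi,
                    "error": "unbalanced reaction",
                    "counts": {el: list(c) for el, c in table.items() if c[0] != c[1]},
                }
            )
            continue
        if ref_smi:
            try:
                ref_inst = parse_reaction(ref_smi, source_id=rid)
                if ref_inst.reference_mapping is not None and inst.reference_mapping is None:
                    # align reference onto the working instance only when atom
                    # orders coincide; otherwise keep the fully-mapped variant
                    inst = ref_inst
            except ReactionError as exc:
                errors.append({"id": rid, "smiles": ref_smi, "error": f"reference: {exc}"})
        instances.append(inst)
    return DatasetLoadResult(instances, errors)
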
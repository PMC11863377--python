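"""Optional post-filters on nonequivalent mappings.

The modular product deliberately ignores hydrogens and bond multiplicity;
these filters re-introduce that information afterwards as tie-breakers:

* filter1 keeps the mappings minimising the number of hydrogen-involving
  bonds created or broken (equivalently, hydrogens that move);
* filter2, applied after filter1, further keeps the mappings minimising
  the total bond-multiplicity change over preserved bonds (aromatic bonds
  count 1.5, so scores may be fractional).
"""

from __future__ import annotations

from dataclasses import dataclass

from .reactions import ReactionInstance

FILTER_MODES = ("none", "filter1", "filter1+filter2")


def hydrogen_move_score(atom_map, reaction: ReactionInstance) -> int:
    """Created-or-broken hydrogen bonds under a total heavy-atom mapping.

    With hydrogens held as implicit counts, each hydrogen that moves from
    heavy atom a to heavy atom b breaks one H-bond and forms one, so the sum
    of absolute implicit-H differences over mapped pairs counts exactly the
    created-or-broken H bonds.  It is even for any balanced reaction.
    """
    if isinstance(atom_map, dict):
        atom_map = tuple(atom_map[i] for i in range(len(atom_map)))
    h_r = reaction.reactants.implicit_h
    h_p = reaction.products.implicit_h
    return sum(abs(h_r[i] - h_p[atom_map[i]]) for i in range(len(atom_map)))


def multiplicity_change_score(
    atom_map, reaction: ReactionInstance, include_changed_bonds: bool = False
) -> float:
    """Total |multiplicity change| over bonds preserved by the mapping.

    Broken and formed bonds are excluded by default (their count is already
    minimised by the MCES objective); ``include_changed_bonds`` adds their
    full multiplicity as a change.
    """
    if isinstance(atom_map, dict):
        atom_map = tuple(atom_map[i] for i in range(len(atom_map)))
    p_mult = reaction.products.bond_multiplicity()
    score = 0.0
    for i, j, m in reaction.reactants.bonds:
        key = frozenset((atom_map[i], atom_map[j]))
        if key in p_mult:
            score += abs(m - p_mult[key])
        elif include_changed_bonds:
            score += m
    if include_changed_bonds:
        preserved = {
            frozenset((atom_map[i], atom_map[j]))
            for i, j, _ in reaction.reactants.bonds
        }
        for i, j, m in reaction.products.bonds:
            if frozenset((i, j)) not in preserved:
                score += m
    return score


@dataclass
class FilterReport:
    mode: str
    input_clusters: int
    surviving_clusters: int
    scores: list[tuple[int, float]]  # (h_move, multiplicity change) per input cluster


def apply_filters(clusters, mode: str = "none"):
    """Keep the clusters minimal under the requested filter mode.

    Scores are read off each cluster's representative and asserted constant
    across members (automorphisms preserve H counts and multiplicities, so
    equivalent mappings must score identically).  At least one cluster
    always survives.
    """
    if mode not in FILTER_MODES:
        raise ValueError(f"unknown filter mode {mode!r}; expected one of {FILTER_MODES}")
    clusters = list(clusters)
    scores = []
    for cluster in clusters:
        rep = cluster.representative
        for member in cluster.members:
            if (member.h_move_score, member.multiplicity_change_score) != (
                rep.h_move_score,
                rep.multiplicity_change_score,
            ):
                raise AssertionError(
                    "equivalent mappings disagree on filter scores: "
                    "automorphism group is too coarse"
                )
        scores.append((rep.h_move_score, rep.multiplicity_change_score))

    surviving = clusters
    if clusters and mode in ("filter1", "filter1+filter2"):
        best_h = min(s[0] for s in scores)
        surviving = [c for c, s in zip(clusters, scores) if s[0] == best_h]
        if mode == "filter1+filter2":
            best_m = min(
                s[1] for c, s in zip(clusters, scores) if s[0] == best_h
            )
            surviving = [
                c for c, s in zip(clusters, scores) if s == (best_h, best_m)
            ]
    report = FilterReport(
        mode=mode,
        input_clusters=len(clusters),
        surviving_clusters=len(surviving),
        scores=scores,
    )
    return surviving, report
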
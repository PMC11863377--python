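# cliquemap

Rule-free atom-to-atom mapping (AAM) for balanced reactions, by exhaustive
enumeration of every mapping that minimises bond cleavages and formations.

Most AAM tools return a single mapping, chosen by reaction rules or a
trained model; when several chemically distinct mechanisms are optimal they
silently pick one, and when the true mechanism is unusual they pick wrong.
`cliquemap` instead enumerates *all* minimum-bond-change mappings, groups
them into chemically nonequivalent reaction patterns using molecular
symmetry, and optionally ranks them by hydrogen movement and
bond-multiplicity change — leaving genuinely ambiguous cases visibly
ambiguous, for mechanistic study, isotope-labelling design, or database
curation.

## Method in brief

For reactant and product graphs R and P (hydrogen-suppressed,
element-labelled), the mappings minimising cleavages + formations are the
maximum common edge subgraphs (MCES). These are found as maximum cliques of
the **modular product**: vertices are pairs of same-type bonds (one from R,
one from P; type = unordered element pair, multiplicity ignored), and two
vertices are adjacent iff their correspondences are compatible — no bond
reused, and atoms shared on one side exactly when shared on the other.

Maximum cliques are enumerated two ways:

* **exact** — branch-and-bound for the clique number, then pivoted
  Bron–Kerbosch enumeration pruned to that size;
* **sa** (default) — the clique problem is written as the QUBO/Ising energy
  `E(x) = −Σ_v x_v + A·Σ_{(u,v)∉E} x_u x_v` with penalty `A = 2 > 1`, whose
  ground states are exactly the maximum cliques; a simulated-annealing
  sampler draws ground states until a coupon-collector stopping rule
  certifies that the probability of having missed one is below `ε`
  (default 0.01).

Each clique induces a partial atom mapping; residual atoms are completed by
all per-element bijections; complete mappings are clustered under
`m ↦ σ_P ∘ m ∘ σ_R` over the molecular automorphism groups; optional
filters keep the clusters minimising hydrogen moves, then multiplicity
changes. See `docs/methods.md` for assumptions, parameters, and
limitations.

## Worked example

The enol→aldehyde tautomerisation `CC=CO>>CCC=O`:

```sh
$ cliquemap map "CC=CO>>CCC=O" --solver exact
reaction: N=5 max_clique=3 m=1 nonequivalent={'none': 1, 'filter1': 1, 'filter1+filter2': 1}
  [CH3:1][CH:2]=[CH:3][OH:4]>>[CH3:1][CH2:2][CH:3]=[O:4]
```

Reading the output: the modular product has `N=5` vertices (four C–C bond
pairs, one C–O pair) and a single maximum clique of size 3 (`m=1`), so
three bonds survive the reaction and only one nonequivalent mapping exists
under every filter mode. The mapped SMILES says atom `i` of the reactants
becomes atom `i` of the products: zero heavy bonds change — the reaction is
a double-bond shift (multiplicity change 2) plus one hydrogen moving from
oxygen to carbon (hydrogen score 2).

A symmetric counterpoint, `CC(C)O>>CCCO` (equivalent methyls in the
reactant): 6 element-preserving bijections exist, 4 are MCES-optimal (one
cleavage + one formation each), and symmetry clustering reduces them to
exactly 2 distinct reaction patterns — one migrating a C–C bond, one a C–O
bond. `cliquemap map "CC(C)O>>CCCO"` reports both.

The same API is available from Python:

```python
import cliquemap as cm

report = cm.run_single("CC(C)O>>CCCO", cm.PipelineOptions(solver="sa", seed=0))
report.cluster_counts   # {'none': 2, 'filter1': 2, 'filter1+filter2': 2}
report.mapped_smiles    # one atom-mapped reaction SMILES per pattern
```

Other entry points: `cliquemap bench dataset.csv` scores enumerated
mappings against reference-mapped SMILES (equivalence-aware: a reference
counts as found if it is symmetric-equivalent to any enumerated mapping),
and `cliquemap gen --atoms 8 --edits 2 --seed 7` emits synthetic balanced
reactions with planted ground-truth maps.

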
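# Methods

## Problem and model

Atom-to-atom mapping (AAM) asks which atom of the reactants becomes which
atom of the products in a balanced chemical reaction. `cliquemap` treats the
question as a pure graph problem, with no reaction rules, templates, or
training data: the plausible mappings are exactly those that minimise the
number of bonds cleaved plus bonds formed, and *all* of them are
enumerated, not just one.

Both sides of a reaction are modelled as hydrogen-suppressed molecular
graphs: atoms are vertices labelled by element, formal charge and an
implicit-hydrogen count; bonds are edges carrying a multiplicity in
{1, 1.5, 2, 3}. Multi-molecule sides are merged into one disconnected
graph. Bonds to hydrogen are never edges — hydrogens enter only through the
per-atom counts, which keeps the combinatorics on the heavy skeleton.

Minimising bond changes is the maximum common edge subgraph (MCES) problem
between the two sides, solved through the **modular product**: one vertex
per (reactant bond, product bond) pair of equal type, where a bond's type
is the unordered element pair of its endpoints and multiplicity is
deliberately ignored (double/triple-bond positions shift in many reactions,
e.g. pericyclic ones, and matching on them overcommits). Two vertices are
adjacent iff the two correspondences can coexist: they reuse no bond on
either side, and their reactant bonds share an atom exactly when their
product bonds do. Cliques of this graph are consistent bond
correspondences, and maximum cliques are the MCESs; each corresponds to the
set of bonds that survive the reaction.

From each maximum clique an atom-level partial mapping is read off by
matching bond endpoints (both orientations of homonuclear pairs are kept
and deduplicated downstream, so no optimal mapping is lost), and the atoms
outside it are assigned by every per-element bijection of the residual
atoms. A configurable cap (default 10^5 completions per reaction) turns
silent combinatorial blow-ups into actionable errors.

### A known edge case: unrealisable cliques

The adjacency rule checks *whether* atoms are shared, not *which* atoms
correspond, so a triangle of bonds matched against a 3-star forms a valid
clique that no atom bijection realises (the line-graph ΔY ambiguity).
`clique_to_partial_mappings` raises on such cliques; the pipeline-level
`realizable_mappings` skips them and, when every maximum clique is
unrealisable, descends one clique size at a time — enumerating all cliques
of that size, non-maximal included — until realisable correspondences
appear. A mapping completed from a size-k clique preserves exactly k bonds
(more would contradict maximality of the realisable size), so the
completions still attain the true minimum of cleavages + formations.

## Maximum-clique enumeration

Two interchangeable enumerators share the clique interface.

**Exact baseline.** A branch-and-bound search with a greedy-colouring upper
bound establishes the maximum clique size; a pivoted Bron–Kerbosch pass
pruned to that size then lists every maximum clique exactly once. Work is
budgeted in explored search nodes rather than wall-clock so that limit
behaviour is reproducible; an optional wall-clock cap exists only for
benchmark parity.

**Sampling enumerator.** The maximum clique problem on G = (V, E) is
encoded as the QUBO

    E(x) = − Σ_{v∈V} x_v + A · Σ_{(u,v)∉E} x_u x_v ,   A > 1,

whose ground states are exactly the maximum cliques at energy −(max size):
removing an endpoint of any violated pair lowers the energy by at least
A − 1. The penalty weight defaults to A = 2 — strong enough for the ground-
state identity, weak enough not to freeze the annealer — with a hard floor
A > 1. Samples come from a single-spin-flip Metropolis annealer
(numba-compiled) with a geometric inverse-temperature ramp sized from the
coefficient range: hot enough to accept the worst single flip ~50% of the
time, cold enough (β_final = ln 1000) that a unit uphill step is accepted
with probability 10⁻³. Defaults: 1000 sweeps, 16 reads per batch, and 3
restarts per returned sample (best-of). The restarts matter: products can
contain isolated near-maximum cliques whose escape barrier is ~2 energy
units, and the Gibbs weight of such traps at any reachable freezing
temperature leaves a few percent of single anneals stuck; best-of-3 drives
the per-sample failure rate to roughly (few %)³.

**Stopping rule.** Sampling repeats until all ground states have been seen
with failure probability at most ε (default 0.01). Assuming approximately
uniform sampling over ground states — a diagnostic chi-square p-value over
per-solution sample counts is reported with every run so the assumption can
be audited — the collector stops after r consecutive optimal-energy draws
that produce nothing new, where with m solutions currently known

    r = ⌈ ln(ε/(m+1)) / ln(m/(m+1)) ⌉ .

If an (m+1)-th solution existed, r consecutive misses would have
probability at most (m/(m+1))^r ≤ ε/(m+1); a union bound over the stages
m = 1, 2, … keeps the total failure probability below ε. Suboptimal draws
count toward nothing (they neither reset nor advance the counter), and a
strictly lower energy restarts the collection. The expected total sample
count grows as O(m ln m). A hard sample cap (default 2·10⁵) terminates
pathological runs; such results are flagged `stopped_by="sample-cap"` and
carry no ε guarantee.

## Symmetry clustering and filters

Two complete mappings describe the same chemistry when they differ only by
relabelling symmetric atoms: m₂ = σ_P ∘ m₁ ∘ σ_R with σ_R, σ_P
automorphisms of the reactant and product graphs. Automorphism groups are
computed by colour-refinement-seeded backtracking and, by default, respect
element, implicit-H count, formal charge *and* bond multiplicity: the
modular product may blur multiplicity, but two final mappings should not be
conflated unless the atoms they exchange are chemically indistinguishable.
A multiplicity/H-blind mode matching the product's coarser abstraction is
available behind flags. Groups are materialised explicitly — heavy-atom
symmetry groups of organic molecules at benchmark scale are small — and
clusters are orbits under the double action, each represented by its
lexicographically smallest member, sorted by (bond changes,
representative).

Two optional filters then use exactly the information the modular product
discarded. Filter 1 keeps the clusters minimising Σ_a |h_R(a) −
h_P(m(a))|, the number of hydrogen-involving bonds created or broken (each
moved hydrogen breaks one H-bond and forms one, so the score is even for
balanced reactions). Filter 2, applied after filter 1, minimises Σ |Δ
multiplicity| over preserved bonds; aromatic bonds count 1.5, so scores can
be fractional. Whether broken/formed bonds should also contribute their
multiplicity is genuinely open; the default counts preserved bonds only,
with a switch (`include_changed_bonds`) for the stricter reading. Filters
never empty the candidate set, and scores are asserted constant within each
cluster (automorphisms preserve both H counts and multiplicities).

## Synthetic reactions

The generator grows a random connected valence-respecting graph (valences
C:4, N:3, O:2, default 1; palette 3×C + N + O, biased toward carbon as in
organic reaction data), copies it, and applies n bond *migrations*: each
edit deletes one bond and forms one valence-legal new bond. Migrations keep
the bond count constant, and since implicit hydrogens fill remaining
valence, the reaction stays balanced by construction; a deletion-only edit
would change the total hydrogen count and unbalance the equation. The
identity permutation is the planted ground truth, costing at most 2 bond
changes per edit. Because a random migration is sometimes undone more
cheaply by a symmetric relabelling — in which case the plant is not a
ground truth at all — the generator rejection-samples until the planted
mapping attains the brute-force minimum (exhaustive check, default on for
n ≤ 10). Reactions are serialised to atom-mapped SMILES and re-parsed, so
fixtures exercise the real I/O path.

What the generator does *not* emulate: realistic reaction-class
distributions, multiplicity changes (generated bonds are single),
charge chemistry, agents, or unbalanced equations. Passing the synthetic
recovery tests therefore demonstrates the combinatorial machinery —
MCES optimality, enumeration completeness, symmetry reduction — not
chemical accuracy on real reaction corpora, which requires reference-mapped
benchmark data fed through `cliquemap bench`.

## Numerical and design choices

- Determinism: every stochastic component is seeded; identical seeds give
  identical runs (the annealer derives per-batch seeds from one stream).
- Tolerances: QUBO energies are compared with an absolute 10⁻⁹ slack;
  coefficients are small integers (or halves), so this is safe.
- Degenerate inputs: a bond-less side yields an empty modular product and
  pure residual permutation; single-atom reactions map trivially; agents
  between `>` separators are dropped with a warning; species consisting
  only of hydrogen are rejected as unsupported.
- Formal charges are stored and respected by the automorphism colouring
  but ignored in bond typing (types are element pairs only).
- Problem sizes in the shipped validation suites — 100 exhaustively
  checked QUBOs (N ≤ 16), 200 SA-vs-exact comparisons (N ≤ 60), 50
  synthetic recoveries (n ≤ 8) — were chosen so the whole battery completes
  in a few minutes on one core while still exercising every failure mode we
  know of.

## Limitations

- Unbalanced reactions are rejected, not mapped.
- Highly symmetric molecules multiply both the number of maximum cliques
  (sampling cost grows as m ln m) and the completion count; the caps
  convert these into explicit errors rather than silent stalls.
- The SA enumerator's ε guarantee is conditional on near-uniform
  ground-state sampling; the reported chi-square diagnostic flags runs
  where the assumption looks doubtful.
- Stereochemistry, tautomer normalisation and agent chemistry are out of
  scope; atom-map numbers on input are treated purely as reference data.
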
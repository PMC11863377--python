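"""End-to-end mapping pipeline and benchmark evaluation.

parse → balance check → modular product → maximum-clique enumeration
(exact branch-and-bound or SA sampling) → mapping completion → symmetry
clustering → optional filters → atom-mapped SMILES.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from typing import Optional

from . import annealing, clique, filters as filters_mod, mapping as mapping_mod
from .product_graph import build_modular_product
from .reactions import ReactionInstance, check_balance, parse_reaction, write_mapped_smiles
from .symmetry import automorphisms, cluster_mappings, equivalent


class UnbalancedReactionError(Exception):
    def __init__(self, table):
        bad = {el: c for el, c in table.items() if c[0] != c[1]}
        super().__init__(f"reaction is unbalanced: {bad}")
        self.table = table


@dataclass
class PipelineOptions:
    solver: str = "sa"  # "sa" | "exact"
    filter_mode: str = "none"  # "none" | "filter1" | "filter1+filter2"
    epsilon: float = 0.01
    penalty_a: float = 2.0
    seed: int = 0
    num_sweeps: int = 1000
    reads_per_call: int = 16
    sample_cap: int = 200_000
    exact_work_limit: Optional[int] = None
    completion_cap: int = 100_000


@dataclass
class RunReport:
    reaction_id: str
    n_atoms: int
    modular_product_n: int
    max_clique_size: int
    num_max_cliques: int
    solver: str
    epsilon: float
    seed: int
    complete_mappings: int
    cluster_counts: dict[str, int]  # nonequivalent mappings per filter mode
    filter_mode: str
    mapped_smiles: list[str]
    timings: dict[str, float] = field(default_factory=dict)
    stopping: dict = field(default_factory=dict)
    clusters: list = field(default_factory=list, repr=False)  # surviving, active mode
    all_clusters: list = field(default_factory=list, repr=False)  # unfiltered

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("clusters")
        d.pop("all_clusters")
        return d


def run_single(reaction, options: PipelineOptions | None = None) -> RunReport:
    """Run the full pipeline on one reaction (SMILES string or instance)."""
    opts = options or PipelineOptions()
    t0 = time.perf_counter()
    if isinstance(reaction, str):
        reaction = parse_reaction(reaction)
    table, balanced = check_balance(reaction)
    if not balanced:
        raise UnbalancedReactionError(table)
    timings = {"parse": time.perf_counter() - t0}

    t0 = time.perf_counter()
    product = build_modular_product(reaction)
    timings["modular_product"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stopping: dict = {}
    if opts.solver == "exact":
        enum = clique.enumerate_max_cliques(product, work_limit=opts.exact_work_limit)
        cliques, max_size = enum.cliques, enum.max_size
    elif opts.solver == "sa":
        params = annealing.SAParams(
            num_sweeps=opts.num_sweeps,
            reads_per_call=opts.reads_per_call,
            seed=opts.seed,
        )
        run = annealing.enumerate_max_cliques_sa(
            product,
            epsilon=opts.epsilon,
            params=params,
            A=opts.penalty_a,
            sample_cap=opts.sample_cap,
        )
        cliques, max_size = run.found.cliques, run.found.max_size
        stopping = {
            "total_samples": run.total_samples,
            "stopped_by": run.stopped_by,
            "uniformity_pvalue": run.uniformity_pvalue,
        }
    else:
        raise ValueError(f"unknown solver {opts.solver!r}")
    timings["clique_enumeration"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    mappings, realized_size = mapping_mod.realizable_mappings(
        cliques, max_size, product, cap=opts.completion_cap
    )
    if realized_size < max_size:
        stopping["realized_clique_size"] = realized_size
    timings["mapping_completion"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    aut_r = automorphisms(reaction.reactants)
    aut_p = automorphisms(reaction.products)
    clusters = cluster_mappings(mappings, aut_r, aut_p)
    cluster_counts = {}
    selected = clusters
    for mode in filters_mod.FILTER_MODES:
        surviving, _rep = filters_mod.apply_filters(clusters, mode)
        cluster_counts[mode] = len(surviving)
        if mode == opts.filter_mode:
            selected = surviving
    timings["clustering_and_filters"] = time.perf_counter() - t0

    mapped = [write_mapped_smiles(reaction, c.representative) for c in selected]
    return RunReport(
        reaction_id=reaction.source_id,
        n_atoms=reaction.reactants.n_atoms,
        modular_product_n=product.N,
        max_clique_size=max_size,
        num_max_cliques=len(cliques),
        solver=opts.solver,
        epsilon=opts.epsilon,
        seed=opts.seed,
        complete_mappings=len(mappings),
        cluster_counts=cluster_counts,
        filter_mode=opts.filter_mode,
        mapped_smiles=mapped,
        timings=timings,
        stopping=stopping,
        clusters=selected,
        all_clusters=clusters,
    )


@dataclass
class BenchmarkSummary:
    n_reactions: int
    correct: dict[str, int]  # per filter mode: reference lies in a surviving cluster
    unique_correct: dict[str, int]  # exactly one surviving cluster, and it is correct
    failures: list[dict]
    per_reaction: list[dict] = field(default_factory=list)


def run_benchmark(instances, options: PipelineOptions | None = None) -> BenchmarkSummary:
    """Equivalence-aware correctness evaluation against reference mappings.

    A reaction counts as *correct* under a filter mode when its reference
    mapping is symmetry-equivalent to a member of some surviving cluster,
    and *unique-correct* when additionally exactly one cluster survives.
    """
    opts = options or PipelineOptions()
    modes = filters_mod.FILTER_MODES
    correct = {mode: 0 for mode in modes}
    unique = {mode: 0 for mode in modes}
    failures: list[dict] = []
    per_reaction: list[dict] = []
    n_reactions = 0

    for inst in instances:
        n_reactions += 1
        if inst.reference_mapping is None:
            raise ValueError(f"reaction {inst.source_id!r} carries no reference mapping")
        try:
            base = run_single(inst, opts)
        except Exception as exc:  # capped/unbalanced reactions are reported, not fatal
            failures.append({"id": inst.source_id, "error": str(exc)})
            continue
        aut_r = automorphisms(inst.reactants)
        aut_p = automorphisms(inst.products)
        ref = mapping_mod.make_complete_mapping(inst.reference_mapping, inst)
        row = {"id": inst.source_id, "n_atoms": base.n_atoms,
               "modular_product_n": base.modular_product_n}
        for mode in modes:
            surviving, _ = filters_mod.apply_filters(base.all_clusters, mode)
            hit = any(
                equivalent(ref, member, aut_r, aut_p)
                for cl in surviving
                for member in cl.members
            )
            if hit:
                correct[mode] += 1
                if len(surviving) == 1:
                    unique[mode] += 1
            row[mode] = {"correct": hit, "surviving": len(surviving)}
        per_reaction.append(row)

    return BenchmarkSummary(
        n_reactions=n_reactions,
        correct=correct,
        unique_correct=unique,
        failures=failures,
        per_reaction=per_reaction,
    )


def power_law_fit(instances) -> tuple[float, float]:
    """Fit N ≈ a · n^b over a set of reactions (log-log least squares).

    Returns (a, b); useful for estimating modular-product size, and hence
    runtime, from atom counts.
    """
    import numpy as np

    ns, Ns = [], []
    for inst in instances:
        product = build_modular_product(inst)
        if product.N > 0 and inst.reactants.n_atoms > 0:
            ns.append(inst.reactants.n_atoms)
            Ns.append(product.N)
    if len(ns) < 2:
        raise ValueError("need at least two reactions with nonempty products")
    b, log_a = np.polyfit(np.log(ns), np.log(Ns), 1)
    return float(np.exp(log_a)), float(b)
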
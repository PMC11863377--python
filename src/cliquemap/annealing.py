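"""Maximum-clique enumeration by simulated-annealing sampling of a QUBO.

The maximum clique problem on a graph G = (V, E) is encoded as

    E(x) = - sum_{v in V} x_v  +  A * sum_{(u,v) not in E} x_u x_v ,

with binary x_v indicating clique membership and penalty weight A > 1.  For
A > 1 the ground states of E are exactly the maximum cliques, at energy
-(max clique size): deleting either endpoint of a violated (non-adjacent)
pair lowers the energy by at least A - 1 > 0, so no penalised state is ever
a minimum.  The QUBO is equivalent to an Ising model via x = (1 - s)/2.

A single-spin-flip Metropolis annealer (numba-compiled) plays the role of a
near-Gibbs ground-state sampler.  Repeated sampling with the
coupon-collector stopping rule below enumerates ALL ground states with
failure probability at most a user-set epsilon, assuming approximately
uniform sampling over ground states:

    with m distinct optima currently known, stop after r consecutive
    optimal-energy draws that produce nothing new, where
    r = ceil( ln(eps / (m+1)) / ln(m / (m+1)) ).

If an (m+1)-th optimum existed, each optimal draw would miss it with
probability at most m/(m+1); a run of r misses therefore has probability at
most eps/(m+1), and the union bound over the stages m = 1, 2, ... keeps the
total failure probability below eps.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .clique import Clique, CliqueEnumeration, _as_adjacency


class PenaltyParameterError(ValueError):
    """A <= 1 cannot guarantee that ground states are cliques."""


@dataclass
class Qubo:
    """Coefficients of the clique QUBO: linear −1 per vertex, +A per non-edge."""

    n: int
    A: float
    quadratic: np.ndarray  # dense symmetric matrix, A at non-adjacent pairs, 0 diagonal
    linear: np.ndarray  # all −1

    def energy(self, assignment) -> float:
        x = np.asarray(assignment, dtype=np.float64)
        if x.shape != (self.n,):
            raise ValueError(f"assignment length {x.shape} != {self.n}")
        return float(self.linear @ x + 0.5 * x @ self.quadratic @ x)


def build_qubo(graph, A: float = 2.0) -> Qubo:
    if A <= 1:
        raise PenaltyParameterError(f"penalty weight A must exceed 1, got {A}")
    adj = _as_adjacency(graph)
    n = adj.shape[0]
    quad = np.where(adj, 0.0, float(A))
    np.fill_diagonal(quad, 0.0)
    return Qubo(n=n, A=float(A), quadratic=quad, linear=np.full(n, -1.0))


def qubo_energy(qubo: Qubo, assignment) -> float:
    return qubo.energy(assignment)


@dataclass
class SAParams:
    """Annealing schedule: geometric inverse-temperature ramp.

    When beta bounds are left unset they are sized from the QUBO coefficient
    range: hot enough that the worst single flip is accepted with ~50%
    probability, cold enough that an uphill unit step is accepted with
    probability ~1e-3.  Each returned sample is the best of ``restarts``
    independent anneals — the usual defence against deep local minima such
    as isolated near-maximum cliques, whose escape barrier no practical
    single-run schedule crosses reliably.
    """

    num_sweeps: int = 1000
    beta_initial: Optional[float] = None
    beta_final: Optional[float] = None
    reads_per_call: int = 16
    restarts: int = 3
    seed: int = 0

    def betas(self, qubo: Qubo) -> np.ndarray:
        max_field = float(np.abs(qubo.linear).max(initial=1.0) + np.abs(qubo.quadratic).sum(axis=1).max(initial=0.0))
        b0 = self.beta_initial if self.beta_initial is not None else math.log(2.0) / max_field
        b1 = self.beta_final if self.beta_final is not None else math.log(1000.0)
        if not (b1 > b0 > 0):
            raise ValueError("need beta_final > beta_initial > 0")
        if self.num_sweeps < 1:
            raise ValueError("num_sweeps must be >= 1")
        return b0 * (b1 / b0) ** (np.arange(self.num_sweeps) / max(self.num_sweeps - 1, 1))


@njit(cache=True)
def _anneal_reads(quad, linear, betas, reads, restarts, seed):  # pragma: no cover
    n = linear.shape[0]
    np.random.seed(seed)
    states = np.zeros((reads, n), dtype=np.int8)
    energies = np.empty(reads, dtype=np.float64)
    for r in range(reads):
        best_e = np.inf
        for _rs in range(restarts):
            x = np.zeros(n, dtype=np.int8)
            for i in range(n):
                if np.random.random() < 0.5:
                    x[i] = 1
            # local field f[i] = dE of setting x[i] from 0 to 1, given the rest
            f = linear.copy()
            for i in range(n):
                for j in range(n):
                    if x[j] == 1:
                        f[i] += quad[i, j]
            for s in range(betas.shape[0]):
                beta = betas[s]
                for i in range(n):
                    dE = f[i] if x[i] == 0 else -f[i]
                    if dE <= 0.0 or np.random.random() < np.exp(-beta * dE):
                        delta = 1.0 if x[i] == 0 else -1.0
                        x[i] = 1 - x[i]
                        for j in range(n):
                            f[j] += delta * quad[j, i]
            e = 0.0
            for i in range(n):
                if x[i] == 1:
                    e += linear[i]
                    for j in range(i + 1, n):
                        if x[j] == 1:
                            e += quad[i, j]
            if e < best_e:
                best_e = e
                states[r] = x
        energies[r] = best_e
    return states, energies


def sa_sample(qubo: Qubo, params: SAParams) -> tuple[np.ndarray, float]:
    """One annealed assignment with its energy; deterministic given the seed."""
    states, energies = _anneal_reads(
        qubo.quadratic, qubo.linear, params.betas(qubo), 1, params.restarts,
        params.seed % (2**31),
    )
    return states[0].copy(), float(energies[0])


def sa_sample_batch(qubo: Qubo, params: SAParams) -> tuple[np.ndarray, np.ndarray]:
    states, energies = _anneal_reads(
        qubo.quadratic, qubo.linear, params.betas(qubo), params.reads_per_call,
        params.restarts, params.seed % (2**31),
    )
    return states, energies


def stopping_threshold(m: int, epsilon: float) -> int:
    """Consecutive non-novel optimal draws required before declaring the set
    of m known optima complete with failure probability <= epsilon."""
    if m < 1:
        return 1
    return math.ceil(math.log(epsilon / (m + 1)) / math.log(m / (m + 1)))


@dataclass
class EnumerationRun:
    found: CliqueEnumeration
    epsilon: float
    total_samples: int
    samples_per_solution: dict[tuple[int, ...], int] = field(default_factory=dict)
    stopped_by: str = "stopping-rule"  # or "sample-cap"
    best_energy: float = 0.0
    uniformity_pvalue: Optional[float] = None

    def uniformity_chisquare(self) -> Optional[float]:
        """p-value of a chi-square test that optimal solutions were sampled
        uniformly — the assumption behind the stopping-rule guarantee."""
        counts = np.array(list(self.samples_per_solution.values()), dtype=float)
        if counts.size < 2 or counts.sum() == 0:
            return None
        from scipy import stats

        return float(stats.chisquare(counts).pvalue)


def enumerate_max_cliques_sa(
    graph,
    epsilon: float = 0.01,
    params: SAParams | None = None,
    A: float = 2.0,
    sample_cap: int = 200_000,
) -> EnumerationRun:
    """Sampling-based enumeration of all maximum cliques.

    Collects distinct minimum-energy samples; whenever a strictly lower
    energy appears, the collection restarts.  Draws above the current best
    energy are discarded: they advance neither novelty nor the consecutive
    non-novel counter.  Terminates by the epsilon stopping rule, or by the
    sample cap (in which case the result carries no epsilon guarantee and is
    flagged ``stopped_by='sample-cap'``).
    """
    if not (0 < epsilon < 1):
        raise ValueError("epsilon must lie in (0, 1)")
    adj = _as_adjacency(graph)
    n = adj.shape[0]
    if n == 0:
        return EnumerationRun(CliqueEnumeration([], 0), epsilon, 0)
    if params is None:
        params = SAParams()
    qubo = build_qubo(adj, A=A)
    betas = params.betas(qubo)

    rng = random.Random(params.seed)
    best = math.inf
    solutions: dict[tuple[int, ...], int] = {}
    consecutive = 0
    total = 0
    stopped_by = "sample-cap"

    done = False
    while not done and total < sample_cap:
        reads = min(params.reads_per_call, sample_cap - total)
        states, energies = _anneal_reads(
            qubo.quadratic, qubo.linear, betas, reads, params.restarts,
            rng.getrandbits(31),
        )
        for k in range(reads):
            total += 1
            e = float(energies[k])
            if e < best - 1e-9:
                best = e
                solutions = {}
                consecutive = 0
            if abs(e - best) <= 1e-9:
                key = tuple(np.flatnonzero(states[k]).tolist())
                if key in solutions:
                    solutions[key] += 1
                    consecutive += 1
                else:
                    solutions[key] = 1
                    consecutive = 0
                if consecutive >= stopping_threshold(len(solutions), epsilon):
                    stopped_by = "stopping-rule"
                    done = True
                    break
            # suboptimal draws are ignored entirely

    cliques = [Clique(frozenset(key)) for key in sorted(solutions)]
    max_size = max((len(key) for key in solutions), default=0)
    run = EnumerationRun(
        found=CliqueEnumeration(cliques, max_size),
        epsilon=epsilon,
        total_samples=total,
        samples_per_solution=dict(solutions),
        stopped_by=stopped_by,
        best_energy=best if solutions else 0.0,
    )
    run.uniformity_pvalue = run.uniformity_chisquare()
    return run
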
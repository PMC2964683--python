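"""Steady-state genetic algorithm over chromosome vectors.

One iteration (generation) draws two distinct parents uniformly at
random, applies uniform crossover with a six-bit mask (probability
``crossover_prob``), applies one-point mutation to each offspring
(probability ``mutation_prob`` per offspring), then replaces the two
worst members of the population with the offspring.  The search stops
when the best fitness reaches zero (a design with no defects and
exactly balanced melting temperatures) or after ``max_generations``
iterations.

All feasibility repair is *hard*: length bounds, template fit, and the
extra-SNP exclusion.  Soft constraints are priced by the fitness
function, never repaired.  A single seeded ``random.Random`` instance
drives every stochastic choice, so a fixed seed reproduces the run
bit for bit.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Callable, Optional

from .constraint_fitness import ConstraintConfig, FitnessBreakdown, fitness
from .sequence_model import (
    ChromosomeVector,
    CTPPPrimerSet,
    TemplateDNA,
    feasible_bounds,
    is_feasible,
    realize_primer_set,
)

logger = logging.getLogger(__name__)

REPAIR_BUDGET = 100  # retries per crossover/mutation repair before giving up


@dataclass(frozen=True)
class GAConfig:
    """GA parameters.

    Defaults follow the classic DeJong/Spears operating point
    (population 50, crossover 0.6, mutation 0.001, 1000 iterations);
    a larger population (1000) samples the Tm landscape more
    accurately at proportional cost.
    """

    population_size: int = 50
    max_generations: int = 1000
    crossover_prob: float = 0.6
    mutation_prob: float = 0.001
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0.0 <= self.crossover_prob <= 1.0):
            raise ValueError("crossover_prob must be in [0, 1]")
        if not (0.0 <= self.mutation_prob <= 1.0):
            raise ValueError("mutation_prob must be in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_generations < 0:
            raise ValueError("max_generations must be >= 0")


@dataclass
class Individual:
    vector: ChromosomeVector
    breakdown: FitnessBreakdown

    @property
    def total(self) -> float:
        return self.breakdown.total


@dataclass
class Population:
    members: list
    generation: int = 0

    def __len__(self) -> int:
        return len(self.members)

    @property
    def best(self) -> Individual:
        return min(self.members, key=lambda m: m.total)

    @property
    def mean_fitness(self) -> float:
        return sum(m.total for m in self.members) / len(self.members)


@dataclass
class GAResult:
    """Outcome of one GA run on one template."""

    best_vector: ChromosomeVector
    best_breakdown: FitnessBreakdown
    primer_set: CTPPPrimerSet
    trace: list  # (generation, best_fitness, mean_fitness)
    generations_run: int
    converged: bool  # True when fitness 0 was reached


class Evaluator:
    """Memoizing fitness evaluator bound to one template and config.

    Vector -> fitness is deterministic, so repeated visits to the same
    chromosome (common on small templates) are served from cache.
    """

    def __init__(self, t: TemplateDNA, cfg: ConstraintConfig):
        self.t = t
        self.cfg = cfg
        self._cache: dict = {}

    def __call__(self, v: ChromosomeVector) -> FitnessBreakdown:
        bd = self._cache.get(v)
        if bd is None:
            s = realize_primer_set(
                self.t, v,
                self.cfg.len_min, self.cfg.len_max, self.cfg.product_min,
                self.cfg.reject_extra_in_inner,
            )
            bd = fitness(s, v, self.t, self.cfg)
            self._cache[v] = bd
        return bd


@dataclass(frozen=True)
class GeneBounds:
    """Legal sampling range per chromosome position."""

    len_min: int
    len_max: int
    product_min: int
    delta1: int
    delta2: int

    def range_for(self, pos: int) -> tuple[int, int]:
        if pos in (0, 2, 3, 5):
            return (self.len_min, self.len_max)
        if pos == 1:
            return (self.product_min, self.delta1)
        return (self.product_min, self.delta2)

    @classmethod
    def from_template(cls, t: TemplateDNA, cfg: ConstraintConfig) -> "GeneBounds":
        d1, d2 = feasible_bounds(t, cfg.len_max, cfg.product_min)
        return cls(cfg.len_min, cfg.len_max, cfg.product_min, d1, d2)


def _feasible(t: TemplateDNA, v: ChromosomeVector, cfg: ConstraintConfig) -> bool:
    return is_feasible(
        t, v, cfg.len_min, cfg.len_max, cfg.product_min, cfg.reject_extra_in_inner
    )


def enumerate_feasible(
    t: TemplateDNA, cfg: ConstraintConfig, bounds: GeneBounds, limit: Optional[int] = None
):
    """All feasible chromosome vectors in lexicographic order."""
    lo = [bounds.range_for(i)[0] for i in range(6)]
    hi = [bounds.range_for(i)[1] for i in range(6)]
    out = []
    for fl1 in range(lo[0], hi[0] + 1):
        for pl1 in range(lo[1], hi[1] + 1):
            for rl1 in range(lo[2], hi[2] + 1):
                for fl2 in range(lo[3], hi[3] + 1):
                    for pl2 in range(lo[4], hi[4] + 1):
                        for rl2 in range(lo[5], hi[5] + 1):
                            v = ChromosomeVector(fl1, pl1, rl1, fl2, pl2, rl2)
                            if _feasible(t, v, cfg):
                                out.append(v)
                                if limit is not None and len(out) > limit:
                                    return out
    return out


def _random_vector(rng: random.Random, bounds: GeneBounds) -> ChromosomeVector:
    return ChromosomeVector(
        rng.randint(bounds.len_min, bounds.len_max),
        rng.randint(bounds.product_min, bounds.delta1),
        rng.randint(bounds.len_min, bounds.len_max),
        rng.randint(bounds.len_min, bounds.len_max),
        rng.randint(bounds.product_min, bounds.delta2),
        rng.randint(bounds.len_min, bounds.len_max),
    )


def initialize(
    t: TemplateDNA,
    cfg: ConstraintConfig,
    ga: GAConfig,
    rng: random.Random,
    evaluate: Optional[Callable] = None,
) -> Population:
    """Random initial population of distinct feasible vectors.

    Rejection-samples within the gene bounds; if random sampling
    cannot fill the population (a tiny template admits few feasible
    vectors) the feasible space is enumerated and used directly, which
    also makes a population of exactly the feasible-space size equal
    that space.
    """
    bounds = GeneBounds.from_template(t, cfg)
    evaluate = evaluate or Evaluator(t, cfg)
    seen = set()
    members = []
    attempts = max(2000, 200 * ga.population_size)
    while len(members) < ga.population_size and attempts > 0:
        attempts -= 1
        v = _random_vector(rng, bounds)
        if v in seen or not _feasible(t, v, cfg):
            continue
        seen.add(v)
        members.append(Individual(v, evaluate(v)))
    if len(members) < ga.population_size:
        space = enumerate_feasible(t, cfg, bounds)
        for v in space:
            if len(members) >= ga.population_size:
                break
            if v not in seen:
                seen.add(v)
                members.append(Individual(v, evaluate(v)))
        if len(members) < ga.population_size:
            raise ValueError(
                f"template admits only {len(space)} feasible vectors; "
                f"cannot fill a duplicate-free population of {ga.population_size}"
            )
    return Population(members=members, generation=0)


def select_pair(pop: Population, rng: random.Random) -> tuple[Individual, Individual]:
    """Two distinct members drawn uniformly (random selection)."""
    n = len(pop.members)
    i = rng.randrange(n)
    j = rng.randrange(n - 1)
    if j >= i:
        j += 1
    return pop.members[i], pop.members[j]


def uniform_crossover(
    a: ChromosomeVector,
    b: ChromosomeVector,
    rng: random.Random,
    ga: GAConfig,
    t: Optional[TemplateDNA] = None,
    cfg: Optional[ConstraintConfig] = None,
    mask: Optional[str] = None,
) -> tuple[ChromosomeVector, ChromosomeVector]:
    """Uniform crossover with a six-bit mask; infeasible exchanges restored.

    A mask bit of 1 swaps that chromosome position between the
    parents.  When a template is supplied, exchanged positions that
    leave either child infeasible are restored one at a time (left to
    right) until both children are feasible; restoring every exchange
    reproduces the parents, so repair always terminates.  An explicit
    ``mask`` (e.g. ``"011001"``) bypasses the crossover-probability
    coin, which otherwise returns unchanged copies of the parents with
    probability ``1 - crossover_prob``.
    """
    if mask is None:
        if rng.random() >= ga.crossover_prob:
            return a, b
        bits = [rng.randint(0, 1) for _ in range(6)]
    else:
        if len(mask) != 6 or set(mask) - {"0", "1"}:
            raise ValueError("mask must be six binary characters")
        bits = [int(c) for c in mask]

    ca, cb = list(a), list(b)
    for i, bit in enumerate(bits):
        if bit:
            ca[i], cb[i] = cb[i], ca[i]

    if t is not None:
        cfg = cfg or ConstraintConfig()
        for i, bit in enumerate(bits):
            if not bit:
                continue
            va, vb = ChromosomeVector(*ca), ChromosomeVector(*cb)
            if _feasible(t, va, cfg) and _feasible(t, vb, cfg):
                break
            ca[i], cb[i] = a[i], b[i]  # restore the offending exchange
    return ChromosomeVector(*ca), ChromosomeVector(*cb)


def one_point_mutation(
    c: ChromosomeVector,
    t: TemplateDNA,
    rng: random.Random,
    ga: GAConfig,
    cfg: Optional[ConstraintConfig] = None,
    point: Optional[int] = None,
    value: Optional[int] = None,
) -> ChromosomeVector:
    """One-point mutation: regenerate one position within its legal range.

    Applied with probability ``mutation_prob`` unless an explicit
    ``point`` is given.  The regenerated value is drawn uniformly from
    the position's legal range and differs from the current value; on
    a feasibility violation a new point is selected and the value
    regenerated, up to a bounded number of retries (the chromosome
    then passes through unchanged, with a logged warning).
    """
    cfg = cfg or ConstraintConfig()
    if point is None:
        if rng.random() >= ga.mutation_prob:
            return c
    bounds = GeneBounds.from_template(t, cfg)

    if point is not None:
        vals = list(c)
        if value is None:
            lo, hi = bounds.range_for(point)
            value = rng.randint(lo, hi)
        vals[point] = value
        v = ChromosomeVector(*vals)
        if not _feasible(t, v, cfg):
            raise ValueError(f"mutation to {tuple(v)} violates feasibility")
        return v

    for _ in range(REPAIR_BUDGET):
        pos = rng.randrange(6)
        lo, hi = bounds.range_for(pos)
        if hi <= lo and c[pos] == lo:
            continue  # no alternative value exists at this position
        newval = rng.randint(lo, hi)
        if newval == c[pos]:
            continue
        vals = list(c)
        vals[pos] = newval
        v = ChromosomeVector(*vals)
        if _feasible(t, v, cfg):
            return v
    logger.warning("mutation repair budget exhausted; chromosome passed through")
    return c


def replace_worst_two(
    pop: Population, child_a: Individual, child_b: Individual
) -> Population:
    """Replace the two maximal-fitness members with the offspring.

    Ties among the worst are broken by stable order: of equally bad
    members, the later-inserted ones are removed first.
    """
    order = sorted(range(len(pop.members)), key=lambda i: pop.members[i].total)
    drop = set(order[-2:])
    members = [m for i, m in enumerate(pop.members) if i not in drop]
    members.extend([child_a, child_b])
    return Population(members=members, generation=pop.generation + 1)


def run_ga(
    t: TemplateDNA,
    cfg: Optional[ConstraintConfig] = None,
    ga: Optional[GAConfig] = None,
) -> GAResult:
    """Full GA search for the best CTPP primer set on one template."""
    cfg = cfg or ConstraintConfig()
    ga = ga or GAConfig()
    rng = random.Random(ga.seed)
    evaluate = Evaluator(t, cfg)

    pop = initialize(t, cfg, ga, rng, evaluate)
    trace = [(0, pop.best.total, pop.mean_fitness)]
    converged = pop.best.breakdown.is_zero(cfg)

    gen = 0
    while gen < ga.max_generations and not converged:
        gen += 1
        pa, pb = select_pair(pop, rng)
        va, vb = uniform_crossover(pa.vector, pb.vector, rng, ga, t, cfg)
        va = one_point_mutation(va, t, rng, ga, cfg)
        vb = one_point_mutation(vb, t, rng, ga, cfg)
        pop = replace_worst_two(pop, Individual(va, evaluate(va)), Individual(vb, evaluate(vb)))
        best = pop.best
        trace.append((gen, best.total, pop.mean_fitness))
        converged = best.breakdown.is_zero(cfg)

    best = pop.best
    primer_set = realize_primer_set(
        t, best.vector, cfg.len_min, cfg.len_max, cfg.product_min,
        cfg.reject_extra_in_inner,
    )
    return GAResult(
        best_vector=best.vector,
        best_breakdown=best.breakdown,
        primer_set=primer_set,
        trace=trace,
        generations_run=gen,
        converged=converged,
    )
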
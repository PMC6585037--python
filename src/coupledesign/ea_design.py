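"""Multi-objective evolutionary knockout search (SPEA2) with two fitness schemes.

``EAw`` maximizes growth and the production flux at maximum growth (read
from the parsimonious flux distribution, which is well-defined where an
FBA vertex is not).  ``EAm`` maximizes growth and the *minimum* product
flux with biomass fixed at its maximum, and only accepts candidates whose
product flux stays positive whenever growth exceeds half of its maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from coupledesign._lp import TOL_ACT, TOL_OPT
from coupledesign.model_core import (
    Environment,
    MetabolicModel,
    apply_knockouts,
    require_objective,
    set_environment,
)
from coupledesign.phenotype_sim import fba, flux_extremum, pfba

logger = logging.getLogger(__name__)

_PENALTY = 1e9  # fitness offset that ranks infeasible/rejected candidates last


@dataclass(frozen=True)
class Candidate:
    """A knockout strategy with its objective vector (maximization sense)."""

    knockouts: frozenset[str]
    objectives: tuple[float, ...] = ()
    feasible: bool = False
    accepted: bool = False

    @property
    def size(self) -> int:
        return len(self.knockouts)


@dataclass
class EAConfig:
    """Hyperparameters of one evolutionary run.

    Only the evaluation cap, the deletion cap and the run count are
    method-level settings; population/archive sizes and operator rates are
    conventional SPEA2 choices, exposed here for tuning.
    """

    formulation: str = "EAw"  # EAw | EAm
    product_id: str = ""
    max_knockouts: int = 20
    max_evaluations: int = 100_000
    population_size: int = 100
    archive_size: int = 100
    mutation_rate: float = 0.8
    crossover_rate: float = 0.5
    runs: int = 10
    seed: int | None = None
    pool: list[str] | None = None  # allowed knockout targets; None = default pool
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.population_size <= 0 or self.archive_size <= 0:
            raise ValueError("population and archive sizes must be positive")
        for rate in (self.mutation_rate, self.crossover_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("operator rates must lie in [0, 1]")


def default_knockout_pool(model: MetabolicModel, excluded=()) -> list[str]:
    """Knockout targets: internal reactions only.

    Exchange/source reactions (single-metabolite columns), the biomass
    pseudo-reaction and any reaction with a positive lower bound (e.g.
    maintenance ATP, which cannot be switched off) are not genetic
    targets.
    """
    pool = []
    for j, rid in enumerate(model.reaction_ids):
        if rid == model.objective_id or rid in excluded:
            continue
        if np.count_nonzero(model.S[:, j]) <= 1:  # exchange / sink / source
            continue
        if model.lb[j] > 0:
            continue
        pool.append(rid)
    return sorted(pool)


def evaluate_candidate(
    model: MetabolicModel,
    env: Environment | None,
    knockouts,
    formulation: str,
    product_id: str,
) -> Candidate:
    """Score one knockout set under the EAw or EAm scheme.

    Mutants with infeasible or zero-growth phenotypes receive objectives
    ``(0, 0)`` and ``feasible=False`` instead of raising.
    """
    knockouts = frozenset(knockouts)
    biomass_id = require_objective(model)
    mut = apply_knockouts(model, knockouts)
    if env is not None:
        mut = set_environment(mut, env)
    growth = fba(mut, biomass_id)
    if not growth.optimal or growth.objective_value <= TOL_ACT:
        return Candidate(knockouts=knockouts, objectives=(0.0, 0.0),
                         feasible=False, accepted=False)
    z = growth.objective_value
    if formulation == "EAw":
        dist = pfba(mut, biomass_id)
        if not dist.optimal:
            return Candidate(knockouts=knockouts, objectives=(0.0, 0.0),
                             feasible=False, accepted=False)
        return Candidate(knockouts=knockouts, objectives=(z, dist[product_id]),
                         feasible=True, accepted=True)
    if formulation == "EAm":
        fix = z * (1.0 - TOL_OPT)
        w = flux_extremum(mut, product_id, "min", extra_lb={biomass_id: fix})
        half = flux_extremum(mut, product_id, "min", extra_lb={biomass_id: z / 2.0})
        if w is None or half is None:
            return Candidate(knockouts=knockouts, objectives=(0.0, 0.0),
                             feasible=False, accepted=False)
        accepted = half > TOL_ACT
        return Candidate(knockouts=knockouts, objectives=(z, w),
                         feasible=True, accepted=accepted)
    raise ValueError(f"unknown EA formulation {formulation!r}")


def _dominates(a: tuple[float, ...], b: tuple[float, ...]) -> bool:
    """Strict Pareto dominance, maximization sense."""
    return all(x >= y for x, y in zip(a, b)) and any(x > y for x, y in zip(a, b))


def spea2_strength_raw(objectives: list[tuple[float, ...]]) -> tuple[np.ndarray, np.ndarray]:
    """Strength ``S`` and raw fitness ``R`` of the SPEA2 ranking."""
    N = len(objectives)
    dominates = np.zeros((N, N), dtype=bool)
    for i in range(N):
        for j in range(N):
            if i != j and _dominates(objectives[i], objectives[j]):
                dominates[i, j] = True
    strength = dominates.sum(axis=1)
    raw = np.array([strength[dominates[:, i]].sum() for i in range(N)], dtype=float)
    return strength, raw


def spea2_fitness(objectives: list[tuple[float, ...]]) -> np.ndarray:
    """Standard SPEA2 fitness: raw strength sum plus nearest-neighbour density.

    Strength ``S(i)`` counts the candidates ``i`` dominates; raw fitness
    ``R(i)`` sums the strengths of the dominators of ``i``; the density
    term ``D(i) = 1 / (sigma_k + 2)`` uses the distance to the
    ``k = floor(sqrt(N))``-th nearest neighbour.  Lower is better;
    non-dominated candidates have fitness < 1.
    """
    N = len(objectives)
    if N == 0:
        return np.zeros(0)
    pts = np.asarray(objectives, dtype=float)
    _, raw = spea2_strength_raw(objectives)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(dist, np.inf)
    k = max(1, min(int(np.sqrt(N)), N - 1))
    sigma_k = np.sort(dist, axis=1)[:, k - 1]
    sigma_k[~np.isfinite(sigma_k)] = 0.0
    density = 1.0 / (sigma_k + 2.0)
    return raw + density


def vary(parents: list[Candidate], config: EAConfig, rng: np.random.Generator,
         pool: list[str]) -> list[frozenset[str]]:
    """Produce offspring knockout sets via uniform set crossover and mutation.

    Mutation applies one of add/remove/replace to a single knockout;
    crossover draws each element of the parent union with probability 0.5
    and truncates to the deletion cap.  The empty set (wild-type) is an
    admissible candidate.
    """
    if not parents:
        raise ValueError("parents must be nonempty")
    offspring: list[frozenset[str]] = []
    n_out = len(parents)
    for k in range(n_out):
        p1 = parents[rng.integers(len(parents))]
        if rng.random() < config.crossover_rate and len(parents) > 1:
            p2 = parents[rng.integers(len(parents))]
            union = sorted(p1.knockouts | p2.knockouts)
            child = {r for r in union if rng.random() < 0.5}
        else:
            child = set(p1.knockouts)
        if rng.random() < config.mutation_rate:
            child = _mutate(child, pool, config.max_knockouts, rng)
        if len(child) > config.max_knockouts:
            keep = rng.choice(sorted(child), size=config.max_knockouts, replace=False)
            child = set(keep)
        offspring.append(frozenset(child))
    return offspring


def _mutate(child: set[str], pool: list[str], max_knockouts: int,
            rng: np.random.Generator) -> set[str]:
    child = set(child)
    available = sorted(set(pool) - child)
    ops = []
    if available and len(child) < max_knockouts:
        ops.append("add")
    if child:
        ops.append("remove")
    if child and available:
        ops.append("replace")
    if not ops:
        return child
    op = ops[rng.integers(len(ops))]
    if op == "add":
        child.add(available[rng.integers(len(available))])
    elif op == "remove":
        child.remove(sorted(child)[rng.integers(len(child))])
    else:
        child.remove(sorted(child)[rng.integers(len(child))])
        child.add(available[rng.integers(len(available))])
    return child


def _truncate(archive: list[Candidate], size: int) -> list[Candidate]:
    """SPEA2 distance-based truncation, deterministic tie-breaking.

    Repeatedly removes the candidate with the smallest nearest-neighbour
    distance profile; ties prefer keeping smaller knockout sets, then
    lexicographically earlier ones.
    """
    archive = list(archive)
    while len(archive) > size:
        pts = np.asarray([c.objectives for c in archive], dtype=float)
        n = len(archive)
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        np.fill_diagonal(dist, np.inf)
        profiles = np.sort(dist, axis=1)
        order = sorted(
            range(n),
            key=lambda i: (
                tuple(profiles[i]),
                -archive[i].size,
                tuple(sorted(archive[i].knockouts, reverse=True)),
            ),
        )
        archive.pop(order[0])
    return archive


def run_ea(
    model: MetabolicModel,
    env: Environment | None,
    config: EAConfig,
) -> list[Candidate]:
    """One SPEA2 run; returns the final non-dominated set of accepted candidates.

    With a fixed ``config.seed`` the run is bit-reproducible.  Evaluations
    are cached per knockout set but every requested evaluation counts
    toward ``max_evaluations``.
    """
    if not config.product_id:
        raise ValueError("config.product_id must be set")
    rng = np.random.default_rng(config.seed)
    pool = sorted(config.pool) if config.pool is not None else default_knockout_pool(
        model, excluded=config.excluded
    )
    if not pool:
        raise ValueError("empty knockout pool")
    cache: dict[frozenset[str], Candidate] = {}
    evaluations = 0

    def evaluate(ko: frozenset[str]) -> Candidate:
        nonlocal evaluations
        evaluations += 1
        if ko not in cache:
            cache[ko] = evaluate_candidate(model, env, ko, config.formulation,
                                           config.product_id)
        return cache[ko]

    def random_candidate() -> frozenset[str]:
        max_n = min(config.max_knockouts, len(pool))
        n = int(rng.integers(1, max_n + 1))
        return frozenset(rng.choice(pool, size=n, replace=False))

    population = [evaluate(random_candidate()) for _ in range(config.population_size)]
    archive: list[Candidate] = []
    while True:
        combined = _dedupe(population + archive)
        fitness = spea2_fitness([c.objectives for c in combined])
        usable = np.array([c.feasible and c.accepted for c in combined])
        fitness = fitness + np.where(usable, 0.0, _PENALTY)
        nondom = [c for c, f in zip(combined, fitness) if f < 1.0]
        if len(nondom) > config.archive_size:
            archive = _truncate(nondom, config.archive_size)
        else:
            # fill with the best dominated candidates for mating pressure
            order = np.argsort(fitness, kind="stable")
            archive = [combined[i] for i in order[: config.archive_size]]
        if evaluations >= config.max_evaluations:
            break
        mating = archive if archive else combined
        offspring = vary(mating, config, rng, pool)
        population = [evaluate(ko) for ko in offspring]
    final = [c for c in archive if c.feasible and c.accepted]
    fitness = spea2_fitness([c.objectives for c in final])
    result = [c for c, f in zip(final, fitness) if f < 1.0]
    logger.info("EA finished: %d evaluations, %d archived strategies",
                evaluations, len(result))
    return sorted(result, key=lambda c: (c.size, sorted(c.knockouts)))


def _dedupe(candidates: list[Candidate]) -> list[Candidate]:
    seen: set[frozenset[str]] = set()
    out = []
    for c in candidates:
        if c.knockouts not in seen:
            seen.add(c.knockouts)
            out.append(c)
    return out


def run_ea_multi(
    model: MetabolicModel,
    env: Environment | None,
    config: EAConfig,
) -> list[list[Candidate]]:
    """Execute ``config.runs`` independent seeded runs (heuristic variance)."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.runs)
    out = []
    for k, ss in enumerate(seeds):
        from dataclasses import replace as _replace

        run_cfg = _replace(config, seed=int(ss.generate_state(1)[0]))
        out.append(run_ea(model, env, run_cfg))
        logger.info("run %d/%d complete", k + 1, config.runs)
    return out
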
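"""Packaged toy networks, a seeded random-network generator, and brute-force
oracles that define ground truth for enumeration, coupling and EA tests.

The oracles deliberately share no code with the MILP enumeration path:
cut sets are found by exhaustively testing reaction subsets with plain
feasibility LPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from coupledesign.intervention import LinearFluxSpace, space_feasible, validate_target_space
from coupledesign.mcs_enum import CutSet
from coupledesign.model_core import Environment, MetabolicModel, apply_knockouts, set_environment
from coupledesign.phenotype_sim import fba, pfba
from coupledesign.screen_analyze import bpcy as _bpcy

#: combinatorial guards keeping oracle runtime within minutes
MAX_ORACLE_REACTIONS = 20
MAX_ORACLE_SIZE = 4

TOY_NAMES = ("TOY-A", "TOY-B", "TOY-C")


def toy_network(name: str, maintenance_lb: float = 0.0) -> MetabolicModel:
    """Build one of the packaged toy models.

    * ``TOY-A`` — a linear chain: substrate -> A -> B -> P -> out.
    * ``TOY-B`` — a branched network where biomass can be made with or
      without co-producing P; knocking out the product-free branch forces
      co-production.
    * ``TOY-C`` — TOY-B plus two product-free bypasses, giving a
      non-trivial knockout landscape for the evolutionary search.
    """
    if name == "TOY-A":
        return MetabolicModel(
            reaction_ids=["R_s", "R_1", "R_2", "R_ex"],
            metabolite_ids=["A", "B", "P"],
            S=np.array([
                [1, -1, 0, 0],
                [0, 1, -1, 0],
                [0, 0, 1, -1],
            ], dtype=float),
            lb=np.zeros(4),
            ub=np.array([10.0, 1000.0, 1000.0, 1000.0]),
            objective_id="R_ex",
            name="TOY-A",
        )
    if name in ("TOY-B", "TOY-C"):
        #            R_s R_1 R_2 R_3 R_bio R_p R_m [R_4 R_5]
        mets = ["A", "B", "D", "P"]
        cols = {
            "R_s": {"A": 1},
            "R_1": {"A": -1, "B": 1},
            "R_2": {"A": -1, "D": 1},
            "R_3": {"B": -1, "D": 1, "P": 1},
            "R_bio": {"D": -1},
            "R_p": {"P": -1},
            "R_m": {"D": -1},
        }
        if name == "TOY-C":
            cols["R_4"] = {"A": -1, "D": 2}
            cols["R_5"] = {"B": -1, "D": 1}
        rids = list(cols)
        S = np.zeros((len(mets), len(rids)))
        for j, rid in enumerate(rids):
            for met, coef in cols[rid].items():
                S[mets.index(met), j] = coef
        lb = np.zeros(len(rids))
        ub = np.full(len(rids), 1000.0)
        ub[rids.index("R_s")] = 10.0
        lb[rids.index("R_m")] = maintenance_lb
        return MetabolicModel(
            reaction_ids=rids,
            metabolite_ids=mets,
            S=S,
            lb=lb,
            ub=ub,
            objective_id="R_bio",
            name=name,
        )
    raise ValueError(f"unknown toy network {name!r}")


def random_network(
    n_intermediates: int = 4,
    n_extra_edges: int = 4,
    rev_fraction: float = 0.0,
    seed: int | None = None,
    max_retries: int = 50,
) -> MetabolicModel:
    """Seeded random layered network: substrate -> intermediates -> biomass/product.

    A backbone chain guarantees a route to the biomass precursor; extra
    sparse edges (some co-producing the product) create alternative routes
    and knockout opportunities.  The model is regenerated (bounded
    retries) until wild-type growth is positive; the result is fully
    determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        model = _random_network_once(n_intermediates, n_extra_edges, rev_fraction, rng)
        growth = fba(model)
        if growth.optimal and growth.objective_value > 1e-6:
            return model
    raise RuntimeError("could not generate a growing random network")


def _random_network_once(n_intermediates, n_extra_edges, rev_fraction, rng):
    inner = [f"I_{k}" for k in range(1, n_intermediates + 1)]
    mets = ["A"] + inner + ["D", "P"]
    chain = ["A"] + inner + ["D"]
    cols: dict[str, dict[str, float]] = {"R_s": {"A": 1.0}}
    for k in range(len(chain) - 1):
        cols[f"R_c{k + 1}"] = {chain[k]: -1.0, chain[k + 1]: 1.0}
    nodes = ["A"] + inner + ["D"]
    for k in range(n_extra_edges):
        src, dst = rng.choice(nodes, size=2, replace=False)
        stoich = {src: -1.0, dst: float(rng.integers(1, 3))}
        if rng.random() < 0.5:
            stoich["P"] = 1.0
        cols[f"R_x{k + 1}"] = stoich
    cols["R_bio"] = {"D": -1.0}
    cols["R_p"] = {"P": -1.0}
    cols["R_m"] = {"D": -1.0}
    rids = list(cols)
    S = np.zeros((len(mets), len(rids)))
    for j, rid in enumerate(rids):
        for met, coef in cols[rid].items():
            S[mets.index(met), j] = coef
    lb = np.zeros(len(rids))
    ub = np.full(len(rids), 1000.0)
    ub[rids.index("R_s")] = 10.0
    for j, rid in enumerate(rids):
        if rid.startswith(("R_c", "R_x")) and rng.random() < rev_fraction:
            lb[j] = -1000.0
    return MetabolicModel(
        reaction_ids=rids,
        metabolite_ids=mets,
        S=S,
        lb=lb,
        ub=ub,
        objective_id="R_bio",
        name="random",
    )


@dataclass
class BruteForceResult:
    """Minimal blocking sets found by exhaustive subset testing."""

    cutsets: list[CutSet]
    status: str = "ok"

    def reaction_sets(self) -> set[frozenset[str]]:
        return {cs.reactions for cs in self.cutsets}


def brute_force_mcs(
    model: MetabolicModel,
    target: LinearFluxSpace,
    max_size: int,
) -> BruteForceResult:
    """Exhaustive minimal-cut-set oracle (independent of the MILP path).

    Tests every reaction subset of size <= ``max_size`` by LP feasibility
    of the target space under the knockouts and keeps exactly the minimal
    blocking sets.
    """
    if model.n_reactions > MAX_ORACLE_REACTIONS:
        raise ValueError(f"oracle guard: model has > {MAX_ORACLE_REACTIONS} reactions")
    if max_size > MAX_ORACLE_SIZE:
        raise ValueError(f"oracle guard: max_size > {MAX_ORACLE_SIZE}")
    report = validate_target_space(model, target)
    if "ORIGIN_INCLUDED" in report.flags:
        return BruteForceResult([], status="unblockable")
    if not space_feasible(model, target):
        return BruteForceResult([], status="target already blocked")
    minimal: list[frozenset[str]] = []
    for size in range(1, max_size + 1):
        for combo in combinations(model.reaction_ids, size):
            cand = frozenset(combo)
            if any(found <= cand for found in minimal):
                continue
            if not space_feasible(model, target, cand):
                minimal.append(cand)
    cutsets = [
        CutSet(reactions=s, minimal=True, formulation=target.label, order_index=k)
        for k, s in enumerate(sorted(minimal, key=lambda s: (len(s), sorted(s))))
    ]
    return BruteForceResult(cutsets)


def exhaustive_best_knockouts(
    model: MetabolicModel,
    env: Environment | None,
    product_id: str,
    substrate_id: str,
    max_size: int,
    metric: str = "BPCY",
    pool: list[str] | None = None,
) -> tuple[frozenset[str], float]:
    """Best knockout set (<= max_size over the EA pool) by the pFBA-phenotype metric.

    Ties break deterministically toward smaller sets, then lexicographic
    order.
    """
    from coupledesign.ea_design import default_knockout_pool

    if metric != "BPCY":
        raise ValueError(f"unsupported metric {metric!r}")
    if model.n_reactions > MAX_ORACLE_REACTIONS or max_size > MAX_ORACLE_SIZE:
        raise ValueError("oracle guard violated")
    pool = sorted(pool) if pool is not None else default_knockout_pool(model)
    best: tuple[frozenset[str], float] | None = None
    candidates = [frozenset()] + [
        frozenset(c) for size in range(1, max_size + 1)
        for c in combinations(pool, size)
    ]
    for cand in candidates:
        mut = apply_knockouts(model, cand)
        if env is not None:
            mut = set_environment(mut, env)
        dist = pfba(mut)
        if not dist.optimal:
            continue
        v_s = abs(dist[substrate_id])
        if v_s <= 0:
            continue
        score = _bpcy(dist[model.objective_id], dist[product_id], v_s)
        key = (score, -len(cand))
        if best is None or key > (best[1], -len(best[0])):
            best = (cand, score)
    if best is None:
        raise RuntimeError("no feasible candidate found")
    return best


def write_fixture_sbml(out_dir: str) -> list[str]:
    """Write the toy networks as SBML files (exercises model I/O round trips)."""
    import os

    from coupledesign.model_core import to_cobra

    paths = []
    os.makedirs(out_dir, exist_ok=True)
    for name in TOY_NAMES:
        import cobra.io

        path = os.path.join(out_dir, f"{name.replace('-', '_')}.xml")
        cobra.io.write_sbml_model(to_cobra(toy_network(name)), path)
        paths.append(path)
    return paths
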
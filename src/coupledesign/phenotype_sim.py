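"""LP-based phenotype prediction: FBA, pFBA, FVA and coupling classification.

All metrics reported downstream are read from pFBA or FVA, which are
well-defined; plain FBA may return an arbitrary optimal vertex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from coupledesign._lp import TOL_OPT, solve_lp
from coupledesign.model_core import (
    Environment,
    MetabolicModel,
    apply_knockouts,
    require_objective,
    set_environment,
    split_reversible,
)

#: coupling thresholds default: small positive value so that low-production
#: growth-coupled designs are not discarded arbitrarily
EPSILON = 1e-4


@dataclass
class FluxDistribution:
    """One steady-state flux vector with its objective value and solver status."""

    fluxes: dict[str, float]
    objective_value: float | None
    status: str

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    """Per-reaction (min, max) flux at a stated growth fraction."""

    ranges: dict[str, tuple[float, float]]
    fraction: float
    objective_value: float

    def __getitem__(self, reaction_id: str) -> tuple[float, float]:
        return self.ranges[reaction_id]


@dataclass
class CouplingClass:
    """Growth-coupling verdict with the supporting LP minima.

    ``strong`` requires every admissible flux vector (no growth demand) to
    carry product above ``p_min`` while growth above ``b_min`` stays
    possible; ``weak`` only requires product above ``p_min`` whenever
    biomass is forced above ``b_min``.
    """

    kind: str  # strong | weak | none
    min_product_free: float | None = None
    min_product_at_growth: float | None = None
    max_growth: float | None = None
    p_min: float = EPSILON
    b_min: float = EPSILON
    status: str = "ok"


class InfeasibleProblemError(RuntimeError):
    """Raised when a base LP required by an analysis is infeasible."""


def _objective_vector(model: MetabolicModel, objective_id: str) -> np.ndarray:
    c = np.zeros(model.n_reactions)
    c[model.index(objective_id)] = 1.0
    return c


def fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    sense: str = "max",
) -> FluxDistribution:
    """Flux balance analysis: optimize one reaction flux at steady state.

    Infeasible or unbounded problems are reported via ``status``; no
    exception is raised.
    """
    objective_id = objective_id or require_objective(model)
    res = solve_lp(
        _objective_vector(model, objective_id),
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        lb=model.lb,
        ub=model.ub,
        sense=sense,
    )
    if not res.optimal:
        return FluxDistribution(fluxes={}, objective_value=None, status=res.status)
    fluxes = dict(zip(model.reaction_ids, res.x))
    return FluxDistribution(fluxes=fluxes, objective_value=res.objective, status="optimal")


def pfba(model: MetabolicModel, objective_id: str | None = None) -> FluxDistribution:
    """Parsimonious FBA: fix the FBA optimum, minimize total absolute flux.

    The absolute-value objective is linearized on the split (fully
    irreversible) model by minimizing the sum of forward and backward
    fluxes.
    """
    objective_id = objective_id or require_objective(model)
    base = fba(model, objective_id)
    if not base.optimal:
        return base
    opt = base.objective_value
    split = split_reversible(model)
    sm = split.model
    # fix the objective flux (fwd - bwd) at its optimum
    obj_row = np.zeros(sm.n_reactions)
    for i in split.columns_of(objective_id):
        obj_row[i] = 1.0 if i in split.fwd_of else -1.0
    A_eq = np.vstack([sm.S, obj_row])
    b_eq = np.concatenate([np.zeros(sm.n_metabolites), [opt]])
    res = solve_lp(
        np.ones(sm.n_reactions),
        A_eq=A_eq,
        b_eq=b_eq,
        lb=sm.lb,
        ub=sm.ub,
        sense="min",
    )
    if not res.optimal:  # numerically brittle fixings: retry with a tolerance band
        slack = TOL_OPT * max(1.0, abs(opt))
        A_ub = np.vstack([obj_row, -obj_row])
        b_ub = np.array([opt + slack, -(opt - slack)])
        res = solve_lp(
            np.ones(sm.n_reactions),
            A_eq=np.asarray(sm.S),
            b_eq=np.zeros(sm.n_metabolites),
            A_ub=A_ub,
            b_ub=b_ub,
            lb=sm.lb,
            ub=sm.ub,
            sense="min",
        )
    if not res.optimal:
        return FluxDistribution(fluxes={}, objective_value=None, status=res.status)
    fluxes = split.to_original_flux(res.x)
    return FluxDistribution(fluxes=fluxes, objective_value=opt, status="optimal")


def fva(
    model: MetabolicModel,
    objective_id: str | None = None,
    fraction: float = 1.0,
    reactions: list[str] | None = None,
) -> FluxRange:
    """Flux variability analysis at a fraction of the optimal objective.

    For each requested reaction, minimize and maximize its flux subject to
    ``v_objective >= fraction * optimum``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    objective_id = objective_id or require_objective(model)
    base = fba(model, objective_id)
    if not base.optimal:
        raise InfeasibleProblemError(f"base FBA is {base.status}")
    opt = base.objective_value
    j_obj = model.index(objective_id)
    A_ub = -np.eye(1, model.n_reactions, j_obj)
    b_ub = np.array([-fraction * opt])
    reactions = list(reactions) if reactions is not None else list(model.reaction_ids)
    ranges: dict[str, tuple[float, float]] = {}
    for rid in reactions:
        c = _objective_vector(model, rid)
        lo = solve_lp(c, A_eq=model.S, b_eq=np.zeros(model.n_metabolites),
                      A_ub=A_ub, b_ub=b_ub, lb=model.lb, ub=model.ub, sense="min")
        hi = solve_lp(c, A_eq=model.S, b_eq=np.zeros(model.n_metabolites),
                      A_ub=A_ub, b_ub=b_ub, lb=model.lb, ub=model.ub, sense="max")
        if not (lo.optimal and hi.optimal):
            raise InfeasibleProblemError(f"FVA subproblem for {rid!r} failed")
        ranges[rid] = (lo.objective, hi.objective)
    return FluxRange(ranges=ranges, fraction=fraction, objective_value=opt)


def flux_extremum(
    model: MetabolicModel,
    reaction_id: str,
    sense: str = "min",
    extra_lb: dict[str, float] | None = None,
) -> float | None:
    """Optimize one flux subject to steady state plus optional extra lower bounds.

    Returns ``None`` when infeasible.  This is the primitive behind
    robustness and coupling checks ("min product at growth >= threshold").
    """
    A_ub = None
    b_ub = None
    if extra_lb:
        rows = []
        rhs = []
        for rid, bound in extra_lb.items():
            row = np.zeros(model.n_reactions)
            row[model.index(rid)] = -1.0
            rows.append(row)
            rhs.append(-bound)
        A_ub = np.vstack(rows)
        b_ub = np.array(rhs)
    res = solve_lp(
        _objective_vector(model, reaction_id),
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        A_ub=A_ub,
        b_ub=b_ub,
        lb=model.lb,
        ub=model.ub,
        sense=sense,
    )
    return res.objective if res.optimal else None


def classify_coupling(
    model: MetabolicModel,
    strategy,
    product_id: str,
    p_min: float = EPSILON,
    b_min: float = EPSILON,
    env: Environment | None = None,
) -> CouplingClass:
    """Classify a knockout strategy as strong/weak/none growth coupling.

    The universal quantifier over admissible flux vectors is evaluated by
    LP minimization of the product flux over the corresponding polyhedron:

    * strong: min product with **no** growth demand >= ``p_min`` and growth
      above ``b_min`` remains attainable;
    * weak: min product subject to ``v_biomass >= b_min`` is >= ``p_min``
      (and not strong).
    """
    biomass_id = require_objective(model)
    mut = apply_knockouts(model, strategy)
    if env is not None:
        mut = set_environment(mut, env)
    growth = fba(mut, biomass_id)
    if not growth.optimal:
        return CouplingClass(kind="none", status=f"mutant {growth.status}",
                             p_min=p_min, b_min=b_min)
    b_max = growth.objective_value
    p_free = flux_extremum(mut, product_id, "min")
    p_at_b = flux_extremum(mut, product_id, "min", extra_lb={biomass_id: b_min})
    if p_free is not None and p_free >= p_min and b_max >= b_min:
        kind = "strong"
    elif p_at_b is not None and p_at_b >= p_min:
        kind = "weak"
    else:
        kind = "none"
    return CouplingClass(
        kind=kind,
        min_product_free=p_free,
        min_product_at_growth=p_at_b,
        max_growth=b_max,
        p_min=p_min,
        b_min=b_min,
    )


def write_flux_tsv(dist: FluxDistribution, path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"reaction_id": r, "flux": v} for r, v in dist.fluxes.items()]
    ).to_csv(path, sep="\t", index=False)


def write_range_tsv(rng: FluxRange, path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"reaction_id": r, "min": lo, "max": hi} for r, (lo, hi) in rng.ranges.items()]
    ).to_csv(path, sep="\t", index=False)
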
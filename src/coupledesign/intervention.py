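"""Target (undesired) and desired flux spaces as linear inequality systems.

A :class:`LinearFluxSpace` holds ``T.v >= b`` jointly with the model's
steady-state and bound constraints.  Three target formulations are
supported:

* ``MCSe`` — low product/substrate yield vectors under a maximum substrate
  uptake, with the maintenance-ATP flux held above ``m_atp`` (the
  inhomogeneous component that keeps the origin out of the space);
* ``MCSf`` — low-yield vectors at a *fixed* substrate uptake, removing the
  maintenance assumption;
* ``MCSw`` — near-zero product vectors at biomass above a fraction ``F``
  of the wild-type maximum (weaker coupling demands).

The yield constraint ``v_p/v_s <= y_min`` is stored linearized as
``y_min*v_s - v_p >= 0``, valid because all formulations force positive
substrate uptake.  Substrate terms are expressed on uptake *magnitude*:
for BiGG-style exchanges (negative flux = uptake) the sign is flipped
automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from coupledesign._lp import feasible
from coupledesign.model_core import Environment, MetabolicModel, apply_knockouts


class ParameterError(ValueError):
    """A formulation parameter required by the chosen formulation is missing."""


@dataclass
class LinearFluxSpace:
    """Inequality system ``T.v >= b`` over the fluxes of a reference model."""

    T: np.ndarray
    b: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.T = np.atleast_2d(np.asarray(self.T, dtype=float))
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.T.shape[0] != self.b.shape[0]:
            raise ValueError("row count of T must match length of b")
        if self.T.shape[0] < 1:
            raise ValueError("a flux space needs at least one row")

    @property
    def n_rows(self) -> int:
        return self.T.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.T.shape[1]

    @property
    def homogeneous(self) -> bool:
        return bool(np.all(self.b <= 0.0))


@dataclass
class FormulationParams:
    """Parameters selecting and instantiating one target-space formulation."""

    formulation: str  # MCSe | MCSf | MCSw
    product_id: str | None = None
    substrate_id: str | None = None
    biomass_id: str | None = None
    atpm_id: str | None = None
    s_max: float | None = None
    y_min: float | None = None
    m_atp: float | None = None
    eps: float | None = None
    F: float | None = None
    b_max: float | None = None

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ParameterError(
                f"{self.formulation} requires parameter(s): {', '.join(missing)}"
            )


@dataclass
class ValidationReport:
    valid: bool
    flags: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)


def _unit_row(model: MetabolicModel, reaction_id: str, coef: float = 1.0) -> np.ndarray:
    row = np.zeros(model.n_reactions)
    row[model.index(reaction_id)] = coef
    return row


def _uptake_row(model: MetabolicModel, substrate_id: str) -> np.ndarray:
    """Row whose dot product with v equals the uptake *magnitude*.

    Exchange reactions written as ``met ->`` carry uptake as negative flux;
    source-style reactions (``-> met``) carry it as positive flux.
    """
    sign = -1.0 if model.lb[model.index(substrate_id)] < 0 else 1.0
    return _unit_row(model, substrate_id, sign)


def build_target_space(model: MetabolicModel, params: FormulationParams) -> LinearFluxSpace:
    """Build the undesired flux space ``T.v >= b`` for one formulation."""
    rows: list[np.ndarray] = []
    rhs: list[float] = []
    form = params.formulation
    if form in ("MCSe", "MCSf"):
        params.require("product_id", "substrate_id", "y_min", "s_max")
        s_row = _uptake_row(model, params.substrate_id)
        # y_min * v_s - v_p >= 0  (linearized low-yield condition)
        rows.append(params.y_min * s_row - _unit_row(model, params.product_id))
        rhs.append(0.0)
        if form == "MCSe":
            params.require("atpm_id", "m_atp")
            rows.append(-s_row)            # uptake <= s_max
            rhs.append(-params.s_max)
            rows.append(_unit_row(model, params.atpm_id))  # v_atp >= m_atp
            rhs.append(params.m_atp)
        else:  # MCSf: fixed uptake, as two inequality rows
            rows.append(s_row)
            rhs.append(params.s_max)
            rows.append(-s_row)
            rhs.append(-params.s_max)
    elif form == "MCSw":
        params.require("product_id", "biomass_id", "eps", "F")
        b_max = params.b_max
        if b_max is None:
            from coupledesign.phenotype_sim import fba

            wt = fba(model, params.biomass_id)
            if not wt.optimal:
                raise ParameterError("MCSw needs b_max but wild-type FBA failed")
            b_max = wt.objective_value
        rows.append(-_unit_row(model, params.product_id))   # v_p <= eps
        rhs.append(-params.eps)
        rows.append(_unit_row(model, params.biomass_id))    # v_b >= F * b_max
        rhs.append(params.F * b_max)
        if params.s_max is not None and params.substrate_id is not None:
            # fixed substrate uptake (optional: engaged when s_max is given)
            s_row = _uptake_row(model, params.substrate_id)
            rows.append(s_row)
            rhs.append(params.s_max)
            rows.append(-s_row)
            rhs.append(-params.s_max)
    else:
        raise ParameterError(f"unknown formulation {form!r}")
    return LinearFluxSpace(T=np.vstack(rows), b=np.array(rhs), label=form)


def build_desired_space(
    model: MetabolicModel,
    env: Environment,
    biomass_id: str,
    min_biomass: float,
) -> LinearFluxSpace:
    """Desired space: environment bounds plus a biomass lower bound.

    The biomass demand is what discards lethal cut sets; ``min_biomass``
    must therefore be strictly positive.
    """
    if min_biomass <= 0:
        raise ValueError("min_biomass must be > 0 (otherwise lethals survive)")
    rows: list[np.ndarray] = []
    rhs: list[float] = []
    for rid, (lo, hi) in env.items():
        model.index(rid)  # id check
        if np.isfinite(lo):
            rows.append(_unit_row(model, rid))
            rhs.append(lo)
        if np.isfinite(hi):
            rows.append(-_unit_row(model, rid))
            rhs.append(-hi)
    rows.append(_unit_row(model, biomass_id))
    rhs.append(min_biomass)
    return LinearFluxSpace(T=np.vstack(rows), b=np.array(rhs), label="desired")


def validate_target_space(model: MetabolicModel, space: LinearFluxSpace) -> ValidationReport:
    """Reject target spaces that contain the origin of the flux cone.

    If the zero flux vector satisfies both the model constraints and
    ``T.0 >= b`` there is no cut set of any size, so enumeration would be
    pointless; such problems are flagged ``ORIGIN_INCLUDED``.
    """
    report = ValidationReport(valid=True)
    if space.n_reactions != model.n_reactions:
        report.valid = False
        report.flags.append("DIMENSION_MISMATCH")
        report.messages.append(
            f"space has {space.n_reactions} columns, model has {model.n_reactions}"
        )
        return report
    zero_in_model = bool(np.all(model.lb <= 0.0) and np.all(model.ub >= 0.0))
    zero_in_space = bool(np.all(space.b <= 0.0))
    if zero_in_model and zero_in_space:
        report.valid = False
        report.flags.append("ORIGIN_INCLUDED")
        report.messages.append(
            "the zero flux vector lies in the target space; no cut set can block it"
        )
    return report


def space_feasible(
    model: MetabolicModel,
    space: LinearFluxSpace,
    knockouts=(),
) -> bool:
    """LP feasibility of a flux space jointly with model constraints and knockouts."""
    mut = apply_knockouts(model, knockouts) if knockouts else model
    return feasible(
        A_eq=mut.S,
        b_eq=np.zeros(mut.n_metabolites),
        A_ub=-space.T,
        b_ub=-space.b,
        lb=mut.lb,
        ub=mut.ub,
    )
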
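"""Load, represent and transform constraint-based metabolic models.

The in-memory representation is a plain dense stoichiometric matrix with
bound vectors; knockouts and environmental conditions are applied by
bound manipulation so that reaction indices stay stable across the whole
pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: COBRA-convention default bounds used when an SBML file carries none.
DEFAULT_UB = 1000.0
DEFAULT_LB_REVERSIBLE = -1000.0


class ModelFormatError(ValueError):
    """Raised when an input file cannot be parsed as a usable model."""


class UnknownReactionError(KeyError):
    """Raised when a reaction identifier is not part of the model."""

    def __init__(self, ids):
        self.ids = sorted(ids)
        super().__init__(f"unknown reaction id(s): {', '.join(self.ids)}")


@dataclass
class MetabolicModel:
    """A stoichiometric model ``S.v = 0, lb <= v <= ub``.

    Rows of ``S`` are metabolites, columns are reactions; entries are
    stoichiometric coefficients.  ``reversible[i]`` holds exactly when
    ``lb[i] < 0``.
    """

    reaction_ids: list[str]
    metabolite_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    objective_id: str | None = None
    reaction_pathways: dict[str, list[str]] = field(default_factory=dict)
    reaction_ec: dict[str, str] = field(default_factory=dict)
    metabolite_formulas: dict[str, str] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        m, n = self.S.shape
        if len(self.reaction_ids) != n or len(self.metabolite_ids) != m:
            raise ValueError("S shape does not match id lists")
        if len(set(self.reaction_ids)) != n:
            raise ValueError("duplicate reaction ids")
        if len(set(self.metabolite_ids)) != m:
            raise ValueError("duplicate metabolite ids")
        if self.lb.shape != (n,) or self.ub.shape != (n,):
            raise ValueError("bound vectors must have one entry per reaction")
        if np.any(self.lb > self.ub):
            bad = [self.reaction_ids[i] for i in np.flatnonzero(self.lb > self.ub)]
            raise ValueError(f"lb > ub for: {', '.join(bad)}")
        if self.objective_id is not None and self.objective_id not in self.reaction_ids:
            raise ValueError(f"objective {self.objective_id!r} not in model")
        self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def reversible(self) -> np.ndarray:
        return self.lb < 0

    def index(self, reaction_id: str) -> int:
        try:
            return self._rxn_index[reaction_id]
        except KeyError:
            raise UnknownReactionError([reaction_id]) from None

    def copy(self) -> "MetabolicModel":
        return replace(
            self,
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            reaction_ids=list(self.reaction_ids),
            metabolite_ids=list(self.metabolite_ids),
            reaction_pathways={k: list(v) for k, v in self.reaction_pathways.items()},
            reaction_ec=dict(self.reaction_ec),
            metabolite_formulas=dict(self.metabolite_formulas),
        )


@dataclass
class Environment:
    """Per-reaction bound overrides (substrate uptake, oxygen, maintenance ATP)."""

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"environment lb > ub for {rid!r}")

    def items(self):
        return self.bounds.items()


@dataclass
class SplitModel:
    """A model with every reversible reaction split into forward/backward halves.

    ``fwd_of``/``bwd_of`` map split column index to the original reaction
    id; every split column appears in exactly one of the two maps.
    """

    model: MetabolicModel
    original: MetabolicModel
    fwd_of: dict[int, str]
    bwd_of: dict[int, str]
    pairing: set[tuple[int, int]]

    def original_reaction_of(self, split_index: int) -> str:
        if split_index in self.fwd_of:
            return self.fwd_of[split_index]
        return self.bwd_of[split_index]

    def columns_of(self, reaction_id: str) -> list[int]:
        """Split-column indices belonging to one original reaction."""
        return [
            i
            for i in range(self.model.n_reactions)
            if self.original_reaction_of(i) == reaction_id
        ]

    def to_original_flux(self, v_split: np.ndarray) -> dict[str, float]:
        """Recombine a split flux vector as fwd - bwd on original reactions."""
        out = {rid: 0.0 for rid in self.original.reaction_ids}
        for i, rid in self.fwd_of.items():
            out[rid] += v_split[i]
        for i, rid in self.bwd_of.items():
            out[rid] -= v_split[i]
        return out


def load_model(path: str) -> MetabolicModel:
    """Read an SBML (Level 3 + FBC preferred) file into a :class:`MetabolicModel`.

    Reaction and metabolite order follow document order.  Files without
    explicit flux bounds fall back to the COBRA defaults (0/1000 for
    irreversible, -1000/1000 for reversible reactions) with a warning.
    A model without a declared objective loads with ``objective_id=None``;
    callers that need one should use :func:`require_objective`.
    """
    import cobra.io

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml/cobra raise a mix of types
        raise ModelFormatError(f"cannot parse SBML file {path!r}: {exc}") from exc
    model = from_cobra(cmodel)
    # cobra fills missing bounds with +/-1000 regardless of the SBML
    # reversibility flag; restore the direction-aware convention
    for rid, reversible in _reactions_without_bounds(str(path)):
        j = model.index(rid)
        model.lb[j] = DEFAULT_LB_REVERSIBLE if reversible else 0.0
        model.ub[j] = DEFAULT_UB
        logger.warning(
            "no flux bounds for %s in %s: defaulting to [%g, %g]",
            rid, path, model.lb[j], model.ub[j],
        )
    return model


def _reactions_without_bounds(path: str) -> list[tuple[str, bool]]:
    """(reaction id, reversible flag) for reactions carrying no bound info.

    A reaction counts as bounded when it has FBC flux bounds or legacy
    kinetic-law LOWER_BOUND/UPPER_BOUND parameters.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    sbml_model = doc.getModel()
    if sbml_model is None:
        return []
    out = []
    for rxn in sbml_model.getListOfReactions():
        fbc = rxn.getPlugin("fbc")
        if fbc is not None and (fbc.isSetLowerFluxBound() or fbc.isSetUpperFluxBound()):
            continue
        kl = rxn.getKineticLaw()
        if kl is not None and any(
            p.getId() in ("LOWER_BOUND", "UPPER_BOUND") for p in kl.getListOfParameters()
        ):
            continue
        out.append((rxn.getId(), bool(rxn.getReversible())))
    return out


def from_cobra(cmodel) -> MetabolicModel:
    """Convert a :class:`cobra.Model` (document order preserved)."""
    reaction_ids = [r.id for r in cmodel.reactions]
    metabolite_ids = [m.id for m in cmodel.metabolites]
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    S = np.zeros((len(metabolite_ids), len(reaction_ids)))
    lb = np.zeros(len(reaction_ids))
    ub = np.zeros(len(reaction_ids))
    pathways: dict[str, list[str]] = {}
    ec: dict[str, str] = {}
    for j, rxn in enumerate(cmodel.reactions):
        for met, coef in rxn.metabolites.items():
            S[met_index[met.id], j] = coef
        lb[j], ub[j] = rxn.bounds
        groups = rxn.annotation.get("pathways") if rxn.annotation else None
        if groups:
            pathways[rxn.id] = groups if isinstance(groups, list) else [groups]
        if rxn.annotation and "ec-code" in rxn.annotation:
            val = rxn.annotation["ec-code"]
            ec[rxn.id] = val if isinstance(val, str) else val[0]
    formulas = {m.id: m.formula for m in cmodel.metabolites if m.formula}
    objective_id = None
    for rxn in cmodel.reactions:
        if rxn.objective_coefficient:
            objective_id = rxn.id
            break
    return MetabolicModel(
        reaction_ids=reaction_ids,
        metabolite_ids=metabolite_ids,
        S=S,
        lb=lb,
        ub=ub,
        objective_id=objective_id,
        reaction_pathways=pathways,
        reaction_ec=ec,
        metabolite_formulas=formulas,
        name=cmodel.id or "",
    )


def to_cobra(model: MetabolicModel):
    """Build a :class:`cobra.Model` mirror (used for SBML export)."""
    import cobra

    cmodel = cobra.Model(model.name or "model")
    mets = {mid: cobra.Metabolite(mid, compartment="c") for mid in model.metabolite_ids}
    for mid, formula in model.metabolite_formulas.items():
        mets[mid].formula = formula
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.add_metabolites(
            {
                mets[model.metabolite_ids[i]]: model.S[i, j]
                for i in np.flatnonzero(model.S[:, j])
            }
        )
        rxn.bounds = (float(model.lb[j]), float(model.ub[j]))
        rxns.append(rxn)
    cmodel.add_reactions(rxns)
    if model.objective_id is not None:
        cmodel.objective = model.objective_id
    return cmodel


def require_objective(model: MetabolicModel) -> str:
    if model.objective_id is None:
        raise ModelFormatError("model declares no objective reaction")
    return model.objective_id


def split_reversible(model: MetabolicModel) -> SplitModel:
    """Replace every reversible reaction with forward and backward halves.

    Backward columns are negated originals; bounds map to fwd ``[0, ub]``
    and bwd ``[0, -lb]``.  Irreversible columns (including those with a
    positive lower bound, e.g. maintenance ATP) are kept as-is.
    """
    cols: list[np.ndarray] = []
    ids: list[str] = []
    lb: list[float] = []
    ub: list[float] = []
    fwd_of: dict[int, str] = {}
    bwd_of: dict[int, str] = {}
    pairing: set[tuple[int, int]] = set()
    for j, rid in enumerate(model.reaction_ids):
        if model.lb[j] < 0:
            f = len(cols)
            cols.append(model.S[:, j])
            ids.append(f"{rid}__fwd")
            lb.append(0.0)
            ub.append(max(model.ub[j], 0.0))
            fwd_of[f] = rid
            b = len(cols)
            cols.append(-model.S[:, j])
            ids.append(f"{rid}__bwd")
            lb.append(0.0)
            ub.append(-model.lb[j])
            bwd_of[b] = rid
            pairing.add((f, b))
        else:
            i = len(cols)
            cols.append(model.S[:, j])
            ids.append(rid)
            lb.append(model.lb[j])
            ub.append(model.ub[j])
            fwd_of[i] = rid
    split = MetabolicModel(
        reaction_ids=ids,
        metabolite_ids=list(model.metabolite_ids),
        S=np.column_stack(cols) if cols else np.zeros((model.n_metabolites, 0)),
        lb=np.array(lb),
        ub=np.array(ub),
        objective_id=None,
        name=f"{model.name}__split",
    )
    return SplitModel(model=split, original=model, fwd_of=fwd_of, bwd_of=bwd_of, pairing=pairing)


def _check_ids(model: MetabolicModel, ids) -> None:
    missing = [r for r in ids if r not in model._rxn_index]
    if missing:
        raise UnknownReactionError(missing)


def apply_knockouts(model: MetabolicModel, knockouts) -> MetabolicModel:
    """Return a copy with ``lb = ub = 0`` for each knocked-out reaction."""
    knockouts = set(knockouts)
    _check_ids(model, knockouts)
    out = model.copy()
    for rid in knockouts:
        j = out.index(rid)
        out.lb[j] = 0.0
        out.ub[j] = 0.0
    return out


def set_environment(model: MetabolicModel, env: Environment) -> MetabolicModel:
    """Return a copy with bounds overridden exactly for the listed reactions."""
    _check_ids(model, env.bounds)
    out = model.copy()
    for rid, (lo, hi) in env.items():
        j = out.index(rid)
        out.lb[j] = lo
        out.ub[j] = hi
    return out


def write_summary_tsv(model: MetabolicModel, path: str) -> None:
    """Write a per-reaction summary (id, lb, ub, reversible, pathways)."""
    import pandas as pd

    rows = [
        {
            "reaction_id": rid,
            "lb": model.lb[j],
            "ub": model.ub[j],
            "reversible": bool(model.lb[j] < 0),
            "pathways": ";".join(model.reaction_pathways.get(rid, [])),
        }
        for j, rid in enumerate(model.reaction_ids)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
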
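"""Cut-set enumeration through a dual system solved as a k-shortest MILP.

The primal question "does the target space stay feasible after knocking
out a reaction set?" is dualized: the target space over the split
(fully irreversible) model,

    S.v = 0,  v >= 0,  A.v >= a

(where ``A``/``a`` collect the target rows plus the engaged flux bounds),
is infeasible exactly when a certificate ``(u, w)`` exists with

    (S'.u - A'.w)_i >= 0   for every reaction column i not knocked out,
    a.w >= 1,  w >= 0.

Relaxation variables ``v_dual`` (one per reaction column) absorb the
violated rows; their support, merged over split pairs, is a reaction set
whose knockout blocks the target space.  Binary indicators on the
relaxation variables turn minimum-support certificates into a MILP; an
exclusion row per incumbent yields the k-shortest enumeration, which
returns cut sets in non-decreasing size and is complete up to the size
cap.  ``h_dual`` carries the downward relaxation used for unsplit
reversible rows (equality rows); on a fully split model it stays at zero
but keeps the block structure of the dual network intact.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from coupledesign.intervention import LinearFluxSpace, space_feasible
from coupledesign.model_core import MetabolicModel, SplitModel

#: big-M linking the relaxation variables to their binary indicators; the
#: dual is a cone whose scale is pinned by the witness row a.w >= 1, so a
#: fixed constant is safe for the network sizes this package targets.
BIG_M = 1e4

#: witness constant: any positive value yields the same supports (cone scaling)
WITNESS_C = 1.0


@dataclass
class DualSystem:
    """The transposed/extended system whose shortest supports are cut sets.

    Variable blocks: ``u`` (one free variable per metabolite), ``v_dual``
    and ``h_dual`` (one nonnegative variable per split reaction column),
    ``w`` (one nonnegative variable per target/bound row).
    """

    split: SplitModel
    target: LinearFluxSpace          # on the original model's columns
    A: np.ndarray                    # target rows + engaged bound rows, split columns
    a: np.ndarray
    n_target_rows: int

    @property
    def n_metabolites(self) -> int:
        return self.split.model.n_metabolites

    @property
    def n_columns(self) -> int:
        return self.split.model.n_reactions

    @property
    def n_rows(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class CutSet:
    """A set of reaction knockouts with provenance flags."""

    reactions: frozenset[str]
    minimal: bool = False
    constrained: bool = False
    formulation: str = ""
    order_index: int = -1

    @property
    def size(self) -> int:
        return len(self.reactions)

    def sorted_reactions(self) -> list[str]:
        return sorted(self.reactions)

    def to_dict(self) -> dict:
        return {
            "reactions": ";".join(self.sorted_reactions()),
            "size": self.size,
            "minimal": self.minimal,
            "constrained": self.constrained,
            "formulation": self.formulation,
        }


class EnumerationResult(list):
    """List of :class:`CutSet` with a termination status attached."""

    def __init__(self, cutsets=(), status: str = "exhausted"):
        super().__init__(cutsets)
        self.status = status


def _split_target(split: SplitModel, target: LinearFluxSpace) -> np.ndarray:
    """Map target rows from original reaction columns to split columns."""
    orig = split.original
    T = np.zeros((target.n_rows, split.model.n_reactions))
    for i in range(split.model.n_reactions):
        if i in split.fwd_of:
            j = orig.index(split.fwd_of[i])
            T[:, i] = target.T[:, j]
        else:
            j = orig.index(split.bwd_of[i])
            T[:, i] = -target.T[:, j]
    return T


def build_dual_system(split: SplitModel, target: LinearFluxSpace) -> DualSystem:
    """Assemble the dual system for a split model and a validated target space.

    The engaged flux bounds of the split model (finite upper bounds and
    positive lower bounds) join the target rows, so the dual certificate
    sees exactly the constraint set the primal feasibility LP uses.
    """
    sm = split.model
    if target.n_reactions != split.original.n_reactions:
        raise ValueError(
            f"target has {target.n_reactions} columns but the model has "
            f"{split.original.n_reactions} reactions"
        )
    rows = [_split_target(split, target)]
    rhs = [np.asarray(target.b, dtype=float)]
    bound_rows = []
    bound_rhs = []
    for i in range(sm.n_reactions):
        if np.isfinite(sm.ub[i]):
            row = np.zeros(sm.n_reactions)
            row[i] = -1.0
            bound_rows.append(row)
            bound_rhs.append(-sm.ub[i])
        if sm.lb[i] > 0:
            row = np.zeros(sm.n_reactions)
            row[i] = 1.0
            bound_rows.append(row)
            bound_rhs.append(sm.lb[i])
    if bound_rows:
        rows.append(np.vstack(bound_rows))
        rhs.append(np.array(bound_rhs))
    return DualSystem(
        split=split,
        target=target,
        A=np.vstack(rows),
        a=np.concatenate(rhs),
        n_target_rows=target.n_rows,
    )


def _columns_by_reaction(split: SplitModel) -> dict[str, list[int]]:
    cols: dict[str, list[int]] = {}
    for i in range(split.model.n_reactions):
        cols.setdefault(split.original_reaction_of(i), []).append(i)
    return cols


def _reduce_to_minimal(
    model: MetabolicModel, target: LinearFluxSpace, reactions: frozenset[str]
) -> frozenset[str] | None:
    """Greedy reduction to a minimal blocking subset; None if not blocking."""
    if space_feasible(model, target, reactions):
        return None
    current = set(reactions)
    for rid in sorted(reactions):
        if len(current) == 1:
            break
        trial = current - {rid}
        if not space_feasible(model, target, trial):
            current = trial
    return frozenset(current)


def enumerate_shortest(
    dual: DualSystem,
    max_size: int,
    max_solutions: int | None = None,
    time_limit: float | None = None,
) -> EnumerationResult:
    """Enumerate minimal cut sets in non-decreasing support size.

    After each incumbent an exclusion row over the merged reaction
    indicators forbids the set and all its supersets.  Every MILP support
    is verified (and, defensively, greedily reduced) against the primal
    target LP before being reported.
    """
    if max_size <= 0:
        return EnumerationResult([], "max_size")
    split = dual.split
    model = split.original
    if not space_feasible(model, dual.target):
        return EnumerationResult([], "target already blocked")
    m, n, nrows = dual.n_metabolites, dual.n_columns, dual.n_rows
    cols_of = _columns_by_reaction(split)
    rxn_order = sorted(cols_of)

    # variable layout: u(m) | w(nrows) | v(n) | h(n) | zv(n) | zh(n)
    nvar = m + nrows + 4 * n
    o_w, o_v, o_h, o_zv, o_zh = m, m + nrows, m + nrows + n, m + nrows + 2 * n, m + nrows + 3 * n
    lbv = np.concatenate([
        np.full(m, -BIG_M), np.zeros(nrows), np.zeros(n), np.zeros(n),
        np.zeros(n), np.zeros(n),
    ])
    ubv = np.concatenate([
        np.full(m, BIG_M), np.full(nrows, BIG_M), np.full(n, BIG_M), np.full(n, BIG_M),
        np.ones(n), np.ones(n),
    ])
    integrality = np.zeros(nvar)
    integrality[o_zv:] = 1

    c = np.zeros(nvar)
    c[o_zv:] = 1.0

    constraints = []
    # reaction rows: S'.u - A'.w + v - h >= 0
    rows = np.zeros((n, nvar))
    rows[:, :m] = dual.split.model.S.T
    rows[:, o_w:o_v] = -dual.A.T
    rows[:, o_v:o_h] = np.eye(n)
    rows[:, o_h:o_zv] = -np.eye(n)
    constraints.append(LinearConstraint(rows, 0.0, np.inf))
    # witness: a.w >= c > 0
    wit = np.zeros(nvar)
    wit[o_w:o_v] = dual.a
    constraints.append(LinearConstraint(wit, WITNESS_C, np.inf))
    # indicator linking: v <= M z, h <= M z
    link = np.zeros((2 * n, nvar))
    link[:n, o_v:o_h] = np.eye(n)
    link[:n, o_zv:o_zh] = -BIG_M * np.eye(n)
    link[n:, o_h:o_zv] = np.eye(n)
    link[n:, o_zh:] = -BIG_M * np.eye(n)
    constraints.append(LinearConstraint(link, -np.inf, 0.0))
    # one active relaxation per original reaction: split pairs and the
    # (v, h) pair of each column cannot be simultaneously active
    excl = np.zeros((len(rxn_order), nvar))
    for k, rid in enumerate(rxn_order):
        for i in cols_of[rid]:
            excl[k, o_zv + i] = 1.0
            excl[k, o_zh + i] = 1.0
    constraints.append(LinearConstraint(excl, -np.inf, 1.0))
    # global size cap
    cap = np.zeros(nvar)
    cap[o_zv:] = 1.0
    constraints.append(LinearConstraint(cap, -np.inf, float(max_size)))

    def reaction_indicator_row(rids) -> np.ndarray:
        row = np.zeros(nvar)
        for rid in rids:
            for i in cols_of[rid]:
                row[o_zv + i] = 1.0
                row[o_zh + i] = 1.0
        return row

    found: list[CutSet] = []
    seen: set[frozenset[str]] = set()
    exclusions: list[LinearConstraint] = []
    status = "exhausted"
    start = time.monotonic()
    while True:
        if max_solutions is not None and len(found) >= max_solutions:
            status = "max_solutions"
            break
        # default HiGHS MIP integrality tolerance (1e-6) combined with the
        # big-M linking lets phantom relaxations of size M*tol slip through
        # with z ~ 0; tighten it so rounded supports are trustworthy
        options = {"mip_feasibility_tolerance": 1e-9,
                   "primal_feasibility_tolerance": 1e-9}
        if time_limit is not None:
            remaining = time_limit - (time.monotonic() - start)
            if remaining <= 0:
                status = "timeout"
                break
            options["time_limit"] = remaining
        with warnings.catch_warnings():
            # scipy forwards the HiGHS tolerance options verbatim but warns
            warnings.filterwarnings("ignore", message="Unrecognized options")
            res = milp(
                c,
                constraints=constraints + exclusions,
                integrality=integrality,
                bounds=Bounds(lbv, ubv),
                options=options,
            )
        if res.status == 1:
            status = "timeout"
            break
        if res.status != 0 or res.x is None:
            status = "exhausted" if found else "no cut sets <= max_size"
            break
        z = res.x[o_zv:]
        active_cols = {i % n for i in np.flatnonzero(z > 0.5)}
        support = frozenset(split.original_reaction_of(i) for i in active_cols)
        reduced = _reduce_to_minimal(model, dual.target, support)
        if reduced is None:
            # The rounded support does not block the target: a numerical
            # leak.  Excluding it would wrongly discard supersets, so stop
            # and report instead of risking an unsound enumeration.
            status = "numerical"
            break
        exclusions.append(
            LinearConstraint(reaction_indicator_row(reduced), -np.inf, len(reduced) - 1.0)
        )
        if reduced in seen:
            continue
        seen.add(reduced)
        if len(reduced) <= max_size:
            found.append(
                CutSet(
                    reactions=reduced,
                    minimal=True,
                    formulation=dual.target.label,
                    order_index=len(found),
                )
            )
    found.sort(key=lambda cs: (cs.size, cs.sorted_reactions()))
    found = [replace(cs, order_index=k) for k, cs in enumerate(found)]
    return EnumerationResult(found, status)


def verify_minimality(
    model: MetabolicModel, target: LinearFluxSpace, cutset: CutSet | frozenset | set
) -> CutSet:
    """Check and, if needed, greedily reduce a cut set to a minimal one.

    The returned :class:`CutSet` carries the reduced reaction set; its
    ``minimal`` flag reports whether the set *as given* was already a
    minimal blocking set.  A non-blocking input is returned unchanged with
    ``minimal=False``.
    """
    reactions = frozenset(cutset.reactions if isinstance(cutset, CutSet) else cutset)
    formulation = cutset.formulation if isinstance(cutset, CutSet) else target.label
    reduced = _reduce_to_minimal(model, target, reactions)
    if reduced is None:
        return CutSet(reactions=reactions, minimal=False, formulation=formulation)
    return CutSet(reactions=reduced, minimal=(reduced == reactions), formulation=formulation)


def constrain_mcs(
    model: MetabolicModel,
    cutsets,
    desired: LinearFluxSpace | None,
) -> list[CutSet]:
    """Keep the cut sets under which the desired space stays feasible."""
    kept: list[CutSet] = []
    for cs in cutsets:
        reactions = cs.reactions if isinstance(cs, CutSet) else frozenset(cs)
        if desired is None or space_feasible(model, desired, reactions):
            base = cs if isinstance(cs, CutSet) else CutSet(reactions=reactions, minimal=True)
            kept.append(replace(base, constrained=True, order_index=len(kept)))
    return kept


def write_cutsets_tsv(cutsets, path: str) -> None:
    import pandas as pd

    pd.DataFrame([cs.to_dict() for cs in cutsets]).to_csv(path, sep="\t", index=False)


def write_cutsets_json(cutsets, path: str, metadata: dict | None = None) -> None:
    payload = {"metadata": metadata or {}, "cutsets": [cs.to_dict() for cs in cutsets]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_strategies_tsv(path: str) -> list[CutSet]:
    """Read the shared strategies schema back into :class:`CutSet` objects."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"reactions": str}, keep_default_na=False)
    out = []
    for k, row in df.iterrows():
        reactions = frozenset(r for r in str(row["reactions"]).split(";") if r)
        out.append(
            CutSet(
                reactions=reactions,
                minimal=bool(row.get("minimal", False)),
                constrained=bool(row.get("constrained", False)),
                formulation=str(row.get("formulation", "")),
                order_index=int(k),
            )
        )
    return out
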
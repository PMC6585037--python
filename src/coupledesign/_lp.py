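"""Thin LP layer over scipy's HiGHS backend.

All linear programs in the package go through :func:`solve_lp` so that
solver options and status mapping live in one place.  Mixed-integer
programs (cut-set enumeration) use :func:`scipy.optimize.milp` directly in
:mod:`coupledesign.mcs_enum`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

#: primal feasibility tolerance used when checking returned solutions
TOL_FEAS = 1e-9
#: relative tolerance when fixing an optimum in a follow-up LP
TOL_OPT = 1e-6
#: threshold below which a flux is considered inactive
TOL_ACT = 1e-6

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "error"}


@dataclass
class LPResult:
    """Outcome of a single LP solve."""

    status: str
    objective: float | None
    x: np.ndarray | None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def solve_lp(
    c: np.ndarray,
    *,
    A_eq: np.ndarray | None = None,
    b_eq: np.ndarray | None = None,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
    lb: np.ndarray | None = None,
    ub: np.ndarray | None = None,
    sense: str = "min",
) -> LPResult:
    """Solve ``min/max c.x  s.t.  A_eq.x = b_eq, A_ub.x <= b_ub, lb <= x <= ub``.

    Infeasible and unbounded problems are reported through ``status``;
    no exception is raised for them.
    """
    c = np.asarray(c, dtype=float)
    n = c.shape[0]
    if lb is None:
        lb = np.full(n, -np.inf)
    if ub is None:
        ub = np.full(n, np.inf)
    bounds = np.column_stack([lb, ub])
    sign = 1.0 if sense == "min" else -1.0
    res = linprog(
        sign * c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return LPResult(status=status, objective=None, x=None)
    return LPResult(status="optimal", objective=sign * res.fun, x=res.x)


def feasible(
    *,
    A_eq: np.ndarray | None = None,
    b_eq: np.ndarray | None = None,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
    lb: np.ndarray | None = None,
    ub: np.ndarray | None = None,
    n: int | None = None,
) -> bool:
    """LP feasibility check (zero objective)."""
    if n is None:
        for mat in (A_eq, A_ub):
            if mat is not None:
                n = np.asarray(mat).shape[1]
                break
        else:  # pragma: no cover - misuse guard
            raise ValueError("cannot infer problem size")
    res = solve_lp(np.zeros(n), A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, lb=lb, ub=ub)
    return res.optimal
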
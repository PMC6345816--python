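"""Thin binary-ILP backend on top of scipy's HiGHS MILP interface.

The contract is deliberately narrow — minimise a linear objective over 0/1
variables subject to "sum over a subset >= 1" covering rows and pinned
variables — because every exact computation in this package (single-layer
MDS, N-layer MDSM, reduced post-preprocessing ILP, canonicalising second
stage) is an instance of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = ["SolverError", "IlpSolution", "solve_binary_min"]

#: statuses surfaced to callers
OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
TIMEOUT = "timeout"


class SolverError(RuntimeError):
    """Solver finished without an optimal solution; carries the status."""

    def __init__(self, status: str, message: str = ""):
        super().__init__(f"ILP solver status={status}: {message}")
        self.status = status


@dataclass(frozen=True)
class IlpSolution:
    status: str
    objective: float
    assignment: np.ndarray  # 0/1 per variable


def solve_binary_min(
    n_vars: int,
    cover_rows: Sequence[Sequence[int]],
    objective: np.ndarray | None = None,
    forced_ones: Sequence[int] = (),
    equality: tuple[np.ndarray, float] | None = None,
    time_limit: float | None = 600.0,
) -> IlpSolution:
    """Minimise ``objective @ x`` over x in {0,1}^n.

    cover_rows: each row is the set of variable indices whose sum must be >= 1.
    forced_ones: variables pinned to 1.
    equality: optional (coefficients, value) row held to exact equality —
        used to pin the cardinality during the canonicalising second stage.
    """
    if objective is None:
        objective = np.ones(n_vars)
    objective = np.asarray(objective, dtype=float)

    lb = np.zeros(n_vars)
    for i in forced_ones:
        lb[i] = 1.0
    bounds = Bounds(lb, np.ones(n_vars))

    constraints = []
    if cover_rows:
        data, rows, cols = [], [], []
        for r, members in enumerate(cover_rows):
            for j in members:
                rows.append(r)
                cols.append(j)
                data.append(1.0)
        a = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(cover_rows), n_vars)
        )
        constraints.append(LinearConstraint(a, lb=np.ones(len(cover_rows)), ub=np.inf))
    if equality is not None:
        coeffs, value = equality
        constraints.append(LinearConstraint(np.asarray(coeffs, float)[None, :], lb=value, ub=value))

    options = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=objective,
        constraints=constraints,
        integrality=np.ones(n_vars),
        bounds=bounds,
        options=options,
    )
    # scipy/HiGHS status codes: 0 optimal, 1 iteration/time limit, 2 infeasible
    if res.status == 0:
        x = np.rint(res.x).astype(int)
        return IlpSolution(OPTIMAL, float(res.fun), x)
    if res.status == 1:
        raise SolverError(TIMEOUT, res.message)
    if res.status == 2:
        raise SolverError(INFEASIBLE, res.message)
    raise SolverError("failed", res.message)
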
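"""Thin wrapper around scipy's HiGHS mixed-integer solver.

All three optimization problems in this package (best-subset L1 regression,
single-module modularity maximization, and the combined model) are assembled
as sparse ``LinearConstraint`` systems and handed to the same backend, so
gap/tolerance handling lives in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

DEFAULT_GAP = 1e-6


class SolverError(RuntimeError):
    """Raised when the MILP backend fails to return a proven-optimal solution."""


@dataclass
class MilpSolution:
    x: np.ndarray
    objective: float
    gap: float | None


def solve_milp(
    c: np.ndarray,
    constraints: list[LinearConstraint],
    integrality: np.ndarray,
    bounds: Bounds,
    gap: float = DEFAULT_GAP,
    time_limit: float | None = None,
) -> MilpSolution:
    """Solve min c.x subject to the given constraints; raise on non-optimal status."""
    options: dict = {"mip_rel_gap": gap}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(
        c=c,
        constraints=constraints,
        integrality=integrality,
        bounds=bounds,
        options=options,
    )
    if res.status != 0 or res.x is None:
        raise SolverError(f"MILP did not solve to optimality: {res.message}")
    return MilpSolution(x=np.asarray(res.x), objective=float(res.fun), gap=res.mip_gap)


def stack_rows(rows: list[np.ndarray]) -> sparse.csr_matrix:
    """Stack dense row blocks into one sparse constraint matrix."""
    return sparse.csr_matrix(np.vstack(rows))
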
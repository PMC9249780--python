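"""Thin deterministic LP layer over scipy's HiGHS interface.

All flux-balance problems in the package reduce to
``optimize c.v  s.t.  S.v = 0, lb <= v <= ub`` (possibly with auxiliary
variables). HiGHS with fixed options is deterministic for a fixed problem,
which downstream reproducibility relies on.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from .errors import GemrankError, InfeasibleError, UnboundedError


def solve_lp(c: np.ndarray, A_eq: np.ndarray, lb: np.ndarray,
             ub: np.ndarray, sense: str = "max",
             ) -> tuple[np.ndarray, float]:
    """Optimize ``c.x`` subject to ``A_eq.x = 0`` and box bounds.

    Returns ``(x, objective)`` with the objective on the requested sense's
    scale. Raises :class:`InfeasibleError` / :class:`UnboundedError`.
    """
    c = np.asarray(c, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    bounds = list(zip(np.asarray(lb, float), np.asarray(ub, float)))
    b_eq = np.zeros(A_eq.shape[0]) if A_eq.size else None
    res = linprog(sign * c, A_eq=A_eq if A_eq.size else None, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status == 2:
        raise InfeasibleError("LP infeasible: no steady-state flux "
                              "distribution satisfies the bounds")
    if res.status == 3:
        raise UnboundedError("LP unbounded: objective reactions lack finite "
                             "bounds")
    if not res.success:
        raise GemrankError(f"LP solver failure: {res.message}")
    return res.x, float(sign * res.fun)


def flux_range(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, j: int,
               ) -> tuple[float, float]:
    """Flux variability of reaction ``j``: (min v_j, max v_j) at steady state."""
    c = np.zeros(S.shape[1])
    c[j] = 1.0
    _, vmin = solve_lp(c, S, lb, ub, sense="min")
    _, vmax = solve_lp(c, S, lb, ub, sense="max")
    return vmin, vmax
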
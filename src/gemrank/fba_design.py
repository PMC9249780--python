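"""Multi-objective FBA design: simplex lattice, scalarized solves, dedup,
and reaction essentiality.

Three metabolic objectives — biomass yield, ATP yield and PI4P
(1-phosphatidyl-1D-myo-inositol-4-phosphate) production — are combined by
the weighted global criterion: each weight vector of a simplex lattice
design {q, m} turns the multi-objective problem into a single weighted-sum
LP directly solvable by FBA. With {3, 4} this gives 15 scalarized tests; a
16th test minimizes the total flux (sum of |v_j|) with biomass anchored at
its single-objective optimum. Yields are read as reaction fluxes at fixed
uptake bounds, the standard FBA interpretation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from ._lp import solve_lp
from .config import AnalysisConfig
from .errors import InfeasibleError, ValidationError
from .model_core import MetabolicModel

logger = logging.getLogger(__name__)

MIN_TOTAL_FLUX_LABEL = "min_total_flux"


class ObjectiveWeights(NamedTuple):
    """Non-negative weights over (biomass, ATP, PI4P), summing to 1."""

    biomass: float
    atp: float
    pi4p: float


@dataclass
class FluxDistribution:
    """One FBA optimum, with the test label that produced it."""

    reaction_ids: list[str]
    v: np.ndarray
    objective_value: float
    test_label: str

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.shape != (len(self.reaction_ids),):
            raise ValidationError("one flux per reaction required")

    def flux(self, rid: str) -> float:
        return float(self.v[self.reaction_ids.index(rid)])


def simplex_lattice(q: int, m: int) -> list[tuple[float, ...]]:
    """All q-component weight vectors with entries in {0, 1/m, ..., 1}
    summing to 1, in deterministic lexicographically-descending order.

    The count is the stars-and-bars number C(q + m - 1, m).
    """
    if q < 2 or m < 1:
        raise ValidationError("simplex lattice requires q >= 2 and m >= 1")

    def compositions(parts: int, total: int):
        if parts == 1:
            yield (total,)
            return
        for first in range(total, -1, -1):
            for rest in compositions(parts - 1, total - first):
                yield (first,) + rest

    out = [tuple(i / m for i in comp) for comp in compositions(q, m)]
    assert len(out) == math.comb(q + m - 1, m)
    return out


def weight_label(w: Sequence[float]) -> str:
    return "w_" + "_".join(f"{x:.2f}" for x in w)


# ---------------------------------------------------------------------------
# oxygen bound
# ---------------------------------------------------------------------------

def apply_oxygen_cap(model: MetabolicModel, cfg: AnalysisConfig,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Bounds with the oxygen uptake rate capped at ``cfg.oxygen_ub``.

    Uptake means flux of oxygen *into* the network. The sign carrying
    uptake is auto-detected from the exchange column's stoichiometry: a
    column that only produces the metabolite imports on positive flux (cap
    the upper bound); a column that only consumes it imports on negative
    flux (cap the lower bound at -oxygen_ub). Models without an
    ``oxygen_uptake`` tag are returned unchanged.
    """
    lb = model.lower_bound.copy()
    ub = model.upper_bound.copy()
    rid = model.objective_tags.get("oxygen_uptake")
    if rid is None:
        logger.info("no oxygen_uptake tag; oxygen cap not applied")
        return lb, ub
    j = model.reaction_index(rid)
    col = model.S[:, j]
    if np.all(col >= 0) and np.any(col > 0):
        ub[j] = min(ub[j], cfg.oxygen_ub)
        logger.info("oxygen cap: %s import-positive, ub=%g", rid, ub[j])
    elif np.all(col <= 0) and np.any(col < 0):
        lb[j] = max(lb[j], -cfg.oxygen_ub)
        logger.info("oxygen cap: %s export-positive, lb=%g", rid, lb[j])
    else:
        ub[j] = min(ub[j], cfg.oxygen_ub)
        logger.warning("oxygen exchange %s has mixed stoichiometry; capping "
                       "positive direction", rid)
    return lb, ub


# ---------------------------------------------------------------------------
# scalarized FBA
# ---------------------------------------------------------------------------

def _objective_vector(model: MetabolicModel, w: Sequence[float]) -> np.ndarray:
    if len(w) != 3:
        raise ValidationError("expected 3 objective weights (biomass, atp, pi4p)")
    c = np.zeros(model.n_reactions)
    for weight, role in zip(w, ("biomass", "atp", "pi4p")):
        c[model.reaction_index(model.tagged_reaction(role))] += weight
    return c


def solve_weighted_fba(model: MetabolicModel, w: Sequence[float],
                       cfg: AnalysisConfig | None = None,
                       label: str | None = None) -> FluxDistribution:
    """Maximize ``w . (v_biomass, v_atp, v_pi4p)`` at steady state.

    The oxygen uptake cap is applied before solving. The attained optimum
    is returned in ``objective_value``.
    """
    cfg = cfg or AnalysisConfig()
    c = _objective_vector(model, w)
    lb, ub = apply_oxygen_cap(model, cfg)
    v, obj = solve_lp(c, model.S, lb, ub, sense="max")
    return FluxDistribution(list(model.reaction_ids), v, obj,
                            label or weight_label(w))


def solve_min_total_flux(model: MetabolicModel,
                         cfg: AnalysisConfig | None = None) -> FluxDistribution:
    """Minimize total flux sum_j |v_j| with biomass fixed at its optimum.

    Absolute values are handled by auxiliary variables ``t_j >= |v_j|``.
    By default the biomass flux is anchored at its single-objective maximum
    (parsimonious-FBA convention); without the anchor the trivial all-zero
    solution is optimal whenever feasible, so the unanchored mode exists
    only as an explicitly flagged degenerate alternative.
    """
    cfg = cfg or AnalysisConfig()
    lb, ub = apply_oxygen_cap(model, cfg)
    n = model.n_reactions
    if cfg.min_flux_anchor_biomass:
        j_bio = model.reaction_index(model.tagged_reaction("biomass"))
        c = np.zeros(n)
        c[j_bio] = 1.0
        _, biomass_opt = solve_lp(c, model.S, lb, ub, sense="max")
        eps = max(cfg.flux_tol, abs(biomass_opt) * 1e-9)
        lb = lb.copy()
        ub = ub.copy()
        lb[j_bio] = biomass_opt - eps
        ub[j_bio] = min(ub[j_bio], biomass_opt + eps)
    else:
        logger.warning("min_total_flux without biomass anchor is degenerate")
    # variables [v, t]; constraints S.v = 0 plus t_j >= |v_j| via
    # v_j - t_j <= 0 and -v_j - t_j <= 0, encoded as bounded slack rows.
    from scipy.optimize import linprog

    t_ub = np.maximum(np.abs(lb), np.abs(ub))
    A_eq = np.hstack([model.S, np.zeros((model.n_metabolites, n))])
    A_ub = np.block([[np.eye(n), -np.eye(n)], [-np.eye(n), -np.eye(n)]])
    b_ub = np.zeros(2 * n)
    c_full = np.concatenate([np.zeros(n), np.ones(n)])
    bounds = list(zip(lb, ub)) + list(zip(np.zeros(n), t_ub))
    res = linprog(c_full, A_eq=A_eq, b_eq=np.zeros(model.n_metabolites),
                  A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if res.status == 2:
        raise InfeasibleError("min-total-flux LP infeasible under the "
                              "biomass anchor")
    if not res.success:
        from .errors import GemrankError

        raise GemrankError(f"LP solver failure: {res.message}")
    v = res.x[:n]
    return FluxDistribution(list(model.reaction_ids), v, float(res.fun),
                            MIN_TOTAL_FLUX_LABEL)


def run_design(model: MetabolicModel, cfg: AnalysisConfig | None = None,
               ) -> list[FluxDistribution]:
    """Solve all lattice-weighted FBA tests plus the min-total-flux test.

    With the default {3, 4} lattice this yields 16 labeled flux
    distributions, in deterministic order.
    """
    cfg = cfg or AnalysisConfig()
    lattice = simplex_lattice(cfg.lattice_q, cfg.lattice_m)
    solutions = [solve_weighted_fba(model, w, cfg) for w in lattice]
    solutions.append(solve_min_total_flux(model, cfg))
    logger.info("design: %d tests solved on %s", len(solutions), model.id)
    return solutions


def deduplicate_solutions(solutions: Sequence[FluxDistribution],
                          dedup_tol: float = 1e-6) -> list[FluxDistribution]:
    """Greedy de-duplication in input order under the L-infinity norm.

    A solution is redundant if its flux vector is within ``dedup_tol`` of
    an already-kept one.
    """
    kept: list[FluxDistribution] = []
    for sol in solutions:
        if kept and sol.reaction_ids != kept[0].reaction_ids:
            raise ValidationError("solutions cover different reaction sets")
        if any(np.max(np.abs(sol.v - k.v)) <= dedup_tol for k in kept):
            continue
        kept.append(sol)
    logger.info("dedup: %d of %d solutions are non-redundant",
                len(kept), len(solutions))
    return kept


def essential_reactions(model: MetabolicModel,
                        cfg: AnalysisConfig | None = None) -> set[str]:
    """Reactions whose knockout drops the biomass optimum by >= the
    configured fraction (5% by default).

    Each reaction is individually constrained to zero flux and biomass is
    re-maximized; an infeasible knockout counts as zero biomass.
    """
    cfg = cfg or AnalysisConfig()
    lb, ub = apply_oxygen_cap(model, cfg)
    j_bio = model.reaction_index(model.tagged_reaction("biomass"))
    c = np.zeros(model.n_reactions)
    c[j_bio] = 1.0
    _, baseline = solve_lp(c, model.S, lb, ub, sense="max")
    if baseline <= cfg.flux_tol:
        raise ValidationError("baseline biomass optimum is zero; "
                              "essentiality is undefined")
    essential: set[str] = set()
    for j, rid in enumerate(model.reaction_ids):
        lbj, ubj = lb[j], ub[j]
        lb[j] = ub[j] = 0.0
        try:
            _, ko = solve_lp(c, model.S, lb, ub, sense="max")
        except InfeasibleError:
            ko = 0.0
        finally:
            lb[j], ub[j] = lbj, ubj
        if (baseline - ko) / baseline >= cfg.essentiality_drop:
            essential.add(rid)
    return essential
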
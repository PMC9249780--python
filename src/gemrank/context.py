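"""Flux-consistent subnetwork extraction and medoid contextualization.

A reaction is flux-consistent when some feasible steady-state flux
distribution carries |v| >= tol through it. Blocked reactions carry zero
flux in every feasible solution, so removing them leaves the flux space of
the remaining reactions unchanged; the maximal consistent subnetwork is
therefore unique and found by a single pass of per-reaction flux
variability analysis (FVA).

Contextualization turns the consistent generic model into a
medoid-specific one: reactions whose GPR evaluates to inactive under the
medoid's binary activity signature are removed (empty-GPR reactions are
always kept), and the consistent subnetwork is re-extracted so that every
surviving reaction can still carry flux. This is a deliberately contracted
extraction — it does not re-fit expression evidence the way weighted
core/non-core methods do, but preserves the medoid -> consistent
condition-specific model contract with fully checkable semantics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from ._lp import flux_range
from .config import AnalysisConfig
from .errors import InfeasibleError
from .expression import BinaryActivitySignature
from .model_core import MetabolicModel

logger = logging.getLogger(__name__)


@dataclass
class RemovalLog:
    """Provenance of reactions removed during contextualization."""

    gpr_inactive: list[str] = field(default_factory=list)
    inconsistent: list[str] = field(default_factory=list)

    def as_records(self) -> list[dict[str, str]]:
        return ([{"reaction": r, "reason": "gpr_inactive"}
                 for r in self.gpr_inactive]
                + [{"reaction": r, "reason": "inconsistent"}
                   for r in self.inconsistent])


def flux_consistent_reactions(model: MetabolicModel, tol: float = 1e-6,
                              ) -> list[str]:
    """Ids of reactions that can carry |flux| >= tol at steady state."""
    consistent = []
    for j, rid in enumerate(model.reaction_ids):
        try:
            vmin, vmax = flux_range(model.S, model.lower_bound,
                                    model.upper_bound, j)
        except InfeasibleError:
            warnings.warn("model admits no steady-state solution; "
                          "returning empty reaction set", stacklevel=2)
            return []
        if vmax >= tol or vmin <= -tol:
            consistent.append(rid)
    return consistent


def find_flux_consistent_subnetwork(model: MetabolicModel,
                                    tol: float = 1e-6) -> MetabolicModel:
    """Maximal submodel in which every reaction is flux-consistent.

    Metabolites left with all-zero stoichiometric rows are dropped.
    Idempotent: re-applying to the result changes nothing.
    """
    keep = flux_consistent_reactions(model, tol)
    removed = set(model.reaction_ids) - set(keep)
    if removed:
        logger.info("consistency: removed %d blocked reactions", len(removed))
    return model.subset(keep)


def contextualize(consistent_model: MetabolicModel,
                  medoid: BinaryActivitySignature,
                  tol: float = 1e-6,
                  cfg: AnalysisConfig | None = None,
                  ) -> tuple[MetabolicModel, RemovalLog]:
    """Medoid-specific consistent model plus a removal provenance log.

    Reactions with a GPR evaluating to 0 under the medoid are removed
    (reactions with an empty GPR are kept); the flux-consistent subnetwork
    of the pruned model is then extracted, which may cascade removals to
    core reactions left without a feasible route. A biomass tag rendered
    inconsistent triggers a warning and the model is still returned.
    """
    cfg = cfg or AnalysisConfig()
    states = medoid.as_dict()
    log = RemovalLog()
    keep = []
    for j, rid in enumerate(consistent_model.reaction_ids):
        expr = consistent_model.gpr(j)
        if expr.is_always_active:
            keep.append(rid)
            continue
        active = expr.evaluate(states, missing=cfg.missing_gene_policy)
        if active:
            keep.append(rid)
        else:
            log.gpr_inactive.append(rid)
    pruned = consistent_model.subset(keep)
    contextual = find_flux_consistent_subnetwork(pruned, tol)
    log.inconsistent = [r for r in pruned.reaction_ids
                        if r not in set(contextual.reaction_ids)]
    biomass = consistent_model.objective_tags.get("biomass")
    if biomass is not None and biomass not in contextual.reaction_ids:
        warnings.warn(
            f"biomass reaction {biomass!r} is not flux-consistent in the "
            "contextualized model; growth objectives are unusable",
            stacklevel=2)
    logger.info("contextualize[%s]: %d -> %d reactions "
                "(%d gpr-inactive, %d inconsistent)", medoid.label,
                consistent_model.n_reactions, contextual.n_reactions,
                len(log.gpr_inactive), len(log.inconsistent))
    return contextual, log
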
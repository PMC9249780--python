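"""End-to-end orchestration: expression -> medoids -> contextualized models
-> multi-objective FBA -> topology -> gene and chemical ranking.

This is the library-level driver behind the CLI ``all`` subcommand and the
natural entry point for programmatic use. Each stage's intermediate
results are kept on the returned :class:`PipelineResult` so callers can
inspect or export any of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import AnalysisConfig
from .context import RemovalLog, contextualize, find_flux_consistent_subnetwork
from .expression import (BinaryActivitySignature, ExpressionMatrix, binarize,
                         flag_upregulated, pam_cluster, select_k_silhouette)
from .fba_design import (FluxDistribution, deduplicate_solutions,
                         essential_reactions, run_design)
from .model_core import MetabolicModel
from .prioritize import (DrugScore, GeneScore, ReactionScore, combine_medoids,
                         drug_relevance, gene_scores, reactions_of_interest,
                         score_reactions)
from .topology import (ChokePointClassification, build_reaction_graph,
                       classify_choke_points, pagerank, reduce_network)

logger = logging.getLogger(__name__)


@dataclass
class MedoidResult:
    """Per-medoid intermediate results."""

    medoid: BinaryActivitySignature
    model: MetabolicModel
    removal_log: RemovalLog
    solutions: list[FluxDistribution]
    nonredundant: list[FluxDistribution]
    classifications: list[ChokePointClassification]
    centralities: list[dict[str, float]]
    scores: list[ReactionScore]
    essential: set[str]


@dataclass
class PipelineResult:
    config: AnalysisConfig
    signatures: list[BinaryActivitySignature]
    k: int
    assignments: list[int]
    consistent_model: MetabolicModel
    medoid_results: list[MedoidResult] = field(default_factory=list)
    combined_scores: list[ReactionScore] = field(default_factory=list)
    essential_union: set[str] = field(default_factory=set)
    upregulated: set[str] = field(default_factory=set)
    roi: set[str] = field(default_factory=set)
    genes: list[GeneScore] = field(default_factory=list)
    drugs: list[DrugScore] = field(default_factory=list)


def analyze_medoid(consistent_model: MetabolicModel,
                   medoid: BinaryActivitySignature,
                   cfg: AnalysisConfig) -> MedoidResult:
    """Contextualize one medoid and run the full FBA/topology battery."""
    model, removal_log = contextualize(consistent_model, medoid,
                                       tol=cfg.flux_tol, cfg=cfg)
    solutions = run_design(model, cfg)
    nonredundant = deduplicate_solutions(solutions, cfg.dedup_tol)
    classifications, centralities = [], []
    for sol in nonredundant:
        net = reduce_network(model, sol, cfg.flux_tol)
        classifications.append(
            classify_choke_points(net, extended_mode=cfg.extended_mode))
        graph = build_reaction_graph(net)
        centralities.append(pagerank(graph, cfg.damping))
    scores = score_reactions(classifications, centralities, cfg)
    essential = essential_reactions(model, cfg)
    return MedoidResult(medoid, model, removal_log, solutions, nonredundant,
                        classifications, centralities, scores, essential)


def run_pipeline(model: MetabolicModel,
                 expression: ExpressionMatrix,
                 differential: pd.DataFrame,
                 interactions: pd.DataFrame | None = None,
                 cfg: AnalysisConfig | None = None,
                 seed: int = 0,
                 k: int | None = None,
                 k_range: tuple[int, ...] = (2, 3, 4, 5)) -> PipelineResult:
    """Run the whole workflow and return every stage's results.

    ``k`` fixes the number of expression clusters; when None it is chosen
    by mean silhouette width over ``k_range`` (clipped to the feasible
    range for the cohort size).
    """
    cfg = cfg or AnalysisConfig()
    tumor = expression.restrict("tumor")
    signatures = binarize(tumor, cfg)
    n = len(signatures)
    if k is None:
        ks = [x for x in k_range if 2 <= x <= n - 1]
        k = select_k_silhouette(signatures, ks, seed=seed)
    assignments, medoids = pam_cluster(signatures, k, seed=seed)
    logger.info("clustering: k=%d over %d tumor samples", k, n)

    consistent = find_flux_consistent_subnetwork(model, cfg.flux_tol)
    result = PipelineResult(
        config=cfg,
        signatures=signatures,
        k=k,
        assignments=[int(a) for a in assignments],
        consistent_model=consistent,
    )
    for medoid in medoids:
        result.medoid_results.append(analyze_medoid(consistent, medoid, cfg))

    result.combined_scores = combine_medoids(
        *[m.scores for m in result.medoid_results])
    result.essential_union = set().union(
        *[m.essential for m in result.medoid_results])
    result.upregulated = flag_upregulated(differential, cfg)

    gprs: dict = {}
    for m in result.medoid_results:
        gprs.update(m.model.gprs())
    result.roi = reactions_of_interest(result.combined_scores,
                                       result.essential_union,
                                       result.upregulated, gprs)
    result.genes = gene_scores(result.roi, result.combined_scores, gprs)
    if interactions is not None and not interactions.empty:
        result.drugs = drug_relevance(interactions, result.genes)
    return result
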
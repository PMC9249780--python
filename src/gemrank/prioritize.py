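"""Occurrence/centrality scoring and gene/chemical ranking.

Per contextualized model, each reaction accumulates two scores across the
non-redundant FBA optima: *occurrence* — in how many optima it is an
extended choke point — and *centrality* — the sum of its PageRank scores.
A reaction is occurrence-selected when it is an extended choke point in at
least the configured fraction of optima ("at least half"), and
topology-selected when its summed centrality lies in the configured top
fraction of ranked reactions ("top 10%", ties at the cutoff included).
Scores from the medoid models are combined by summation. Reactions of
interest are the essential, upregulated-gene-associated reactions that are
additionally occurrence- and/or topology-selected; gene scores are
max-normalized sums over a gene's reactions of interest, and a chemical's
relevance is the sum of its distinct target genes' scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import AnalysisConfig
from .errors import ValidationError
from .gpr import GprExpression
from .topology import LABEL_EXTENDED, ChokePointClassification

logger = logging.getLogger(__name__)

INTERACTION_TYPES = ("direct", "expression_increase", "expression_decrease",
                     "predicted")


@dataclass
class ReactionScore:
    reaction_id: str
    occurrence: int
    centrality: float
    is_occurrence_selected: bool = False
    is_topology_selected: bool = False

    def __post_init__(self) -> None:
        if self.occurrence < 0 or self.centrality < 0:
            raise ValidationError("scores must be non-negative")


@dataclass
class GeneScore:
    gene_id: str
    occurrence_raw: float
    centrality_raw: float
    occurrence_norm: float
    centrality_norm: float

    @property
    def relevance(self) -> float:
        return self.occurrence_norm + self.centrality_norm


@dataclass
class DrugScore:
    chemical_id: str
    relevance: float
    n_genes: int
    genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reaction scoring
# ---------------------------------------------------------------------------

def score_reactions(classifications: Sequence[ChokePointClassification],
                    centralities: Sequence[Mapping[str, float]],
                    cfg: AnalysisConfig | None = None,
                    ) -> list[ReactionScore]:
    """Score reactions over one medoid model's non-redundant optima.

    ``classifications[i]`` and ``centralities[i]`` must describe the same
    optimum. Reactions inactive in an optimum contribute 0 there. The
    occurrence cutoff is ``ceil(occurrence_fraction * n_solutions)`` and
    the centrality cutoff keeps the top
    ``floor(centrality_top_fraction * n_ranked)`` reactions, with ties at
    the cutoff value included.
    """
    cfg = cfg or AnalysisConfig()
    if len(classifications) != len(centralities):
        raise ValidationError("classification and centrality lists must "
                              "index the same solutions")
    n_solutions = len(classifications)
    if n_solutions == 0:
        raise ValidationError("no non-redundant solutions to score")
    reactions: set[str] = set()
    for cls, cen in zip(classifications, centralities):
        reactions |= set(cls.labels)
        reactions |= set(cen)
    occurrence = {r: 0 for r in reactions}
    centrality = {r: 0.0 for r in reactions}
    for cls, cen in zip(classifications, centralities):
        for r in cls.reactions_with_label(LABEL_EXTENDED):
            occurrence[r] += 1
        for r, s in cen.items():
            centrality[r] += float(s)

    occ_cut = math.ceil(cfg.occurrence_fraction * n_solutions)
    ranked = sorted(reactions, key=lambda r: (-centrality[r], r))
    k = math.floor(cfg.centrality_top_fraction * len(ranked))
    if k >= 1:
        threshold = centrality[ranked[k - 1]]
        topo = {r for r in reactions if centrality[r] >= threshold}
    else:
        topo = set()
    return [
        ReactionScore(r, occurrence[r], centrality[r],
                      is_occurrence_selected=occurrence[r] >= occ_cut,
                      is_topology_selected=r in topo)
        for r in sorted(reactions)
    ]


def combine_medoids(*score_lists: Sequence[ReactionScore],
                    ) -> list[ReactionScore]:
    """Combine per-medoid reaction scores by summation over the union.

    A reaction absent from a medoid's model contributes 0 there; selection
    flags are OR-ed across medoids.
    """
    combined: dict[str, ReactionScore] = {}
    for scores in score_lists:
        for s in scores:
            if s.reaction_id not in combined:
                combined[s.reaction_id] = ReactionScore(
                    s.reaction_id, s.occurrence, s.centrality,
                    s.is_occurrence_selected, s.is_topology_selected)
            else:
                c = combined[s.reaction_id]
                c.occurrence += s.occurrence
                c.centrality += s.centrality
                c.is_occurrence_selected |= s.is_occurrence_selected
                c.is_topology_selected |= s.is_topology_selected
    return [combined[r] for r in sorted(combined)]


def reactions_of_interest(combined: Sequence[ReactionScore],
                          essential: set[str],
                          upregulated_genes: set[str],
                          gprs: Mapping[str, GprExpression]) -> set[str]:
    """Venn intersection defining candidate target reactions.

    A reaction qualifies when it is essential AND its GPR references at
    least one tumor-upregulated gene AND it is occurrence-selected and/or
    topology-selected.
    """
    out = set()
    for s in combined:
        if s.reaction_id not in essential:
            continue
        expr = gprs.get(s.reaction_id)
        if expr is None or not (expr.genes() & upregulated_genes):
            continue
        if s.is_occurrence_selected or s.is_topology_selected:
            out.add(s.reaction_id)
    return out


# ---------------------------------------------------------------------------
# gene and chemical ranking
# ---------------------------------------------------------------------------

def gene_scores(roi: Iterable[str],
                combined: Sequence[ReactionScore],
                gprs: Mapping[str, GprExpression]) -> list[GeneScore]:
    """Per-gene scores over the reactions of interest.

    Raw gene occurrence (centrality) is the sum over reactions of interest
    whose GPR references the gene; each component is then divided by its
    maximum across genes (max-normalization, with an all-zero column
    normalizing to zero). Relevance is the sum of the two normalized
    components, so it lies in [0, 2]. The raw sums are kept alongside.
    """
    roi = set(roi)
    by_id = {s.reaction_id: s for s in combined}
    raw_occ: dict[str, float] = {}
    raw_cen: dict[str, float] = {}
    for rid in sorted(roi):
        if rid not in by_id:
            raise ValidationError(f"reaction of interest {rid!r} has no score")
        if rid not in gprs:
            raise ValidationError(f"reaction {rid!r} has no GPR")
        for g in gprs[rid].genes():
            raw_occ[g] = raw_occ.get(g, 0.0) + by_id[rid].occurrence
            raw_cen[g] = raw_cen.get(g, 0.0) + by_id[rid].centrality
    if not raw_occ:
        import warnings

        warnings.warn("no reactions of interest; gene ranking is empty",
                      stacklevel=2)
        return []
    max_occ = max(raw_occ.values())
    max_cen = max(raw_cen.values())
    out = [
        GeneScore(
            gene_id=g,
            occurrence_raw=raw_occ[g],
            centrality_raw=raw_cen[g],
            occurrence_norm=raw_occ[g] / max_occ if max_occ > 0 else 0.0,
            centrality_norm=raw_cen[g] / max_cen if max_cen > 0 else 0.0,
        )
        for g in sorted(raw_occ)
    ]
    out.sort(key=lambda s: (-s.relevance, s.gene_id))
    return out


def read_interactions_tsv(path: str | Path) -> pd.DataFrame:
    """Read a chemical-gene interaction snapshot TSV.

    Expected columns: chemical, gene, interaction_type, source (the
    documented mapping for DGIdb/CTD-style exports).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return validate_interactions(df)


def validate_interactions(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("chemical", "gene"):
        if col not in df.columns:
            raise ValidationError(f"interaction table missing column {col!r}")
    if "interaction_type" not in df.columns:
        df = df.assign(interaction_type="direct")
    if "source" not in df.columns:
        df = df.assign(source="")
    if (df["gene"].astype(str) == "").any():
        raise ValidationError("interaction table has empty gene ids")
    bad = set(df["interaction_type"]) - set(INTERACTION_TYPES)
    if bad:
        raise ValidationError(f"unknown interaction types: {sorted(bad)}")
    dups = df.duplicated(subset=["chemical", "gene", "interaction_type",
                                 "source"])
    if dups.any():
        raise ValidationError("duplicate interaction rows")
    return df


def drug_relevance(interactions: pd.DataFrame,
                   genes: Sequence[GeneScore]) -> list[DrugScore]:
    """Rank chemicals by the summed relevance of their distinct target genes.

    Gene ids are matched case-sensitively; rows whose gene has no score are
    dropped (count logged). Interaction direction is reporting metadata and
    does not weight the score. Output is sorted by descending relevance,
    ties broken alphabetically by chemical id.
    """
    interactions = validate_interactions(interactions)
    score_by_gene = {g.gene_id: g.relevance for g in genes}
    pairs = interactions[["chemical", "gene"]].drop_duplicates()
    matched = pairs[pairs["gene"].isin(score_by_gene)]
    n_dropped = len(pairs) - len(matched)
    if n_dropped:
        logger.info("drug ranking: dropped %d interaction pairs with "
                    "unscored genes", n_dropped)
    out = []
    for chem, grp in matched.groupby("chemical", sort=True):
        gene_list = sorted(set(grp["gene"]))
        out.append(DrugScore(
            chemical_id=str(chem),
            relevance=float(sum(score_by_gene[g] for g in gene_list)),
            n_genes=len(gene_list),
            genes=gene_list,
        ))
    out.sort(key=lambda d: (-d.relevance, d.chemical_id))
    return out


# ---------------------------------------------------------------------------
# tabular exports
# ---------------------------------------------------------------------------

def reaction_scores_frame(scores: Sequence[ReactionScore]) -> pd.DataFrame:
    return pd.DataFrame([{
        "reaction_id": s.reaction_id,
        "occurrence": s.occurrence,
        "centrality": s.centrality,
        "is_occurrence_selected": s.is_occurrence_selected,
        "is_topology_selected": s.is_topology_selected,
    } for s in scores])


def gene_scores_frame(genes: Sequence[GeneScore]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": g.gene_id,
        "occurrence_raw": g.occurrence_raw,
        "centrality_raw": g.centrality_raw,
        "occurrence_norm": g.occurrence_norm,
        "centrality_norm": g.centrality_norm,
        "relevance": g.relevance,
    } for g in genes])


def drug_ranking_frame(drugs: Sequence[DrugScore]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chemical": d.chemical_id,
        "relevance": d.relevance,
        "n_genes": d.n_genes,
        "genes": ";".join(d.genes),
    } for d in drugs])
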
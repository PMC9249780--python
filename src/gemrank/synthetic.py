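"""Synthetic fixtures with known ground truth.

Generates toy stoichiometric models with planted choke-point motifs and
essentiality structure, a matched two-cluster tumor/normal expression
dataset with planted upregulated genes, and a small chemical-gene
interaction table — everything the full pipeline consumes, at a scale
where every stage can be checked against brute force.

The toy model is assembled from independent "units", each fed by its own
exchange reaction and ending in a terminal metabolite consumed by the
biomass sink, so the maximum-biomass flux distribution activates every
unit in its designed forward direction:

* linear chains — every interior reaction is an extended choke point and
  every main-path reaction is essential;
* one motif block per planted choke-point class (none, single consuming,
  single producing, double, extended), using fixed-bound feeder reactions
  to force the side branches that destroy or preserve exclusivity;
* redundant parallel pairs — two interchangeable routes to the terminal
  metabolite, so neither is essential;
* an ATP unit consumed by biomass plus a PI4P branch, giving the three
  tagged FBA objectives, and an oxygen exchange consumed by biomass so
  the uptake cap is well-defined.

Ground truth for choke-point classes refers to the designed forward flux
direction; recovery tests should first confirm the FBA optimum realizes
that direction (alternate-optima guard).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression import BinaryActivitySignature, ExpressionMatrix
from .model_core import MetabolicModel
from .topology import (LABEL_DOUBLE, LABEL_EXTENDED, LABEL_NONE,
                       LABEL_SINGLE_CONSUMING, LABEL_SINGLE_PRODUCING)

_MAIN_UB = 10.0
_BIOMASS_UB = 1.0
_FORCED_SIDE = 0.3  # fixed feeder flux forcing side branches active


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study conditions.

    Defaults emulate a small two-cluster tumor cohort with a normal
    reference: 20 tumor and 10 normal samples and planted upregulation of
    2 log2 units on the target genes. The default is noise-free: the
    per-gene mean threshold of the binarization marks below-average
    samples inactive, so any per-entry noise on an always-active gene
    flips about half of its activity calls — planted all-active profiles
    are exactly recoverable only at sigma 0. The multiplicative
    log-normal noise dial exists for robustness experiments.
    """

    n_linear_chains: int = 2
    n_parallel_motifs: int = 1
    motif_none: int = 1
    motif_single_consuming: int = 1
    motif_single_producing: int = 1
    motif_double: int = 1
    motif_extended: int = 1
    n_extra_genes: int = 4
    n_tumor_samples: int = 20
    n_normal_samples: int = 10
    effect_size: float = 2.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_linear_chains, self.n_parallel_motifs,
                  self.motif_none, self.motif_single_consuming,
                  self.motif_single_producing, self.motif_double,
                  self.motif_extended, self.n_extra_genes)
        if any(c < 0 for c in counts):
            raise ValidationError("fixture counts must be >= 0")
        if self.n_tumor_samples < 4 or self.n_normal_samples < 2:
            raise ValidationError("need >= 4 tumor and >= 2 normal samples")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


@dataclass
class ModelTruth:
    """Planted per-reaction labels of the toy model."""

    chokepoint_class: dict[str, str] = field(default_factory=dict)
    essential: set[str] = field(default_factory=set)
    non_essential: set[str] = field(default_factory=set)
    target_reactions: set[str] = field(default_factory=set)
    gene_to_reactions: dict[str, list[str]] = field(default_factory=dict)
    target_genes: set[str] = field(default_factory=set)
    marker_genes: set[str] = field(default_factory=set)
    blocked: set[str] = field(default_factory=set)


@dataclass
class ExpressionTruth:
    """Planted structure of the synthetic expression dataset."""

    profiles: list[BinaryActivitySignature]
    assignments: dict[str, int]
    upregulated: set[str]
    target_genes: set[str]


class _NetworkBuilder:
    def __init__(self) -> None:
        self.metabolites: list[str] = []
        self._met_seen: set[str] = set()
        self.reactions: list[tuple[str, dict[str, float], float, float]] = []
        self.biomass_inputs: dict[str, float] = {}

    def met(self, mid: str) -> str:
        if mid not in self._met_seen:
            self._met_seen.add(mid)
            self.metabolites.append(mid)
        return mid

    def rxn(self, rid: str, coeffs: dict[str, float], lb: float = 0.0,
            ub: float = _MAIN_UB) -> str:
        for m in coeffs:
            self.met(m)
        self.reactions.append((rid, dict(coeffs), lb, ub))
        return rid

    def feed_biomass(self, mid: str, coef: float = 1.0) -> None:
        self.met(mid)
        self.biomass_inputs[mid] = self.biomass_inputs.get(mid, 0.0) + coef


def _build_units(spec: FixtureSpec, b: _NetworkBuilder, truth: ModelTruth,
                 ) -> list[str]:
    """Add all units; returns reaction ids needing a GPR, in order."""
    gpr_rxns: list[str] = []

    def main(rid: str, coeffs: dict[str, float], lb: float = 0.0,
             ub: float = _MAIN_UB, gene: bool = True) -> str:
        b.rxn(rid, coeffs, lb, ub)
        if gene:
            gpr_rxns.append(rid)
        return rid

    for i in range(spec.n_linear_chains):
        u = f"ch{i}"
        main(f"EX_{u}", {f"{u}_A": 1.0}, gene=False)
        c1 = main(f"{u}_r1", {f"{u}_A": -1.0, f"{u}_B": 1.0})
        c2 = main(f"{u}_r2", {f"{u}_B": -1.0, f"{u}_T": 1.0})
        b.feed_biomass(f"{u}_T")
        truth.chokepoint_class[c1] = LABEL_EXTENDED
        truth.chokepoint_class[c2] = LABEL_EXTENDED
        truth.essential |= {f"EX_{u}", c1, c2}
        truth.target_reactions |= {c1, c2}

    for i in range(spec.motif_none):
        u = f"mn{i}"
        main(f"EX_{u}", {f"{u}_L": 1.0}, gene=False)
        t = main(f"{u}_t", {f"{u}_L": -1.0, f"{u}_R": 1.0})
        c2 = main(f"{u}_c2", {f"{u}_L": -1.0, f"{u}_W": 1.0})
        b.rxn(f"{u}_p2", {f"{u}_R": 1.0}, lb=_FORCED_SIDE, ub=_FORCED_SIDE)
        d = main(f"{u}_d", {f"{u}_R": -1.0, f"{u}_T": 1.0})
        b.feed_biomass(f"{u}_T")
        b.feed_biomass(f"{u}_W")
        truth.chokepoint_class[t] = LABEL_NONE
        truth.essential |= {f"EX_{u}", t, c2, d}
        truth.non_essential.add(f"{u}_p2")

    for i in range(spec.motif_single_consuming):
        u = f"mc{i}"
        main(f"EX_{u}", {f"{u}_M": 1.0}, gene=False)
        t = main(f"{u}_t", {f"{u}_M": -1.0, f"{u}_R": 1.0})
        b.rxn(f"{u}_p2", {f"{u}_R": 1.0}, lb=_FORCED_SIDE, ub=_FORCED_SIDE)
        d = main(f"{u}_d", {f"{u}_R": -1.0, f"{u}_T": 1.0})
        b.feed_biomass(f"{u}_T")
        truth.chokepoint_class[t] = LABEL_SINGLE_CONSUMING
        truth.essential |= {f"EX_{u}", t, d}
        truth.non_essential.add(f"{u}_p2")

    for i in range(spec.motif_single_producing):
        u = f"mp{i}"
        main(f"EX_{u}", {f"{u}_L": 1.0}, gene=False)
        t = main(f"{u}_t", {f"{u}_L": -1.0, f"{u}_M": 1.0})
        c2 = main(f"{u}_c2", {f"{u}_L": -1.0, f"{u}_W": 1.0})
        d = main(f"{u}_d", {f"{u}_M": -1.0, f"{u}_T": 1.0})
        b.feed_biomass(f"{u}_T")
        b.feed_biomass(f"{u}_W")
        truth.chokepoint_class[t] = LABEL_SINGLE_PRODUCING
        truth.essential |= {f"EX_{u}", t, c2, d}

    for i in range(spec.motif_double):
        u = f"md{i}"
        b.rxn(f"{u}_pa", {f"{u}_m1": 1.0}, lb=0.0, ub=2 * _FORCED_SIDE)
        b.rxn(f"{u}_pb", {f"{u}_m1": 1.0}, lb=2 * _FORCED_SIDE,
              ub=2 * _FORCED_SIDE)
        t = main(f"{u}_t", {f"{u}_m1": -1.0, f"{u}_m2": 1.0})
        d = main(f"{u}_d", {f"{u}_m2": -1.0, f"{u}_T": 1.0})
        b.feed_biomass(f"{u}_T")
        truth.chokepoint_class[t] = LABEL_DOUBLE
        truth.essential |= {t, d}

    for i in range(spec.motif_extended):
        u = f"mx{i}"
        main(f"EX_{u}", {f"{u}_A": 1.0}, gene=False)
        t = main(f"{u}_t", {f"{u}_A": -1.0, f"{u}_B": 1.0})
        d = main(f"{u}_d", {f"{u}_B": -1.0, f"{u}_T": 1.0})
        b.feed_biomass(f"{u}_T")
        truth.chokepoint_class[t] = LABEL_EXTENDED
        truth.essential |= {f"EX_{u}", t, d}
        truth.target_reactions |= {t, d}

    for i in range(spec.n_parallel_motifs):
        u = f"pp{i}"
        main(f"EX_{u}", {f"{u}_S": 1.0}, gene=False)
        q1 = main(f"{u}_q1", {f"{u}_S": -1.0, f"{u}_T": 1.0})
        q2 = main(f"{u}_q2", {f"{u}_S": -1.0, f"{u}_T": 1.0})
        b.feed_biomass(f"{u}_T")
        truth.essential.add(f"EX_{u}")
        truth.non_essential |= {q1, q2}

    # energy unit: biomass consumes ATP, so the route is essential
    main("EX_glc", {"glc": 1.0}, gene=False)
    main("glycolysis", {"glc": -1.0, "atp": 1.0})
    main("atp_demand", {"atp": -1.0})
    b.feed_biomass("atp", 0.5)
    truth.essential |= {"EX_glc", "glycolysis"}
    truth.non_essential.add("atp_demand")

    # PI4P branch: not consumed by biomass, active only under its objective
    main("EX_ins", {"ins": 1.0}, gene=False)
    main("pi4p_syn", {"ins": -1.0, "pi4p": 1.0})
    main("pi4p_demand", {"pi4p": -1.0})
    truth.non_essential |= {"pi4p_syn", "pi4p_demand"}

    # oxygen, consumed by biomass; uptake is import-positive
    b.rxn("EX_o2", {"o2": 1.0}, lb=0.0, ub=1000.0)
    b.feed_biomass("o2", 0.1)
    truth.essential.add("EX_o2")

    # orphan with no substrate source: blocked, dropped by the
    # consistency pass before any downstream stage sees it
    b.rxn("blocked_orphan", {"orp_C": -1.0, "orp_D": 1.0})
    truth.blocked.add("blocked_orphan")
    return gpr_rxns


def generate_toy_model(spec: FixtureSpec) -> tuple[MetabolicModel, ModelTruth]:
    """Assemble the toy model and its planted ground truth.

    GPRs assign one or two genes (``g0001`` ...) per internal reaction,
    deterministically from the seed; exchange, feeder and biomass
    reactions carry empty (always-active) rules. The genes of the
    redundant parallel route and of the PI4P branch are held out as
    cluster markers / non-targets by the expression generator.
    """
    rng = np.random.default_rng(spec.seed)
    b = _NetworkBuilder()
    truth = ModelTruth()
    gpr_rxns = _build_units(spec, b, truth)

    coeffs = {m: -c for m, c in b.biomass_inputs.items()}
    b.rxn("biomass", coeffs, lb=0.0, ub=_BIOMASS_UB)
    truth.essential.add("biomass")

    gene_counter = 0

    def next_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"g{gene_counter:04d}"

    gpr_by_rxn: dict[str, str] = {}
    for rid in gpr_rxns:
        g1 = next_gene()
        truth.gene_to_reactions.setdefault(g1, []).append(rid)
        # roughly a quarter of internal reactions model a two-subunit complex
        if rng.random() < 0.25:
            g2 = next_gene()
            truth.gene_to_reactions.setdefault(g2, []).append(rid)
            gpr_by_rxn[rid] = f"{g1} and {g2}"
        else:
            gpr_by_rxn[rid] = g1

    met_index = {m: i for i, m in enumerate(b.metabolites)}
    S = np.zeros((len(b.metabolites), len(b.reactions)))
    rids, lbs, ubs, gpr_text = [], [], [], []
    for j, (rid, cf, lb, ub) in enumerate(b.reactions):
        rids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        gpr_text.append(gpr_by_rxn.get(rid, ""))
        for m, c in cf.items():
            S[met_index[m], j] = c

    model = MetabolicModel(
        metabolite_ids=list(b.metabolites),
        reaction_ids=rids,
        S=S,
        lower_bound=np.array(lbs),
        upper_bound=np.array(ubs),
        gpr_text=gpr_text,
        gene_ids=sorted(truth.gene_to_reactions),
        objective_tags={"biomass": "biomass", "atp": "atp_demand",
                        "pi4p": "pi4p_demand", "oxygen_uptake": "EX_o2"},
        id=f"toy_model_seed{spec.seed}",
    )

    gene_rxns = truth.gene_to_reactions
    truth.target_genes = {
        g for g, rs in gene_rxns.items()
        if any(r in truth.target_reactions for r in rs)
    }
    # cluster markers: genes of the redundant second route only; every
    # tagged objective reaction must stay active in both planted profiles
    truth.marker_genes = {
        g for g, rs in gene_rxns.items()
        if all(r.endswith("_q2") for r in rs)
    }
    return model, truth


def generate_expression(spec: FixtureSpec, model: MetabolicModel,
                        truth: ModelTruth,
                        ) -> tuple[ExpressionMatrix, pd.DataFrame,
                                   ExpressionTruth]:
    """Two-cluster tumor cohort plus a normal cohort and a differential
    table.

    Tumor samples are drawn from two planted binary activity profiles:
    both keep every objective-critical model gene active, while cluster B
    switches off the redundant-route marker genes and the held-out extra
    genes. Active genes sit at
    a high baseline, inactive ones at zero; the planted upregulated genes
    (the extended-choke-point target genes) are lowered in the normal
    cohort by ``effect_size`` log2 units. Multiplicative log-normal noise
    at the requested sigma is applied to non-zero entries.

    The differential table's logFC column is recomputed from the generated
    matrix with the epsilon-smoothed fold-change helper; its p-value
    column is planted (tiny for upregulated genes, 0.5 otherwise), a
    synthetic stand-in for a cohort-scale differential-expression pipeline,
    which is out of scope here.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = list(model.gene_ids) + [f"x{i:04d}"
                                    for i in range(spec.n_extra_genes)]
    base = 100.0
    n_genes = len(genes)

    # cluster B switches off the redundant-route marker genes and every
    # held-out extra gene, giving the clusters a comfortable Hamming gap
    # without touching any objective-critical model gene
    extra = set(genes) - set(model.gene_ids)
    profile_a = np.ones(n_genes, dtype=int)
    profile_b = np.ones(n_genes, dtype=int)
    for i, g in enumerate(genes):
        if g in truth.marker_genes or g in extra:
            profile_b[i] = 0
    profiles = [
        BinaryActivitySignature(genes, profile_a, label="profile_A"),
        BinaryActivitySignature(genes, profile_b, label="profile_B"),
    ]

    n_t, n_n = spec.n_tumor_samples, spec.n_normal_samples
    tumor_ids = [f"tumor_{i:03d}" for i in range(n_t)]
    normal_ids = [f"normal_{i:03d}" for i in range(n_n)]
    assignment = {s: (0 if i < (n_t + 1) // 2 else 1)
                  for i, s in enumerate(tumor_ids)}

    values = np.zeros((n_genes, n_t + n_n))
    for j, s in enumerate(tumor_ids):
        prof = profiles[assignment[s]].states
        values[:, j] = prof * base
    upregulated = set(truth.target_genes)
    normal_level = np.array([
        base / (2.0 ** spec.effect_size) if g in upregulated else base
        for g in genes
    ])
    for j in range(n_n):
        values[:, n_t + j] = normal_level
    if spec.noise_sigma > 0:
        noise = np.exp(rng.normal(0.0, spec.noise_sigma, size=values.shape))
        values = values * noise

    expr = ExpressionMatrix(
        gene_ids=genes,
        sample_ids=tumor_ids + normal_ids,
        values=values,
        cohort={**{s: "tumor" for s in tumor_ids},
                **{s: "normal" for s in normal_ids}},
    )

    eps = 1.0
    mt = values[:, :n_t].mean(axis=1)
    mn = values[:, n_t:].mean(axis=1)
    logfc = np.log2((mt + eps) / (mn + eps))
    pvals = np.array([1e-30 if g in upregulated else 0.5 for g in genes])
    table = pd.DataFrame({"gene": genes, "logFC": logfc, "pvalue": pvals})

    etruth = ExpressionTruth(
        profiles=profiles,
        assignments=assignment,
        upregulated=upregulated,
        target_genes=set(truth.target_genes),
    )
    return expr, table, etruth


def generate_interactions(truth: ModelTruth, seed: int = 0) -> pd.DataFrame:
    """Chemical-gene interaction snapshot with planted drug->target rows.

    One chemical covers two target genes, one covers a single target gene,
    and one decoy targets only non-target genes; a duplicate-source row
    exercises per-gene deduplication downstream.
    """
    targets = sorted(truth.target_genes)
    non_targets = sorted(set(truth.gene_to_reactions) - truth.target_genes)
    rows: list[dict[str, str]] = []
    if len(targets) >= 2:
        rows += [
            {"chemical": "chem_multi", "gene": targets[0],
             "interaction_type": "expression_decrease", "source": "snapshotA"},
            {"chemical": "chem_multi", "gene": targets[1],
             "interaction_type": "direct", "source": "snapshotA"},
            {"chemical": "chem_multi", "gene": targets[0],
             "interaction_type": "expression_decrease", "source": "snapshotB"},
        ]
    if targets:
        rows.append({"chemical": "chem_single", "gene": targets[0],
                     "interaction_type": "direct", "source": "snapshotA"})
    if non_targets:
        rows.append({"chemical": "chem_decoy", "gene": non_targets[0],
                     "interaction_type": "predicted", "source": "snapshotA"})
    return pd.DataFrame(rows,
                        columns=["chemical", "gene", "interaction_type",
                                 "source"])


def write_fixture(outdir: str | Path, spec: FixtureSpec) -> dict[str, Path]:
    """Materialize a full fixture as the file formats the pipeline reads.

    Writes the COBRA-JSON model, expression and cohort TSVs, the
    differential table, the interaction snapshot, and a gene->reaction
    manifest; returns the path of each artifact.
    """
    from .expression import write_expression_tsv
    from .model_core import save_model

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, truth = generate_toy_model(spec)
    expr, table, _ = generate_expression(spec, model, truth)
    inter = generate_interactions(truth, seed=spec.seed)

    paths = {
        "model": outdir / "model.json",
        "expression": outdir / "expression.tsv",
        "cohorts": outdir / "cohorts.tsv",
        "differential": outdir / "differential.tsv",
        "interactions": outdir / "interactions.tsv",
        "gene_manifest": outdir / "gene_manifest.tsv",
        "config": outdir / "config.yaml",
    }
    save_model(model, paths["model"])
    write_expression_tsv(expr, paths["expression"], paths["cohorts"])
    table.to_csv(paths["differential"], sep="\t", index=False)
    inter.to_csv(paths["interactions"], sep="\t", index=False)
    pd.DataFrame(
        [{"gene": g, "reactions": ";".join(rs)}
         for g, rs in sorted(truth.gene_to_reactions.items())]
    ).to_csv(paths["gene_manifest"], sep="\t", index=False)
    import yaml

    with open(paths["config"], "w") as fh:
        yaml.safe_dump({"objective_tags": dict(model.objective_tags)}, fh)
    return paths
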
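# Methods

gemrank implements an expression-informed target-ranking workflow for
genome-scale metabolic models (GSMs). The pipeline answers two questions:
*what to target* — which reactions are simultaneously essential, tied to
tumor-upregulated genes, and topologically critical across a family of
metabolic states — and *how to target it* — which chemicals, from a
snapshot of chemical–gene interactions, cover the genes behind those
reactions.

## Model and procedure

**Constraint-based model.** A GSM is a stoichiometric matrix
S ∈ ℝ^(m×n) (metabolites × reactions) with flux bounds l ≤ v ≤ u
(mmol/gDW/h) and per-reaction gene–protein–reaction (GPR) boolean rules
(AND = complex subunits, OR = isozymes). Flux balance analysis (FBA)
solves max c·v s.t. S·v = 0, l ≤ v ≤ u. With positive flux, column j
consumes metabolites with S_ij < 0 and produces those with S_ij > 0;
negative flux reverses the roles. This sign convention is set once in
`model_core` and inherited everywhere.

**Expression binarization and medoids.** Tumor samples are binarized
gene-wise: state(g, s) = 1 iff E[g, s] ≥ Q (the global quantile of the
pooled matrix, Q1 by default, linear/type-7 interpolation) **and**
E[g, s] ≥ mean_s' E[g, s'] (the gene-local criterion). Both comparisons
are inclusive, which matters for constant rows sitting exactly at both
thresholds. The binary vectors are clustered with PAM (k-medoids,
BUILD + SWAP to convergence, Manhattan distance — the Hamming count on
0/1 data), with k chosen by mean silhouette width. Medoids are actual
samples, which keeps the downstream activity evidence realizable.

**Consistency and contextualization.** A reaction is flux-consistent at
tolerance τ when some steady-state solution carries |v| ≥ τ through it.
Blocked reactions carry zero flux in every solution, so removing them
does not change anyone else's flux space; the maximal consistent
subnetwork is unique and obtained by one pass of per-reaction flux
variability analysis (FVA: maximize and minimize each v_j). The
contextualization step is a deliberately contracted extraction: reactions
whose GPR evaluates to 0 under the medoid signature are removed (empty
GPRs — exchanges, biomass — are kept), then the consistent subnetwork is
re-extracted, cascading removals to reactions stranded by the pruning.
This preserves the medoid → consistent condition-specific model contract
with fully checkable semantics; it does **not** re-fit expression
evidence the way weighted core/non-core extraction methods do, so genes
called inactive in the medoid are hard constraints here.

**Multi-objective FBA design.** Three objectives describe the modeled
metabolic states: biomass yield, ATP yield, and production of
1-phosphatidyl-1D-myo-inositol-4-phosphate (PI4P), each read as the flux
of a tagged reaction at fixed uptake bounds. The weighted global
criterion collapses them to single LPs max w·(v_bio, v_atp, v_pi4p) over
the simplex-lattice design {q=3, m=4}: all weight vectors with entries in
{0, ¼, ½, ¾, 1} summing to 1 — C(6,4) = 15 tests. A 16th test minimizes
total flux Σ|v_j| (via auxiliary variables t_j ≥ |v_j|) with biomass
anchored at its single-objective optimum; without an anchor the all-zero
vector is optimal whenever feasible, so the unanchored variant exists
only as an explicitly flagged degenerate mode. Oxygen uptake is capped at
2 mmol/gDW/h at solve time; the sign carrying uptake is auto-detected
from the exchange column's stoichiometry. Optima are de-duplicated
greedily in input order under the L∞ norm (tolerance 1e-6), giving the
non-redundant solution set.

**Essentiality.** On each contextualized model, every reaction is
individually clamped to zero flux and biomass re-maximized; a reaction is
essential when the optimum drops by ≥ 5% of the baseline. Infeasible
knockouts count as zero biomass. The screen runs once per model against
the biomass objective, not per weight vector.

**Choke points.** Each non-redundant optimum induces a reduced network of
its active elements: reactions with |v| above the flux tolerance,
columns sign-flipped when carried in reverse, inactive metabolites
dropped. On that oriented network, a reaction is a *single choke point on
the consumption side* when some metabolite is consumed exclusively by it
(production side analogously), a *double choke point* when both hold, and
an *extended choke point* — the stringent selection class — when, for
some witnessing pair (m_in, m_out), the neighbourhood is itself made of
single choke points: every producer of m_in is single-producing and every
consumer of m_out is single-consuming (the ALL quantifier; an EXISTS
variant is available via `AnalysisConfig.extended_mode`). Only incidence
signs matter; stoichiometric magnitudes are ignored. Exchange reactions
count as producers/consumers like any other column. An optional currency
metabolite exclusion list exists but defaults to empty.

**Centrality.** The reduced network is converted to its reactions-as-
nodes directed graph: edge i → j iff some metabolite is produced by i and
consumed by j in the realized directions. Standard PageRank (damping
0.85, uniform teleportation, dangling mass redistributed uniformly,
power iteration to L1 change < 1e-10) scores the nodes.

**Scoring and ranking.** Per medoid model, a reaction's *occurrence* is
the number of non-redundant optima in which it is an extended choke
point, and its *centrality* is its summed PageRank across them (0 when
inactive). It is occurrence-selected when occurrence ≥
⌈0.5 · n_solutions⌉ ("at least half") and topology-selected when its
summed centrality falls in the top ⌊0.10 · n_ranked⌋ ("top 10%"), ties
at the cutoff included. Medoid score lists are combined by summation over
the union of reactions, selection flags OR-ed. *Reactions of interest*
are those that are essential AND reference ≥ 1 upregulated gene
(logFC ≥ 1.5 and p ≤ 1e-16, inclusive, from a supplied differential
table) AND are occurrence- and/or topology-selected. Gene scores sum
occurrence and centrality over the gene's reactions of interest; each
component is max-normalized to [0, 1] (an all-zero column normalizes to
zero), so gene relevance = occurrence_norm + centrality_norm ∈ [0, 2].
Raw sums are emitted alongside the normalized ones, since either
convention appears in practice. A chemical's relevance is the sum of
relevance over its *distinct* scored target genes; interaction direction
(direct, expression increase/decrease, predicted) is reporting metadata
and never weights the score.

## Parameters

| parameter | default | unit / range | role |
|---|---|---|---|
| `global_quantile` | 0.25 | fraction | pooled-matrix activity threshold (Q1) |
| `logfc_min` / `pvalue_max` | 1.5 / 1e-16 | log2 / probability | upregulation call (inclusive) |
| `oxygen_ub` | 2.0 | mmol/gDW/h | oxygen uptake cap at FBA time |
| `essentiality_drop` | 0.05 | fraction | biomass reduction deeming a knockout essential |
| `lattice_q`, `lattice_m` | 3, 4 | — | simplex lattice design (15 weight vectors) |
| `occurrence_fraction` | 0.5 | fraction | extended-choke-point occurrence cutoff |
| `centrality_top_fraction` | 0.10 | fraction | summed-PageRank selection cutoff |
| `damping` | 0.85 | — | PageRank damping |
| `flux_tol` | 1e-6 | flux | zero-flux threshold (consistency, reduction) |
| `dedup_tol` | 1e-6 | flux | L∞ radius identifying duplicate optima |

## Numerical choices

- All LPs go through HiGHS (scipy interface) with default fixed options;
  for a fixed problem the solver is deterministic, which the bitwise
  output-reproducibility guarantee relies on.
- FBA optima are generally non-unique. Determinism comes from the fixed
  solver and fixed problem assembly order, not from a claim of
  uniqueness; conclusions that depend on the particular optimum (e.g.
  which of two redundant twins carries flux) are exactly the ones the
  dedup/occurrence machinery is designed to average over.
- PAM ties (equal-objective swaps, medoid ordering) break toward the
  lowest sample index; silhouette ties prefer the smaller k. The `seed`
  arguments exist for interface stability — the algorithms are
  deterministic without them.
- The min-total-flux anchor fixes biomass within ±max(flux_tol, 1e-9 ×
  optimum) rather than exactly, avoiding knife-edge infeasibility.
- Degenerate inputs: an all-identical signature set returns the smallest
  candidate k with a warning; an infeasible model yields an empty
  consistent subnetwork with a warning; an all-zero flux vector reduces
  to an empty network that downstream stages skip; a zero baseline
  biomass makes essentiality undefined and raises.

## Synthetic fixtures: what they do and do not show

`gemrank.synthetic` assembles toy models from exchange-fed units wired
into a biomass sink: linear chains (interior reactions extended choke
points, whole path essential), one motif block per planted choke-point
class — with fixed-bound feeder reactions forcing the side branches that
make or break exclusivity — redundant parallel pairs (nothing essential),
an ATP route consumed by biomass, a PI4P branch active only under its own
objective, an oxygen exchange, and a blocked orphan reaction removed by
the consistency pass. Expression data comes from two planted activity
profiles differing in the redundant-route marker genes and a set of
held-out extra genes, over a tumor cohort of 20 and a normal cohort of
10; target genes are lowered 2 log2 units in the normal cohort.

The generator's default is noise-free, and that is a substantive choice:
the gene-local "≥ mean" criterion marks below-average samples inactive,
so under any per-entry multiplicative noise an always-active gene loses
about half of its activity calls, and the hard-removal contextualization
then destroys the biomass route. Planted all-active profiles are exactly
recoverable only at σ = 0. Passing recovery tests therefore demonstrates
correctness of the machinery on clean two-cluster structure — they do not
demonstrate robustness of the binarize → hard-removal chain to expression
noise, which in the original workflow is absorbed by a weighted
core/non-core extraction step that this package deliberately contracts.
The fixture's differential table likewise plants its p-value column
(cohorts of 20 vs 10 cannot reach p ≤ 1e-16 by any test), standing in for
an out-of-scope cohort-scale differential-expression pipeline; only the
logFC column is recomputed from the generated matrix.

Fixture scale (≈ 38 reactions, 30 genes, 30 samples) keeps every oracle
brute-forceable: the whole test suite, including two full pipeline runs
and the cobra/GLPK cross-checks, completes in well under a minute.

## Known limitations

- The contextualization substitute treats medoid-inactive genes as hard
  removals; real cohorts binarized this way produce noisy signatures that
  this policy does not tolerate (see above). Feeding it medoids from a
  dedicated extraction method is the intended production path.
- Essentiality is reaction-level; mapping back to genes through GPRs
  (isozyme masking, complex membership) is only done via "references an
  upregulated gene", not via gene-level knockouts.
- The top-10% centrality selection operates on centrality summed over
  optima, not per optimum; both readings are defensible and the choice is
  recorded here.
- No thermodynamic (loopless) constraints: internal cycles can carry flux
  in lattice tests, though the min-total-flux test suppresses them.
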
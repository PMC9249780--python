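"""Expression binarization, k-medoids clustering and upregulation calls.

Tumor expression profiles are binarized with two simultaneous thresholds —
a global quantile over the pooled matrix (Q1 by default) and a per-gene
mean across samples — so each sample becomes a 0/1 activity vector. The
vectors are clustered with PAM (k-medoids) under Manhattan distance, which
on binary data is the Hamming count; the number of clusters is chosen by
mean silhouette width. Upregulated genes are read off a precomputed
differential-expression table with inclusive logFC and p-value thresholds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import pairwise_distances, silhouette_score

from .config import AnalysisConfig
from .errors import ValidationError

logger = logging.getLogger(__name__)

COHORT_TUMOR = "tumor"
COHORT_NORMAL = "normal"


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative normalized counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    cohort: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")
        for s, c in self.cohort.items():
            if s not in self.sample_ids:
                raise ValidationError(f"cohort label for unknown sample {s!r}")
            if c not in (COHORT_TUMOR, COHORT_NORMAL):
                raise ValidationError(f"cohort must be tumor/normal, got {c!r}")

    def restrict(self, cohort: str) -> "ExpressionMatrix":
        cols = [j for j, s in enumerate(self.sample_ids)
                if self.cohort.get(s) == cohort]
        if not cols:
            raise ValidationError(f"no samples with cohort {cohort!r}")
        sids = [self.sample_ids[j] for j in cols]
        return ExpressionMatrix(self.gene_ids, sids, self.values[:, cols],
                                {s: cohort for s in sids})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)


@dataclass
class BinaryActivitySignature:
    """Per-gene 0/1 activity vector for a sample or a cluster medoid."""

    gene_ids: list[str]
    states: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.states.shape != (len(self.gene_ids),):
            raise ValidationError("one state per gene required")
        if not np.isin(self.states, (0, 1)).all():
            raise ValidationError("states must be 0 or 1")

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.gene_ids, (int(s) for s in self.states)))


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def binarize(expr: ExpressionMatrix, cfg: AnalysisConfig | None = None,
             ) -> list[BinaryActivitySignature]:
    """Binarize each sample: 1 iff value >= global quantile AND >= gene mean.

    Both thresholds are inclusive. The global threshold is the
    ``cfg.global_quantile`` quantile of the pooled matrix (linear
    interpolation between order statistics, R type-7, by default); the
    local one is the per-gene mean across the supplied samples.
    """
    cfg = cfg or AnalysisConfig()
    if expr.values.size == 0:
        raise ValidationError("cannot binarize an empty expression matrix")
    if len(expr.gene_ids) < 2 or len(expr.sample_ids) < 2:
        raise ValidationError("binarization requires >= 2 genes and >= 2 samples")
    global_thr = float(np.quantile(expr.values, cfg.global_quantile,
                                   method=cfg.quantile_method))
    gene_means = expr.values.mean(axis=1, keepdims=True)
    states = (expr.values >= global_thr) & (expr.values >= gene_means)
    logger.info("binarize: global threshold (q=%.2f) = %.4g",
                cfg.global_quantile, global_thr)
    return [
        BinaryActivitySignature(expr.gene_ids, states[:, j].astype(int),
                                label=sid)
        for j, sid in enumerate(expr.sample_ids)
    ]


def _signature_matrix(signatures: Sequence[BinaryActivitySignature]) -> np.ndarray:
    if not signatures:
        raise ValidationError("no signatures supplied")
    genes = signatures[0].gene_ids
    for s in signatures[1:]:
        if s.gene_ids != genes:
            raise ValidationError("signatures have inconsistent gene lists")
    return np.vstack([s.states for s in signatures]).astype(float)


# ---------------------------------------------------------------------------
# PAM (k-medoids), BUILD + SWAP
# ---------------------------------------------------------------------------

def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        best_j, best_gain = -1, -np.inf
        dist_near = D[:, medoids].min(axis=1)
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(dist_near - D[:, j], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    return sorted(medoids)


def _pam_objective(D: np.ndarray, medoids: Sequence[int]) -> float:
    return float(D[:, list(medoids)].min(axis=1).sum())


def pam_cluster(signatures: Sequence[BinaryActivitySignature], k: int,
                seed: int = 0,
                ) -> tuple[np.ndarray, list[BinaryActivitySignature]]:
    """Cluster binary signatures with PAM under Manhattan distance.

    Classic BUILD + SWAP to convergence; ties in medoid selection are broken
    by the lowest index, so the result is deterministic and ``seed`` is kept
    only for interface stability. Returns ``(assignments, medoids)`` where
    assignments index into the returned medoid list and each medoid is a
    member of the input set relabelled ``medoid_<i>``.
    """
    X = _signature_matrix(signatures)
    n = X.shape[0]
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k >= n:
        raise ValidationError(f"k={k} requires more than k signatures (got {n})")
    D = pairwise_distances(X, metric="manhattan")
    medoids = _pam_build(D, k)
    best_obj = _pam_objective(D, medoids)
    improved = True
    while improved:
        improved = False
        best_swap, best_swap_obj = None, best_obj
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                cand = medoids[:mi] + [h] + medoids[mi + 1:]
                obj = _pam_objective(D, cand)
                if obj < best_swap_obj - 1e-12:
                    best_swap_obj, best_swap = obj, (mi, h)
        if best_swap is not None:
            mi, h = best_swap
            medoids[mi] = h
            medoids = sorted(medoids)
            best_obj = best_swap_obj
            improved = True
    assignments = np.argmin(D[:, medoids], axis=1)
    medoid_sigs = [
        BinaryActivitySignature(signatures[m].gene_ids,
                                signatures[m].states.copy(),
                                label=f"medoid_{i}")
        for i, m in enumerate(medoids)
    ]
    return assignments, medoid_sigs


def select_k_silhouette(signatures: Sequence[BinaryActivitySignature],
                        k_range: Sequence[int], seed: int = 0) -> int:
    """Pick the k in ``k_range`` maximizing mean silhouette width of PAM.

    Ties prefer the smaller k. If all signatures are identical the
    silhouette is undefined; the smallest candidate k is returned with a
    warning.
    """
    X = _signature_matrix(signatures)
    n = X.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValidationError("empty k_range")
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValidationError(f"k_range must lie within [2, {n - 1}]")
    D = pairwise_distances(X, metric="manhattan")
    if np.allclose(D, 0):
        warnings.warn("all signatures identical; silhouette undefined, "
                      "returning smallest k", stacklevel=2)
        return ks[0]
    best_k, best_score = ks[0], -np.inf
    for k in ks:
        assignments, _ = pam_cluster(signatures, k, seed=seed)
        if len(set(assignments.tolist())) < 2:
            continue
        score = float(silhouette_score(D, assignments, metric="precomputed"))
        logger.info("silhouette k=%d: %.4f", k, score)
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    return best_k


# ---------------------------------------------------------------------------
# differential expression thresholds
# ---------------------------------------------------------------------------

def flag_upregulated(table: pd.DataFrame, cfg: AnalysisConfig | None = None,
                     ) -> set[str]:
    """Genes with logFC >= cfg.logfc_min and p-value <= cfg.pvalue_max.

    Both comparisons are inclusive. ``table`` must have columns ``gene``,
    ``logFC`` and ``pvalue`` (or gene ids as index).
    """
    cfg = cfg or AnalysisConfig()
    if table.empty:
        raise ValidationError("differential table is empty")
    df = table.reset_index() if "gene" not in table.columns else table
    for col in ("gene", "logFC", "pvalue"):
        if col not in df.columns:
            raise ValidationError(f"differential table missing column {col!r}")
    if ((df["pvalue"] < 0) | (df["pvalue"] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    mask = (df["logFC"] >= cfg.logfc_min) & (df["pvalue"] <= cfg.pvalue_max)
    return set(df.loc[mask, "gene"].astype(str))


def naive_differential_table(expr: ExpressionMatrix, epsilon: float = 1.0,
                             ) -> pd.DataFrame:
    """Convenience logFC table for synthetic tests only (non-canonical).

    logFC = log2((mean tumor + eps) / (mean normal + eps)); the p-value
    column is a Welch t-test on log2(value + eps). This is *not* a
    differential-expression method — real analyses should supply a table
    from a dedicated pipeline (e.g. limma/edgeR output).
    """
    from scipy import stats

    tumor = expr.restrict(COHORT_TUMOR).values
    normal = expr.restrict(COHORT_NORMAL).values
    mt, mn = tumor.mean(axis=1), normal.mean(axis=1)
    logfc = np.log2((mt + epsilon) / (mn + epsilon))
    lt = np.log2(tumor + epsilon)
    ln = np.log2(normal + epsilon)
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pvals = stats.ttest_ind(lt, ln, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    return pd.DataFrame({"gene": expr.gene_ids, "logFC": logfc,
                         "pvalue": pvals})


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path,
                        cohort_path: str | Path | None = None,
                        ) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header = samples)
    plus an optional two-column (sample, cohort) TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cohort: dict[str, str] = {}
    if cohort_path is not None:
        cdf = pd.read_csv(cohort_path, sep="\t")
        if cdf.shape[1] < 2:
            raise ValidationError("cohort file needs columns: sample, cohort")
        cohort = dict(zip(cdf.iloc[:, 0].astype(str), cdf.iloc[:, 1].astype(str)))
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        cohort=cohort,
    )


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path,
                         cohort_path: str | Path | None = None) -> None:
    df = expr.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
    if cohort_path is not None:
        pd.DataFrame({
            "sample": expr.sample_ids,
            "cohort": [expr.cohort.get(s, "") for s in expr.sample_ids],
        }).to_csv(cohort_path, sep="\t", index=False)


def read_differential_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "logFC", "pvalue"):
        if col not in df.columns:
            raise ValidationError(f"differential table missing column {col!r}")
    return df
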
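"""Analysis configuration shared across pipeline stages.

All thresholds of the workflow live in one frozen dataclass so that a run is
fully described by its config plus its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Any, Mapping

from .errors import ValidationError

#: Reaction roles that may be tagged on a model. ``biomass``, ``atp`` and
#: ``pi4p`` are the three scalarized FBA objectives; ``oxygen_uptake`` is the
#: exchange reaction capped during model analysis.
OBJECTIVE_ROLES = ("biomass", "atp", "pi4p", "oxygen_uptake")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the target-ranking workflow.

    Parameters
    ----------
    global_quantile:
        Quantile of the pooled expression values used as the global
        "maybe active" threshold during binarization (Q1 by default).
    logfc_min, pvalue_max:
        Inclusive thresholds flagging a gene as tumor-upregulated from a
        precomputed differential-expression table.
    oxygen_ub:
        Upper bound on the oxygen uptake rate (mmol/gDW/h) applied when
        solving FBA problems.
    essentiality_drop:
        Minimal fractional reduction of the optimal biomass flux, upon
        single-reaction knockout, for the reaction to count as essential.
    lattice_q, lattice_m:
        Simplex-lattice design {q, m} enumerating objective-weight mixtures.
    occurrence_fraction:
        Fraction of non-redundant optima in which a reaction must be an
        extended choke point to be occurrence-selected ("at least half").
    centrality_top_fraction:
        Fraction of ranked reactions selected as topologically important
        by summed PageRank centrality ("top 10%").
    damping:
        PageRank damping factor.
    flux_tol:
        Fluxes with absolute value at or below this are treated as zero.
    dedup_tol:
        L-infinity tolerance under which two flux distributions are the
        same optimum.
    quantile_method:
        Quantile convention for the global threshold; ``"linear"`` matches
        R's default type-7 interpolation.
    extended_mode:
        Quantifier over the neighbourhood of a double choke point when
        testing for the extended class: ``"all"`` (strict) or ``"exists"``.
    missing_gene_policy:
        ``"strict"`` raises when a GPR references a gene absent from an
        activity signature; ``"zero"`` treats it as inactive.
    min_flux_anchor_biomass:
        Anchor the minimum-total-flux test at the biomass optimum
        (parsimonious-FBA convention). If False the test returns the
        trivial all-zero optimum and is flagged degenerate.
    """

    global_quantile: float = 0.25
    logfc_min: float = 1.5
    pvalue_max: float = 1e-16
    oxygen_ub: float = 2.0
    essentiality_drop: float = 0.05
    lattice_q: int = 3
    lattice_m: int = 4
    occurrence_fraction: float = 0.5
    centrality_top_fraction: float = 0.10
    damping: float = 0.85
    flux_tol: float = 1e-6
    dedup_tol: float = 1e-6
    quantile_method: str = "linear"
    extended_mode: str = "all"
    missing_gene_policy: str = "strict"
    min_flux_anchor_biomass: bool = True
    objective_tags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("global_quantile", "essentiality_drop",
                     "occurrence_fraction", "centrality_top_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must be in (0, 1], got {v!r}")
        for name in ("flux_tol",):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.dedup_tol < 0:
            raise ValidationError("dedup_tol must be >= 0")
        if not (0.0 < self.damping < 1.0):
            raise ValidationError("damping must be in (0, 1)")
        if self.lattice_q < 2 or self.lattice_m < 1:
            raise ValidationError("lattice requires q >= 2 and m >= 1")
        if self.extended_mode not in ("all", "exists"):
            raise ValidationError("extended_mode must be 'all' or 'exists'")
        if self.missing_gene_policy not in ("strict", "zero"):
            raise ValidationError("missing_gene_policy must be 'strict' or 'zero'")
        unknown = set(self.objective_tags) - set(OBJECTIVE_ROLES)
        if unknown:
            raise ValidationError(f"unknown objective roles: {sorted(unknown)}")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["objective_tags"] = dict(self.objective_tags)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    def with_(self, **kwargs: Any) -> "AnalysisConfig":
        return replace(self, **kwargs)
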
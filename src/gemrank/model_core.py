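"""Genome-scale metabolic model container and SBML/COBRA-JSON I/O.

The in-memory representation is a plain stoichiometric matrix (rows =
metabolites, columns = reactions) with per-reaction flux bounds and GPR
rules. Sign convention, inherited by every downstream stage: with positive
flux, column j consumes the metabolites with ``S[i, j] < 0`` and produces
those with ``S[i, j] > 0``; negative flux reverses the roles.

File parsing and writing is delegated to :mod:`cobra` (SBML Level 3 + FBC
and COBRA-style JSON); this module only converts to and from the internal
container and validates the result.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .config import OBJECTIVE_ROLES
from .errors import FormatError, ValidationError
from .gpr import ALWAYS_ACTIVE, GprExpression, parse_gpr

logger = logging.getLogger(__name__)


@dataclass
class MetabolicModel:
    """Stoichiometric model with GPR rules and tagged objective reactions.

    ``objective_tags`` maps a role in ``{"biomass", "atp", "pi4p",
    "oxygen_uptake"}`` to a reaction id of this model; roles are matched by
    exact reaction id only, never by name heuristics.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lower_bound: np.ndarray
    upper_bound: np.ndarray
    gpr_text: list[str]
    gene_ids: list[str]
    objective_tags: dict[str, str] = field(default_factory=dict)
    id: str = "model"

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lower_bound = np.asarray(self.lower_bound, dtype=float)
        self.upper_bound = np.asarray(self.upper_bound, dtype=float)
        self._gpr_cache: dict[int, GprExpression] = {}
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        n_met, n_rxn = len(self.metabolite_ids), len(self.reaction_ids)
        if len(set(self.metabolite_ids)) != n_met:
            raise ValidationError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != n_rxn:
            raise ValidationError("duplicate reaction ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if self.S.shape != (n_met, n_rxn):
            raise ValidationError(
                f"S has shape {self.S.shape}, expected ({n_met}, {n_rxn})")
        if self.lower_bound.shape != (n_rxn,) or self.upper_bound.shape != (n_rxn,):
            raise ValidationError("bounds must be per-reaction vectors")
        bad = np.nonzero(self.lower_bound > self.upper_bound)[0]
        if bad.size:
            rid = self.reaction_ids[int(bad[0])]
            raise ValidationError(
                f"reaction {rid!r}: lower bound exceeds upper bound")
        if len(self.gpr_text) != n_rxn:
            raise ValidationError("one GPR rule required per reaction")
        gene_set = set(self.gene_ids)
        for j in range(n_rxn):
            missing = self.gpr(j).genes() - gene_set
            if missing:
                raise ValidationError(
                    f"reaction {self.reaction_ids[j]!r} references unknown "
                    f"genes {sorted(missing)}")
        for role, rid in self.objective_tags.items():
            if role not in OBJECTIVE_ROLES:
                raise ValidationError(f"unknown objective role {role!r}")
            if rid not in self.reaction_ids:
                raise ValidationError(
                    f"objective role {role!r} tags unknown reaction {rid!r}")

    # -- accessors ----------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise ValidationError(f"unknown reaction id {rid!r}") from None

    def gpr(self, j: int) -> GprExpression:
        """Parsed GPR of reaction column ``j`` (cached)."""
        if j not in self._gpr_cache:
            text = self.gpr_text[j]
            self._gpr_cache[j] = parse_gpr(text) if text.strip() else ALWAYS_ACTIVE
        return self._gpr_cache[j]

    def gprs(self) -> dict[str, GprExpression]:
        return {rid: self.gpr(j) for j, rid in enumerate(self.reaction_ids)}

    def tagged_reaction(self, role: str) -> str:
        if role not in self.objective_tags:
            raise ValidationError(f"model has no {role!r} objective tag")
        return self.objective_tags[role]

    # -- structural operations ----------------------------------------
    def subset(self, keep_reactions: Sequence[str]) -> "MetabolicModel":
        """Submodel restricted to ``keep_reactions``.

        Metabolites whose row becomes all-zero are dropped; objective tags
        pointing at removed reactions are dropped (logged); gene_ids are
        restricted to genes still referenced by a retained GPR.
        """
        keep = set(keep_reactions)
        unknown = keep - set(self.reaction_ids)
        if unknown:
            raise ValidationError(f"unknown reaction ids: {sorted(unknown)}")
        cols = [j for j, rid in enumerate(self.reaction_ids) if rid in keep]
        S = self.S[:, cols]
        rows = [i for i in range(self.n_metabolites) if np.any(S[i, :] != 0)]
        rids = [self.reaction_ids[j] for j in cols]
        gpr_text = [self.gpr_text[j] for j in cols]
        referenced: set[str] = set()
        for j in cols:
            referenced |= self.gpr(j).genes()
        tags = {}
        for role, rid in self.objective_tags.items():
            if rid in keep:
                tags[role] = rid
            else:
                logger.warning("objective tag %s -> %s dropped by subset",
                               role, rid)
        return MetabolicModel(
            metabolite_ids=[self.metabolite_ids[i] for i in rows],
            reaction_ids=rids,
            S=S[rows, :],
            lower_bound=self.lower_bound[cols].copy(),
            upper_bound=self.upper_bound[cols].copy(),
            gpr_text=gpr_text,
            gene_ids=[g for g in self.gene_ids if g in referenced],
            objective_tags=tags,
            id=self.id,
        )

    # -- cobra conversion ---------------------------------------------
    def to_cobra(self):
        """Convert to a :class:`cobra.Model` (metabolites in compartment c)."""
        import cobra

        model = cobra.Model(self.id)
        mets = {}
        for mid in self.metabolite_ids:
            m = cobra.Metabolite(mid, compartment="c")
            mets[mid] = m
        model.add_metabolites(list(mets.values()))
        rxns = []
        for j, rid in enumerate(self.reaction_ids):
            r = cobra.Reaction(rid,
                               lower_bound=float(self.lower_bound[j]),
                               upper_bound=float(self.upper_bound[j]))
            rxns.append(r)
        model.add_reactions(rxns)
        for j, r in enumerate(rxns):
            coeffs = {
                mets[self.metabolite_ids[i]]: float(self.S[i, j])
                for i in range(self.n_metabolites) if self.S[i, j] != 0
            }
            r.add_metabolites(coeffs)
            if self.gpr_text[j].strip():
                r.gene_reaction_rule = self.gpr_text[j]
        return model

    @classmethod
    def from_cobra(cls, model, objective_tags: Mapping[str, str] | None = None,
                   ) -> "MetabolicModel":
        from cobra.util.array import create_stoichiometric_matrix

        S = create_stoichiometric_matrix(model, array_type="dense")
        return cls(
            metabolite_ids=[m.id for m in model.metabolites],
            reaction_ids=[r.id for r in model.reactions],
            S=S,
            lower_bound=np.array([r.lower_bound for r in model.reactions]),
            upper_bound=np.array([r.upper_bound for r in model.reactions]),
            gpr_text=[r.gene_reaction_rule or "" for r in model.reactions],
            gene_ids=sorted(g.id for g in model.genes),
            objective_tags=dict(objective_tags or {}),
            id=model.id or "model",
        )


def _check_json_duplicates(path: Path) -> None:
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("reactions", "metabolites"):
        ids = [e.get("id") for e in raw.get(key, [])]
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        if dups:
            raise ValidationError(
                f"{path}: duplicate {key[:-1]} ids {sorted(dups)}")


def load_model(path: str | Path, format: str | None = None,
               objective_tags: Mapping[str, str] | None = None,
               ) -> MetabolicModel:
    """Load an SBML (L3 + FBC) or COBRA-style JSON model.

    ``format`` is ``"sbml"`` or ``"json"``; inferred from the file suffix
    when omitted. ``objective_tags`` attaches role -> reaction-id tags and
    is validated against the loaded reaction list.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FormatError(f"model file not found: {path}")
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        _check_json_duplicates(path)
        try:
            cm = cobra.io.load_json_model(str(path))
        except (ValidationError, FormatError):
            raise
        except Exception as exc:
            raise FormatError(f"{path}: failed to parse COBRA JSON: {exc}") from exc
    elif format == "sbml":
        try:
            cm = cobra.io.read_sbml_model(str(path))
        except Exception as exc:
            raise FormatError(f"{path}: failed to parse SBML: {exc}") from exc
    else:
        raise ValidationError(f"unknown model format {format!r}")
    model = MetabolicModel.from_cobra(cm, objective_tags=objective_tags)
    logger.info("loaded %s: %d metabolites, %d reactions, %d genes",
                path, model.n_metabolites, model.n_reactions,
                len(model.gene_ids))
    return model


def save_model(model: MetabolicModel, path: str | Path,
               format: str | None = None) -> None:
    """Write a model as COBRA-JSON or SBML L3+FBC."""
    import cobra.io

    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    cm = model.to_cobra()
    if format == "json":
        cobra.io.save_json_model(cm, str(path))
    elif format == "sbml":
        cobra.io.write_sbml_model(cm, str(path))
    else:
        raise ValidationError(f"unknown model format {format!r}")
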
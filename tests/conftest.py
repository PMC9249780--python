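"""Shared fixtures: compact model construction helpers."""

from __future__ import annotations

import numpy as np
import pytest

from gemrank.model_core import MetabolicModel

DEFAULT_UB = 10.0


def make_model(reactions, objective_tags=None, gene_ids=None, model_id="toy"):
    """Build a MetabolicModel from a list of reaction tuples.

    Each entry is ``(rid, {met: coef}, lb, ub)`` or ``(rid, {met: coef},
    lb, ub, gpr_text)``. Metabolites appear in first-use order.
    """
    mets: list[str] = []
    seen: set[str] = set()
    for entry in reactions:
        for m in entry[1]:
            if m not in seen:
                seen.add(m)
                mets.append(m)
    S = np.zeros((len(mets), len(reactions)))
    midx = {m: i for i, m in enumerate(mets)}
    rids, lbs, ubs, gprs = [], [], [], []
    genes: set[str] = set()
    for j, entry in enumerate(reactions):
        rid, coeffs, lb, ub = entry[:4]
        gpr = entry[4] if len(entry) > 4 else ""
        rids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        gprs.append(gpr)
        for m, c in coeffs.items():
            S[midx[m], j] = c
    if gene_ids is None:
        from gemrank.gpr import parse_gpr

        for g in gprs:
            if g.strip():
                genes |= parse_gpr(g).genes()
        gene_ids = sorted(genes)
    return MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=rids,
        S=S,
        lower_bound=np.array(lbs, float),
        upper_bound=np.array(ubs, float),
        gpr_text=gprs,
        gene_ids=gene_ids,
        objective_tags=dict(objective_tags or {}),
        id=model_id,
    )


@pytest.fixture
def chain_model():
    """EX -> A -> B -> biomass sink; every reaction on the path is
    essential."""
    return make_model(
        [
            ("EX_A", {"A": 1.0}, 0, 10),
            ("r1", {"A": -1.0, "B": 1.0}, 0, 10, "g1"),
            ("biomass", {"B": -1.0}, 0, 10, "g2"),
        ],
        objective_tags={"biomass": "biomass"},
    )


@pytest.fixture
def three_objective_model():
    """Small model with biomass, ATP and PI4P routes plus oxygen uptake."""
    return make_model(
        [
            ("EX_glc", {"glc": 1.0}, 0, 10),
            ("EX_o2", {"o2": 1.0}, 0, 1000),
            ("to_bio", {"glc": -1.0, "o2": -0.1, "bio_pre": 1.0}, 0, 10, "g1"),
            ("biomass", {"bio_pre": -1.0}, 0, 10),
            ("to_atp", {"glc": -1.0, "atp": 1.0}, 0, 10, "g2"),
            ("atp_demand", {"atp": -1.0}, 0, 10),
            ("EX_ins", {"ins": 1.0}, 0, 5),
            ("to_pi4p", {"ins": -1.0, "pi4p": 1.0}, 0, 10, "g3"),
            ("pi4p_demand", {"pi4p": -1.0}, 0, 10),
        ],
        objective_tags={"biomass": "biomass", "atp": "atp_demand",
                        "pi4p": "pi4p_demand", "oxygen_uptake": "EX_o2"},
    )
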
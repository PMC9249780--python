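"""Per-solution network reduction, choke-point classification, and
reaction-centric PageRank.

Each unique FBA optimum induces a condition-specific network containing
only its active elements: reactions with |v| above the flux tolerance,
oriented by the sign of their flux (columns of reactions carried in
reverse are sign-flipped), and the metabolites they touch. Choke points
are incidence properties of that oriented network: a reaction is a single
choke point when it is the exclusive consumer (or producer) of some
metabolite, a double choke point when both, and an extended choke point —
the stringent class introduced for target selection — when it is a double
choke point surrounded by single choke points on both sides. Centrality is
computed on the reactions-as-nodes directed graph (the line-graph view of
the stoichiometry) with standard PageRank.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ValidationError
from .fba_design import FluxDistribution
from .model_core import MetabolicModel

logger = logging.getLogger(__name__)

#: Classification labels, from least to most specific.
LABEL_NONE = "none"
LABEL_SINGLE_CONSUMING = "single_consuming"
LABEL_SINGLE_PRODUCING = "single_producing"
LABEL_DOUBLE = "double"
LABEL_EXTENDED = "extended"


@dataclass
class ReducedNetwork:
    """Active reactions and metabolites of one flux distribution.

    ``S`` is the oriented stoichiometric submatrix: columns of reactions
    carried at negative flux are multiplied by -1, so positive entries
    always mean production in the realized direction.
    """

    reaction_ids: list[str]
    metabolite_ids: list[str]
    S: np.ndarray
    orientation: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (len(self.metabolite_ids), len(self.reaction_ids)):
            raise ValidationError("oriented S shape inconsistent with ids")

    @property
    def is_empty(self) -> bool:
        return not self.reaction_ids

    def producers(self, i: int) -> list[str]:
        return [self.reaction_ids[j] for j in np.nonzero(self.S[i, :] > 0)[0]]

    def consumers(self, i: int) -> list[str]:
        return [self.reaction_ids[j] for j in np.nonzero(self.S[i, :] < 0)[0]]


@dataclass
class ChokePointClassification:
    """Per-reaction choke-point labels with witnessing metabolites."""

    labels: dict[str, str]
    is_single_consuming: dict[str, bool]
    is_single_producing: dict[str, bool]
    witnesses_in: dict[str, list[str]]
    witnesses_out: dict[str, list[str]]

    def label(self, rid: str) -> str:
        return self.labels.get(rid, LABEL_NONE)

    def reactions_with_label(self, label: str) -> set[str]:
        return {r for r, lab in self.labels.items() if lab == label}


def reduce_network(model: MetabolicModel, flux: FluxDistribution,
                   flux_tol: float = 1e-6) -> ReducedNetwork:
    """Network of elements active in ``flux``: reactions with |v| > tol,
    oriented by sign(v), and the metabolites they involve."""
    if flux.reaction_ids != list(model.reaction_ids):
        raise ValidationError("flux distribution does not match the model's "
                              "reaction list")
    active = np.nonzero(np.abs(flux.v) > flux_tol)[0]
    if active.size == 0:
        warnings.warn("all-zero flux distribution yields an empty network",
                      stacklevel=2)
        return ReducedNetwork([], [], np.zeros((0, 0)))
    signs = np.sign(flux.v[active])
    S = model.S[:, active] * signs[np.newaxis, :]
    rows = np.nonzero(np.any(S != 0, axis=1))[0]
    rids = [model.reaction_ids[j] for j in active]
    return ReducedNetwork(
        reaction_ids=rids,
        metabolite_ids=[model.metabolite_ids[i] for i in rows],
        S=S[rows, :],
        orientation={r: int(s) for r, s in zip(rids, signs)},
    )


def classify_choke_points(net: ReducedNetwork, extended_mode: str = "all",
                          exclude_metabolites: set[str] | None = None,
                          ) -> ChokePointClassification:
    """Classify every active reaction into its most specific choke class.

    A reaction r is *single consuming* if some metabolite is consumed
    exclusively by r, *single producing* if some metabolite is produced
    exclusively by r, *double* if both, and *extended* if additionally,
    for some witnessing pair (m_in exclusively consumed by r, m_out
    exclusively produced by r), the neighbourhood is itself made of single
    choke points: producers of m_in are single producing and consumers of
    m_out are single consuming. ``extended_mode="all"`` (default) requires
    this of every neighbour — the stringent reading of "surrounded by" —
    while ``"exists"`` requires at least the neighbours that exist to
    include one such choke point on each populated side.

    ``exclude_metabolites`` optionally drops currency metabolites from the
    incidence analysis; no exclusion is applied by default. Stoichiometric
    magnitudes are ignored — only incidence signs matter.
    """
    if net.is_empty:
        return ChokePointClassification({}, {}, {}, {}, {})
    excl = exclude_metabolites or set()
    met_idx = [i for i, m in enumerate(net.metabolite_ids) if m not in excl]
    producers = {net.metabolite_ids[i]: set(net.producers(i)) for i in met_idx}
    consumers = {net.metabolite_ids[i]: set(net.consumers(i)) for i in met_idx}

    witnesses_in: dict[str, list[str]] = {r: [] for r in net.reaction_ids}
    witnesses_out: dict[str, list[str]] = {r: [] for r in net.reaction_ids}
    for i in met_idx:
        m = net.metabolite_ids[i]
        if len(consumers[m]) == 1:
            witnesses_in[next(iter(consumers[m]))].append(m)
        if len(producers[m]) == 1:
            witnesses_out[next(iter(producers[m]))].append(m)

    is_sc = {r: bool(witnesses_in[r]) for r in net.reaction_ids}
    is_sp = {r: bool(witnesses_out[r]) for r in net.reaction_ids}

    def neighbourhood_ok(r: str, m_in: str, m_out: str) -> bool:
        ups = producers[m_in] - {r}
        downs = consumers[m_out] - {r}
        if extended_mode == "all":
            return (all(is_sp[p] for p in ups)
                    and all(is_sc[c] for c in downs))
        up_ok = (not ups) or any(is_sp[p] for p in ups)
        down_ok = (not downs) or any(is_sc[c] for c in downs)
        return up_ok and down_ok

    labels: dict[str, str] = {}
    for r in net.reaction_ids:
        if is_sc[r] and is_sp[r]:
            extended = any(
                neighbourhood_ok(r, m_in, m_out)
                for m_in in witnesses_in[r]
                for m_out in witnesses_out[r]
            )
            labels[r] = LABEL_EXTENDED if extended else LABEL_DOUBLE
        elif is_sc[r]:
            labels[r] = LABEL_SINGLE_CONSUMING
        elif is_sp[r]:
            labels[r] = LABEL_SINGLE_PRODUCING
        else:
            labels[r] = LABEL_NONE
    return ChokePointClassification(labels, is_sc, is_sp,
                                    witnesses_in, witnesses_out)


def build_reaction_graph(net: ReducedNetwork) -> nx.DiGraph:
    """Directed reactions-as-nodes graph of the oriented network.

    There is an edge i -> j exactly when some metabolite is produced by i
    and consumed by j in the realized flux directions. Node order is the
    sorted reaction-id list, making downstream iteration deterministic.
    """
    g = nx.DiGraph()
    g.add_nodes_from(sorted(net.reaction_ids))
    for i in range(len(net.metabolite_ids)):
        prods = net.producers(i)
        cons = net.consumers(i)
        for p in prods:
            for c in cons:
                g.add_edge(p, c)
    return g


def pagerank(graph: nx.DiGraph, damping: float = 0.85,
             tol: float = 1e-10) -> dict[str, float]:
    """PageRank with uniform teleportation and uniform dangling
    redistribution; power iteration until the L1 change drops below tol."""
    n = graph.number_of_nodes()
    if n == 0:
        return {}
    if n == 1:
        return {next(iter(graph.nodes)): 1.0}
    # networkx's stopping rule is err < n * tol, so rescale to honour an
    # absolute L1 tolerance.
    scores = nx.pagerank(graph, alpha=damping, tol=tol / n, max_iter=100000)
    return {node: float(s) for node, s in scores.items()}
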
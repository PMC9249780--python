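"""Network reduction, choke-point classification (five concrete motifs plus
randomized brute-force agreement) and reaction-graph PageRank."""

import networkx as nx
import numpy as np
import pytest

from gemrank.fba_design import FluxDistribution
from gemrank.topology import (LABEL_DOUBLE, LABEL_EXTENDED, LABEL_NONE,
                              LABEL_SINGLE_CONSUMING, LABEL_SINGLE_PRODUCING,
                              ReducedNetwork, build_reaction_graph,
                              classify_choke_points, pagerank, reduce_network)

from conftest import make_model


def net_from(reactions):
    """ReducedNetwork from (rid, {met: signed coef}) pairs (already
    oriented)."""
    mets = []
    seen = set()
    for _, coeffs in reactions:
        for m in coeffs:
            if m not in seen:
                seen.add(m)
                mets.append(m)
    S = np.zeros((len(mets), len(reactions)))
    midx = {m: i for i, m in enumerate(mets)}
    for j, (_, coeffs) in enumerate(reactions):
        for m, c in coeffs.items():
            S[midx[m], j] = c
    return ReducedNetwork([r for r, _ in reactions], mets, S,
                          {r: 1 for r, _ in reactions})


def brute_force_labels(net, extended_mode="all"):
    """Independent re-derivation by enumerating every (reaction,
    metabolite) incidence pair explicitly."""
    rxns = net.reaction_ids
    mets = net.metabolite_ids
    produced = {(r, m): net.S[mets.index(m), rxns.index(r)] > 0
                for r in rxns for m in mets}
    consumed = {(r, m): net.S[mets.index(m), rxns.index(r)] < 0
                for r in rxns for m in mets}

    def producers(m):
        return {r for r in rxns if produced[(r, m)]}

    def consumers(m):
        return {r for r in rxns if consumed[(r, m)]}

    sc = {r: any(consumers(m) == {r} for m in mets) for r in rxns}
    sp = {r: any(producers(m) == {r} for m in mets) for r in rxns}

    labels = {}
    for r in rxns:
        if sc[r] and sp[r]:
            ext = False
            for m_in in mets:
                if consumers(m_in) != {r}:
                    continue
                for m_out in mets:
                    if producers(m_out) != {r}:
                        continue
                    ups = producers(m_in) - {r}
                    downs = consumers(m_out) - {r}
                    if extended_mode == "all":
                        ok = all(sp[p] for p in ups) and \
                            all(sc[c] for c in downs)
                    else:
                        ok = ((not ups or any(sp[p] for p in ups))
                              and (not downs or any(sc[c] for c in downs)))
                    if ok:
                        ext = True
            labels[r] = LABEL_EXTENDED if ext else LABEL_DOUBLE
        elif sc[r]:
            labels[r] = LABEL_SINGLE_CONSUMING
        elif sp[r]:
            labels[r] = LABEL_SINGLE_PRODUCING
        else:
            labels[r] = LABEL_NONE
    return labels


class TestReduceNetwork:
    @pytest.fixture
    def chain(self):
        return make_model([
            ("EX_A", {"A": 1.0}, 0, 10),
            ("r1", {"A": -1.0, "B": 1.0}, -10, 10),
            ("EX_B", {"B": -1.0}, 0, 10),
        ])

    def test_forward_chain_all_retained(self, chain):
        flux = FluxDistribution(chain.reaction_ids, np.array([10., 10., 10.]),
                                10.0, "t")
        net = reduce_network(chain, flux)
        assert net.reaction_ids == chain.reaction_ids
        assert all(net.orientation[r] == 1 for r in net.reaction_ids)

    def test_negative_flux_flips_stoichiometry(self, chain):
        flux = FluxDistribution(chain.reaction_ids, np.array([0., -5., 0.]),
                                0.0, "t")
        net = reduce_network(chain, flux)
        assert net.reaction_ids == ["r1"]
        assert net.orientation["r1"] == -1
        # flipped: A produced, B consumed
        a = net.S[net.metabolite_ids.index("A"), 0]
        b = net.S[net.metabolite_ids.index("B"), 0]
        assert a > 0 and b < 0

    def test_subthreshold_flux_dropped(self, chain):
        flux = FluxDistribution(chain.reaction_ids,
                                np.array([10., 1e-9, 10.]), 10.0, "t")
        net = reduce_network(chain, flux, flux_tol=1e-6)
        assert "r1" not in net.reaction_ids

    def test_all_zero_flux_warns_and_empties(self, chain):
        flux = FluxDistribution(chain.reaction_ids, np.zeros(3), 0.0, "t")
        with pytest.warns(UserWarning):
            net = reduce_network(chain, flux)
        assert net.is_empty


class TestChokePointMotifs:
    """The five canonical motifs, instantiated as concrete oriented
    networks; the planted target reaction is always ``t``."""

    def test_motif_not_a_choke_point(self):
        # L has two consumers, R has two producers -> t exclusive on nothing
        net = net_from([
            ("src", {"L": 1.0}),
            ("t", {"L": -1.0, "R": 1.0}),
            ("alt_consumer", {"L": -1.0, "W": 1.0}),
            ("alt_producer", {"R": 1.0}),
            ("sink", {"R": -1.0, "W": -1.0}),
        ])
        assert classify_choke_points(net).label("t") == LABEL_NONE

    def test_motif_single_consuming(self):
        net = net_from([
            ("src", {"M": 1.0}),
            ("t", {"M": -1.0, "R": 1.0}),
            ("alt_producer", {"R": 1.0}),
            ("sink", {"R": -1.0}),
        ])
        cls = classify_choke_points(net)
        assert cls.label("t") == LABEL_SINGLE_CONSUMING
        assert cls.is_single_consuming["t"] and not cls.is_single_producing["t"]

    def test_motif_single_producing(self):
        net = net_from([
            ("src", {"L": 1.0}),
            ("t", {"L": -1.0, "M": 1.0}),
            ("alt_consumer", {"L": -1.0}),
            ("sink", {"M": -1.0}),
        ])
        cls = classify_choke_points(net)
        assert cls.label("t") == LABEL_SINGLE_PRODUCING

    def test_motif_double_not_extended(self):
        # t is exclusive on both sides, but m1 has two producers, neither
        # of which is a single choke point on the production side
        net = net_from([
            ("pa", {"m1": 1.0}),
            ("pb", {"m1": 1.0}),
            ("t", {"m1": -1.0, "m2": 1.0}),
            ("d", {"m2": -1.0, "T": 1.0}),
            ("sink", {"T": -1.0}),
        ])
        cls = classify_choke_points(net)
        assert cls.label("t") == LABEL_DOUBLE

    def test_motif_extended(self):
        # surrounded: upstream producer and downstream consumer are single
        # choke points themselves
        net = net_from([
            ("src", {"A": 1.0}),
            ("t", {"A": -1.0, "B": 1.0}),
            ("d", {"B": -1.0, "T": 1.0}),
            ("sink", {"T": -1.0}),
        ])
        cls = classify_choke_points(net)
        assert cls.label("t") == LABEL_EXTENDED

    def test_exists_mode_is_weaker_than_all(self):
        # m1 fed by one single-producing reaction and one that is not:
        # the all-quantifier refuses, the exists-quantifier accepts
        # pa is sole producer of q -> single_producing; pb is exclusive
        # on nothing (extra has a second producer) -> not single_producing
        net = net_from([
            ("pa", {"q": 1.0, "m1": 1.0}),
            ("pb", {"m1": 1.0, "extra": 1.0}),
            ("pc", {"extra": 1.0}),
            ("q_sink", {"q": -1.0}),
            ("extra_sink", {"extra": -1.0, "q2": 1.0}),
            ("q2_sink", {"q2": -1.0}),
            ("t", {"m1": -1.0, "m2": 1.0}),
            ("d", {"m2": -1.0}),
        ])
        strict = classify_choke_points(net, extended_mode="all")
        loose = classify_choke_points(net, extended_mode="exists")
        assert strict.label("t") == LABEL_DOUBLE
        assert loose.label("t") == LABEL_EXTENDED

    @pytest.mark.parametrize("mode", ["all", "exists"])
    def test_matches_bruteforce_on_random_networks(self, mode):
        rng = np.random.default_rng(29)
        for _ in range(200):
            n_rxn = int(rng.integers(3, 13))
            n_met = int(rng.integers(2, 9))
            S = np.zeros((n_met, n_rxn))
            for j in range(n_rxn):
                k = int(rng.integers(1, 4))
                mets = rng.choice(n_met, size=min(k, n_met), replace=False)
                for m in mets:
                    S[m, j] = rng.choice([-1.0, 1.0])
            keep = np.any(S != 0, axis=1)
            S = S[keep]
            mets = [f"M{i}" for i in range(S.shape[0])]
            net = ReducedNetwork([f"r{j}" for j in range(n_rxn)], mets, S,
                                 {f"r{j}": 1 for j in range(n_rxn)})
            got = classify_choke_points(net, extended_mode=mode).labels
            assert got == brute_force_labels(net, extended_mode=mode)

    def test_specificity_hierarchy_invariant(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            n_rxn, n_met = 8, 6
            S = rng.choice([-1.0, 0.0, 0.0, 1.0], size=(n_met, n_rxn))
            net = ReducedNetwork([f"r{j}" for j in range(n_rxn)],
                                 [f"M{i}" for i in range(n_met)], S,
                                 {f"r{j}": 1 for j in range(n_rxn)})
            cls = classify_choke_points(net)
            for r in net.reaction_ids:
                if cls.label(r) in (LABEL_DOUBLE, LABEL_EXTENDED):
                    assert cls.is_single_consuming[r]
                    assert cls.is_single_producing[r]


class TestReactionGraph:
    def test_chain_edges(self):
        net = net_from([
            ("r1", {"A": 1.0}),
            ("r2", {"A": -1.0, "B": 1.0}),
            ("r3", {"B": -1.0}),
        ])
        g = build_reaction_graph(net)
        assert set(g.edges) == {("r1", "r2"), ("r2", "r3")}

    def test_two_producers_one_consumer(self):
        net = net_from([
            ("p1", {"A": 1.0}),
            ("p2", {"A": 1.0}),
            ("c", {"A": -1.0}),
        ])
        g = build_reaction_graph(net)
        assert set(g.edges) == {("p1", "c"), ("p2", "c")}

    def test_reversed_flux_reverses_edges(self):
        model = make_model([
            ("EX_A", {"A": 1.0}, 0, 10),
            ("r1", {"A": -1.0, "B": 1.0}, -10, 10),
            ("r2", {"B": -1.0, "A": 1.0}, -10, 10),
        ])
        fwd = FluxDistribution(model.reaction_ids, np.array([0., 5., 5.]),
                               0.0, "f")
        rev = FluxDistribution(model.reaction_ids, np.array([0., -5., -5.]),
                               0.0, "r")
        g_fwd = build_reaction_graph(reduce_network(model, fwd))
        g_rev = build_reaction_graph(reduce_network(model, rev))
        assert set(g_rev.edges) == {(b, a) for a, b in g_fwd.edges}

    def test_invariant_under_metabolite_reordering(self):
        reactions = [
            ("r1", {"A": 1.0, "B": 1.0}),
            ("r2", {"B": -1.0, "C": 1.0}),
            ("r3", {"C": -1.0, "A": -1.0}),
        ]
        net1 = net_from(reactions)
        perm = [2, 0, 1]
        net2 = ReducedNetwork(net1.reaction_ids,
                              [net1.metabolite_ids[i] for i in perm],
                              net1.S[perm, :], net1.orientation)
        assert set(build_reaction_graph(net1).edges) == \
            set(build_reaction_graph(net2).edges)


def dense_pagerank_oracle(g, damping=0.85, tol=1e-12):
    """Dense power iteration, independent of networkx."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    P = np.zeros((n, n))
    for u in nodes:
        succ = list(g.successors(u))
        if succ:
            for v in succ:
                P[idx[u], idx[v]] = 1.0 / len(succ)
        else:
            P[idx[u], :] = 1.0 / n
    x = np.full(n, 1.0 / n)
    while True:
        x_new = damping * (x @ P) + (1 - damping) / n
        if np.abs(x_new - x).sum() < tol:
            return dict(zip(nodes, x_new))
        x = x_new


class TestPagerank:
    def test_three_cycle_is_uniform(self):
        g = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "a")])
        scores = pagerank(g)
        for v in scores.values():
            assert v == pytest.approx(1 / 3, abs=1e-9)

    def test_star_matches_dense_oracle(self):
        g = nx.DiGraph([("a", "hub"), ("b", "hub"), ("c", "hub")])
        scores = pagerank(g, damping=0.85)
        oracle = dense_pagerank_oracle(g, 0.85)
        for node in g.nodes:
            assert scores[node] == pytest.approx(oracle[node], abs=1e-10)

    def test_random_graphs_match_oracle_and_normalize(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            n = int(rng.integers(2, 12))
            g = nx.DiGraph()
            g.add_nodes_from(f"n{i}" for i in range(n))
            for i in range(n):
                for j in range(n):
                    if i != j and rng.random() < 0.3:
                        g.add_edge(f"n{i}", f"n{j}")
            scores = pagerank(g)
            oracle = dense_pagerank_oracle(g)
            assert sum(scores.values()) == pytest.approx(1.0, abs=1e-9)
            for node in g.nodes:
                assert scores[node] == pytest.approx(oracle[node], abs=1e-8)
                assert scores[node] >= 0

    def test_single_node(self):
        g = nx.DiGraph()
        g.add_node("only")
        assert pagerank(g) == {"only": 1.0}
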
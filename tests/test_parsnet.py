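"""Statistical-parsimony network construction."""

import itertools

import networkx as nx
import numpy as np
import pytest

from hapsurv.coalsim import SimConfig, simulate
from hapsurv.parsnet import (
    NetworkError,
    ParameterError,
    build_network,
    export_network,
    pairwise_differences,
    parsimony_limit,
    read_network_edges,
)
from hapsurv.seqio import Alignment, collapse_haplotypes

from conftest import simple_alignment


def table_of(seqs, outgroup=None):
    return collapse_haplotypes(simple_alignment(seqs, outgroup=outgroup, coding=()))


class TestPairwiseDifferences:
    def test_single_difference(self):
        d = pairwise_differences(table_of({"a": "AAA", "b": "AAT"}))
        assert d[0, 1] == d[1, 0] == 1 and d[0, 0] == 0

    def test_identical_pair(self):
        # cannot occur post-collapse, but the matrix is still defined
        ht = table_of({"a": "AAA", "b": "AAA"})
        assert pairwise_differences(ht).tolist() == [[0]]

    def test_hand_counted_triple(self):
        ht = table_of({"a": "ACGT", "b": "TCGA", "c": "ACGA"})
        d = pairwise_differences(ht)
        by_seq = {s: i for i, s in enumerate(ht.haplotypes)}
        i, j, k = by_seq["ACGT"], by_seq["TCGA"], by_seq["ACGA"]
        assert d[i, j] == 2 and d[i, k] == 1 and d[j, k] == 1


class TestParsimonyLimit:
    def test_override_passthrough(self):
        assert parsimony_limit(721, override=10) == 10

    def test_bad_override(self):
        with pytest.raises(ParameterError):
            parsimony_limit(721, override=0)

    def test_bad_alpha(self):
        with pytest.raises(ParameterError):
            parsimony_limit(721, alpha=1.5)

    def test_at_least_one_step(self):
        assert parsimony_limit(10, 0.95) >= 1

    def test_monotone_in_length(self):
        limits = [parsimony_limit(m) for m in (100, 300, 721, 1500)]
        assert limits == sorted(limits)

    def test_frozen_regression_values(self):
        # computed once from the multiple-hit model and frozen
        assert parsimony_limit(721, 0.95) == 10
        assert parsimony_limit(81, 0.95) == 3


class TestBuildNetwork:
    def test_two_haplotypes_one_step(self):
        net = build_network(table_of({"a": "AAA", "b": "AAT"}), limit=5)
        g = net.graph
        assert g.number_of_edges() == 1
        assert set(net.node_class.values()) == {"tip"}

    def test_chain_of_three(self):
        # d(A,B)=1, d(B,C)=1, d(A,C)=2 -> chain A-B-C with B interior
        ht = table_of({"a": "AAA", "b": "AAT", "c": "ACT"})
        net = build_network(ht, limit=5)
        g = net.graph
        assert g.number_of_edges() == 2
        classes = net.node_class
        mid = ht.ids[ht.haplotypes.index("AAT")]
        assert classes[mid] == "interior"
        assert sum(1 for c in classes.values() if c == "tip") == 2

    def test_limit_excludes_distant_pair(self):
        net = build_network(table_of({"a": "AAAA", "b": "TTTT"}), limit=3)
        assert net.graph.number_of_edges() == 0
        assert len(net.components) == 2
        # isolated observed nodes classify as tips
        assert set(net.node_class.values()) == {"tip"}

    def test_intermediates_inserted(self):
        net = build_network(table_of({"a": "AAAA", "b": "AATT"}), limit=5)
        g = net.graph
        inferred = [n for n, o in g.nodes(data="observed") if not o]
        assert len(inferred) == 1 and g.degree(inferred[0]) == 2

    def test_empty_table_raises(self):
        from hapsurv.seqio import HaplotypeTable

        empty = HaplotypeTable(haplotypes=(), counts=(), members=(), n=0,
                               h=0, site_index=())
        with pytest.raises(NetworkError):
            build_network(empty, limit=3)

    def test_deterministic(self):
        seqs = {"a": "ACGTA", "b": "ACGTT", "c": "AGGTT", "d": "TCGTA"}
        nets = [build_network(table_of(seqs), limit=5) for _ in range(2)]
        e1 = {tuple(sorted(e)) for e in nets[0].graph.edges}
        e2 = {tuple(sorted(e)) for e in nets[1].graph.edges}
        assert e1 == e2


class TestExport:
    def test_roundtrip_isomorphic(self, tmp_path):
        ht = table_of({"a": "AAAA", "b": "AATT", "c": "AATA"})
        net = build_network(ht, limit=5)
        path = tmp_path / "net.tsv"
        export_network(net, path)
        g2 = read_network_edges(path)
        assert nx.is_isomorphic(net.graph, g2)
        text = path.read_text()
        assert "#nodes" in text and "#edges" in text

    def test_inferred_node_flagged(self, tmp_path):
        net = build_network(table_of({"a": "AAAA", "b": "AATT"}), limit=5)
        path = tmp_path / "net.tsv"
        export_network(net, path)
        rows = [l.split("\t") for l in path.read_text().splitlines()
                if l.startswith("I")]
        assert rows and all(r[1] == "0" and r[3] == "inferred" for r in rows)

    def test_graphml(self, tmp_path):
        net = build_network(table_of({"a": "AAAA", "b": "AATA"}), limit=5)
        path = tmp_path / "net.graphml"
        export_network(net, path, graphml=True)
        g2 = nx.read_graphml(path)
        assert g2.number_of_nodes() == net.graph.number_of_nodes()


def steiner_minimal_edges(haplotypes):
    """Brute-force minimum edge count of a connected single-step network.

    Enumerates candidate intermediates over the cartesian product of
    observed states per variable site; feasible only for tiny inputs.
    """
    L = len(haplotypes[0])
    var_sites = [i for i in range(L) if len({h[i] for h in haplotypes}) > 1]
    pools = [sorted({h[i] for h in haplotypes}) for i in var_sites]
    template = haplotypes[0]
    candidates = set()
    for combo in itertools.product(*pools):
        seq = list(template)
        for site, state in zip(var_sites, combo):
            seq[site] = state
        candidates.add("".join(seq))
    candidates -= set(haplotypes)

    def connected_edge_count(nodes):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in itertools.combinations(nodes, 2):
            if sum(a != b for a, b in zip(u, v)) == 1:
                g.add_edge(u, v)
        if not nx.is_connected(g):
            return None
        # minimal single-step connection uses a spanning tree
        return len(nodes) - 1

    best = None
    for k in range(len(candidates) + 1):
        for extra in itertools.combinations(sorted(candidates), k):
            e = connected_edge_count(list(haplotypes) + list(extra))
            if e is not None:
                best = e
                break
        if best is not None:
            break
    return best


class TestMinimalConnection:
    # seeds drawn once, keeping every replicate with 2..6 haplotypes and
    # few enough variable sites for the exhaustive search to be feasible
    @pytest.mark.parametrize("seed", [1, 3, 8, 10, 11, 12, 15, 17, 18, 22])
    def test_matches_exhaustive_search_on_small_samples(self, seed):
        """On homoplasy-free data the network attains the Steiner-minimal
        edge count found by exhaustive search (<= 6 haplotypes)."""
        cfg = SimConfig(n=6, L=60, theta=2.0, outgroup_divergence=0.0, seed=seed)
        rep = simulate(cfg)
        ht = collapse_haplotypes(rep.alignment)
        assert 2 <= ht.h <= 6
        net = build_network(ht, limit=60)
        expected = steiner_minimal_edges(tuple(ht.haplotypes))
        assert net.graph.number_of_edges() == expected

    def test_perfect_phylogeny_is_tree(self):
        """Simulated infinite-sites data yield a tree whose edges biject
        with the segregating sites."""
        for seed in range(5):
            rep = simulate(SimConfig(seed=100 + seed, outgroup_divergence=0.0))
            ht = collapse_haplotypes(rep.alignment)
            net = build_network(ht, limit=len(ht.site_index))
            g = net.graph
            assert nx.is_tree(g)
            sites = [g.edges[e]["site"] for e in g.edges]
            assert len(sites) == len(set(sites))
            # every segregating site appears on exactly one edge
            seg = {
                i for i in range(len(ht.site_index))
                if len({h[i] for h in ht.haplotypes}) > 1
            }
            assert set(sites) == seg
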
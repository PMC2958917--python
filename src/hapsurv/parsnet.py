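"""Statistical-parsimony (TCS-style) haplotype networks.

Haplotypes are connected through single-mutation edges, inserting
unsampled intermediate nodes where needed, as long as the mutational
distance between the endpoints does not exceed a connection limit.  The
limit is the largest number of steps for which a multiple-hit model puts
the probability of a homoplasy-free (parsimonious) connection at or above
the requested confidence (95% by default).

The probability model: with ``j`` observed differences over ``m``
analyzed columns, per-site substitution counts are Poisson with mean
``lam`` obtained from the Jukes-Cantor correction of ``p = j/m``.  A
connection at ``j`` steps is parsimonious when every observed difference
is due to exactly one substitution, so

``P(j, m) = P(exactly 1 hit | visibly different)^j``.

Ambiguous alternative connections are resolved deterministically:
candidate pairs are processed in increasing distance, preferring pairs
whose endpoints have higher sample counts, then higher current degree,
then lexicographic node order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .seqio import EmptyInputError, HaplotypeTable, HapsurvError

logger = logging.getLogger("hapsurv")


class ParameterError(HapsurvError):
    """Invalid parameter value."""


class NetworkError(HapsurvError):
    """Network construction failed or was given an empty table."""


def pairwise_differences(ht: HaplotypeTable) -> np.ndarray:
    """Symmetric matrix of Hamming distances between haplotypes."""
    if ht.h == 0:
        raise EmptyInputError("empty haplotype table")
    mat = np.frombuffer("".join(ht.haplotypes).encode(), dtype="S1").reshape(
        ht.h, len(ht.site_index)
    )
    return (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(int)


def _parsimony_probability(j: int, m: int) -> float:
    p = j / m
    if p >= 0.75:
        return 0.0
    lam = -0.75 * math.log1p(-4.0 * p / 3.0)
    if lam == 0.0:
        return 1.0
    p_diff = 0.75 * (1.0 - math.exp(-4.0 * lam / 3.0))
    p_one = lam * math.exp(-lam)
    return (p_one / p_diff) ** j


def parsimony_limit(n_columns: int, alpha: float = 0.95, override: int | None = None) -> int:
    """Largest step count with parsimonious-connection probability >= alpha.

    One step is always accepted.  ``override`` bypasses the computation.
    """
    if override is not None:
        if override < 1:
            raise ParameterError("override must be >= 1")
        return int(override)
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must lie in (0, 1)")
    if n_columns < 1:
        raise ParameterError("n_columns must be >= 1")
    j = 1
    while j + 1 <= n_columns and _parsimony_probability(j + 1, n_columns) >= alpha:
        j += 1
    return j


@dataclass
class ParsimonyNetwork:
    """Observed haplotypes plus inferred intermediates, single-step edges.

    Node attributes: ``seq`` (analyzed-column sequence), ``count``
    (0 for inferred nodes), ``observed`` (bool).  Edge attribute ``site``
    is the index into the analyzed columns where the endpoints differ;
    the state pair follows from the endpoint sequences.
    """

    graph: nx.Graph
    connection_limit: int
    site_index: tuple[int, ...] = ()
    source: HaplotypeTable | None = field(default=None, repr=False)
    #: component root node per component (keyed by min node id), set by
    #: mutmap.orient_mutations
    roots: dict[str, str] | None = field(default=None, repr=False)

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    @property
    def node_class(self) -> dict[str, str]:
        """Observed nodes are tips iff their degree is <= 1."""
        return {
            node: ("tip" if self.graph.degree(node) <= 1 else "interior")
            for node, obs in self.graph.nodes(data="observed")
            if obs
        }

    def edge_states(self, u: str, v: str) -> tuple[int, str, str]:
        site = self.graph.edges[u, v]["site"]
        return site, self.graph.nodes[u]["seq"][site], self.graph.nodes[v]["seq"][site]


def _diff_sites(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


def build_network(ht: HaplotypeTable, limit: int) -> ParsimonyNetwork:
    """Agglomerative statistical-parsimony network construction.

    Candidate haplotype pairs are processed in increasing mutational
    distance; a pair at distance ``d <= limit`` is connected through
    ``d - 1`` intermediates unless a path of length <= ``d`` already
    exists.  Pairs beyond ``limit`` stay in separate components.
    """
    if limit < 1:
        raise ParameterError("limit must be >= 1")
    if ht.h == 0:
        raise NetworkError("cannot build a network from an empty haplotype table")

    g = nx.Graph()
    ids = list(ht.ids)
    seq_to_node: dict[str, str] = {}
    for hid, seq, cnt in zip(ids, ht.haplotypes, ht.counts):
        g.add_node(hid, seq=seq, count=cnt, observed=True)
        seq_to_node[seq] = hid

    dmat = pairwise_differences(ht)
    counts = dict(zip(ids, ht.counts))
    n_inferred = 0

    def node_for(seq: str) -> str:
        nonlocal n_inferred
        node = seq_to_node.get(seq)
        if node is None:
            n_inferred += 1
            node = f"I{n_inferred}"
            g.add_node(node, seq=seq, count=0, observed=False)
            seq_to_node[seq] = node
        return node

    obs_mat = np.frombuffer("".join(ht.haplotypes).encode(), dtype="S1").reshape(
        ht.h, len(ht.site_index)
    )
    obs_counts = np.asarray(ht.counts)
    outgroup = ht.outgroup_restricted

    def connect(u: str, v: str) -> None:
        """Join u and v through a chain of single-step intermediates.

        Sites are flipped in ascending order of the number of sampled
        individuals sharing u's state: the carriers of u's state at a
        path mutation are exactly the haplotypes on u's side of that
        edge, which grow monotonically along the true path, so this
        order reconstructs (and reuses) the ancestral intermediates
        exactly on homoplasy-free data.
        """
        su, sv = g.nodes[u]["seq"], g.nodes[v]["seq"]
        # anchor the chain at the higher-count endpoint for determinism
        if (counts.get(v, 0), sv) > (counts.get(u, 0), su):
            u, v, su, sv = v, u, sv, su
        sites = _diff_sites(su, sv)
        carrier = {
            s: int(obs_counts[obs_mat[:, s] == su[s].encode()].sum()) for s in sites
        }
        # per-site putative ancestral state, direction-independent: the
        # outgroup state when it matches one of the two endpoint states,
        # otherwise the majority state
        anc_state = {}
        for s in sites:
            a, b = su[s], sv[s]
            if outgroup is not None and outgroup[s] in (a, b):
                anc_state[s] = outgroup[s]
            else:
                ca = carrier[s]
                cb = int(obs_counts[obs_mat[:, s] == b.encode()].sum())
                anc_state[s] = a if ca > cb else b if cb > ca else min(a, b)

        def order_key(s: int, cur: str) -> tuple:
            # primary: carrier count of the current state (monotone along the
            # true path on homoplasy-free data); tie-break: undo putatively
            # derived states before applying new ones, so chains pass
            # through the ancestral sequence
            return carrier[s], 0 if cur[s] != anc_state[s] else 1

        prev = u
        cur = su
        remaining = list(sites)
        while remaining:
            # among minimal-key sites prefer a flip that reuses an existing
            # node (keeps re-walked segments direction-independent), then
            # the lowest site index
            low = min(order_key(s, cur) for s in remaining)
            ties = [s for s in sorted(remaining) if order_key(s, cur) == low]
            site, cur_next = ties[0], None
            for s in ties:
                cand = cur[:s] + sv[s] + cur[s + 1 :]
                if cur_next is None:
                    site, cur_next = s, cand
                if cand in seq_to_node:
                    site, cur_next = s, cand
                    break
            cur = cur_next
            remaining.remove(site)
            nxt = node_for(cur)
            if prev != nxt and not g.has_edge(prev, nxt):
                g.add_edge(prev, nxt, site=site)
            prev = nxt

    by_distance: dict[int, list[tuple[str, str]]] = {}
    for i in range(ht.h):
        for k in range(i + 1, ht.h):
            d = int(dmat[i, k])
            if 0 < d <= limit:
                by_distance.setdefault(d, []).append((ids[i], ids[k]))

    for d in sorted(by_distance):
        pending = list(by_distance[d])
        while pending:
            # deterministic preference: higher endpoint counts, then more
            # interior endpoints (current degree), then lexicographic ids
            def key(pair: tuple[str, str]):
                u, v = pair
                cu, cv = counts[u], counts[v]
                du, dv = g.degree(u), g.degree(v)
                return (-max(cu, cv), -(cu + cv), -max(du, dv), -(du + dv), u, v)

            pending.sort(key=key)
            u, v = pending.pop(0)
            try:
                if nx.shortest_path_length(g, u, v) <= d:
                    continue
            except nx.NetworkXNoPath:
                pass
            connect(u, v)

    net = ParsimonyNetwork(
        graph=g, connection_limit=limit, site_index=ht.site_index, source=ht
    )
    n_comp = nx.number_connected_components(g)
    if n_comp > 1:
        logger.info("network split into %d components at limit %d", n_comp, limit)
    return net


def export_network(net: ParsimonyNetwork, path, graphml: bool = False) -> None:
    """Write the network as TSV edge list + node table (or GraphML)."""
    if graphml:
        g = nx.Graph()
        for node, data in net.graph.nodes(data=True):
            g.add_node(node, seq=data["seq"], count=data["count"], observed=data["observed"])
        for u, v, data in net.graph.edges(data=True):
            g.add_edge(u, v, site=data["site"])
        nx.write_graphml(g, str(path))
        return
    node_class = net.node_class
    with open(path, "w") as fh:
        fh.write("#nodes\nnode\tcount\tobserved\tclass\tsequence\n")
        for node in sorted(net.graph.nodes):
            d = net.graph.nodes[node]
            cls = node_class.get(node, "inferred")
            fh.write(f"{node}\t{d['count']}\t{int(d['observed'])}\t{cls}\t{d['seq']}\n")
        fh.write("#edges\nnode1\tnode2\tsite\tstates\n")
        for u, v in sorted(net.graph.edges):
            site, a, b = net.edge_states(u, v)
            col = net.site_index[site] + 1 if net.site_index else site + 1
            fh.write(f"{u}\t{v}\t{col}\t{a}/{b}\n")


def read_network_edges(path) -> nx.Graph:
    """Reconstruct the graph from an exported TSV edge list (round-trip aid)."""
    g = nx.Graph()
    section = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                section = line[1:]
                continue
            if not line or line.startswith(("node\t", "node1\t")):
                continue
            parts = line.split("\t")
            if section == "nodes":
                g.add_node(
                    parts[0],
                    count=int(parts[1]),
                    observed=bool(int(parts[2])),
                    seq=parts[4],
                )
            elif section == "edges":
                g.add_edge(parts[0], parts[1], site=int(parts[2]) - 1)
    return g
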
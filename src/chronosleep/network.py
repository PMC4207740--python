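"""Seed-gene shortest-path subnetworks and hypergeometric term enrichment.

The network model follows the most stringent shortest-path setting: a
non-seed node is admitted only if it lies on a seed-connector-seed path
(at most one intermediate step between seeds), and only edges on admitted
paths are kept.  Term enrichment is the hypergeometric upper tail
P(X >= k) for the overlap k between a query set and each term set drawn
from a finite universe, BH-adjusted across terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def normalize_id(name: str) -> str:
    return str(name).strip().upper()


@dataclass
class InteractionGraph:
    """Case-normalized molecular interaction graph (undirected by default)."""

    graph: nx.Graph

    @classmethod
    def from_edges(cls, edges, directed: bool = False, synonyms: dict | None = None):
        """Build from an iterable of (source, target[, ...]) pairs.

        Self-loops are dropped; identifiers are upper-cased and optionally
        mapped through a synonym table before normalization.
        """
        syn = {normalize_id(k): normalize_id(v) for k, v in (synonyms or {}).items()}

        def canon(name):
            n = normalize_id(name)
            return syn.get(n, n)

        g = nx.DiGraph() if directed else nx.Graph()
        dropped = 0
        for row in edges:
            a, b = canon(row[0]), canon(row[1])
            if a == b:
                dropped += 1
                continue
            g.add_edge(a, b)
        if dropped:
            logger.info("dropped %d self-loop edges", dropped)
        return cls(graph=g)

    @property
    def nodes(self):
        return set(self.graph.nodes)


@dataclass
class NetworkModel:
    """Seeds plus admitted connectors and the edges of admitted paths."""

    seed_nodes: set
    connector_nodes: set
    edges: set  # frozenset pairs for undirected, tuples for directed
    missing_seeds: set = field(default_factory=set)

    @property
    def nodes(self) -> set:
        return self.seed_nodes | self.connector_nodes


def shortest_path_network(
    graph: InteractionGraph, seeds, max_intermediates: int = 1
) -> NetworkModel:
    """Build the seed subnetwork with at most one connector per seed pair.

    The model contains every seed present in the graph, all direct
    seed-seed edges and, when ``max_intermediates`` is 1, every non-seed
    node adjacent to two or more distinct seeds together with the edges of
    those seed-connector-seed paths.  Seeds absent from the graph are
    reported in ``missing_seeds``, not fatal.
    """
    seeds = {normalize_id(s) for s in seeds}
    if not seeds:
        raise ValueError("empty seed set")
    if max_intermediates not in (0, 1):
        raise ValueError("max_intermediates must be 0 or 1 (the most stringent settings)")
    g = graph.graph
    directed = g.is_directed()
    present = seeds & set(g.nodes)
    missing = seeds - present

    edges: set = set()
    connectors: set = set()

    def pack(a, b):
        return (a, b) if directed else frozenset((a, b))

    for s in sorted(present):
        for t in g.successors(s) if directed else g.neighbors(s):
            if t in present:
                edges.add(pack(s, t))
    if max_intermediates == 1:
        candidates = set()
        for s in present:
            candidates.update(g.successors(s) if directed else g.neighbors(s))
        for v in sorted(candidates - present):
            if directed:
                ins = {s for s in g.predecessors(v) if s in present}
                outs = {t for t in g.successors(v) if t in present}
                # admitted iff some directionally consistent seed s -> v -> t, s != t
                if any(s != t for s in ins for t in outs):
                    connectors.add(v)
                    for s in ins:
                        if any(t != s for t in outs):
                            edges.add((s, v))
                    for t in outs:
                        if any(s != t for s in ins):
                            edges.add((v, t))
            else:
                seed_neighbors = {s for s in g.neighbors(v) if s in present}
                if len(seed_neighbors) >= 2:
                    connectors.add(v)
                    for s in seed_neighbors:
                        edges.add(pack(v, s))
    return NetworkModel(
        seed_nodes=present, connector_nodes=connectors, edges=edges, missing_seeds=missing
    )


@dataclass
class TermCollection:
    """Named gene sets with GMT semantics (term -> member set)."""

    terms: dict
    descriptions: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, terms: dict):
        return cls(terms={k: {normalize_id(g) for g in v} for k, v in terms.items()})


def hypergeometric_enrichment(query, terms: TermCollection, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each term set.

    Query and term genes are intersected with the universe first (dropped
    query genes are logged).  Returns a DataFrame indexed by term with
    columns ``term_size``, ``overlap``, ``p_value``, ``p_adjusted``,
    sorted by p-value.
    """
    universe = {normalize_id(g) for g in universe}
    if not universe:
        raise ValueError("empty universe")
    query = {normalize_id(g) for g in query}
    dropped = len(query - universe)
    if dropped:
        logger.info("dropped %d query genes outside the universe", dropped)
    query &= universe
    if not query:
        raise ValueError("query is empty after intersection with the universe")
    N, n = len(universe), len(query)
    rows = []
    for term in sorted(terms.terms):
        members = {normalize_id(g) for g in terms.terms[term]} & universe
        K = len(members)
        k = len(members & query)
        p = float(sst.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"term": term, "term_size": K, "overlap": k, "p_value": min(p, 1.0)})
    table = pd.DataFrame(rows).set_index("term")
    table["p_adjusted"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    return table.sort_values("p_value", kind="mergesort")
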
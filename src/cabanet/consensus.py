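"""Seven-algorithm community-detection consensus on the association network.

The stable edges from the graphical-Markov stage form a weighted undirected
association graph (weight = bootstrap selection frequency).  Seven classical
community-detection algorithms partition it — edge betweenness, leading
eigenvector, fast-greedy modularity, Louvain (fast unfolding), label
propagation, walktrap, and infomap — and an explanatory factor is declared
associated with a response variable when the two fall in the same community
in at least ``min_models`` of the seven partitions (default 4).  A separate
sign rule calls the direction of an association positive when the bootstrap
positive-sign frequency reaches ``causality_threshold`` (default 80%).

The seven partitioners are delegated to igraph; the graph construction,
co-clustering vote and consensus table are implemented here.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .gm import AnalysisConfig, StabilityResult

logger = logging.getLogger(__name__)

SEVEN_MODELS = (
    "edge_betweenness",
    "leading_eigenvector",
    "fast_greedy",
    "louvain",
    "label_propagation",
    "walktrap",
    "infomap",
)


@dataclass
class ConsensusConfig:
    min_models: int = 4
    causality_threshold: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.min_models <= 7:
            raise ValueError("min_models must be in 1..7")
        if not 0.0 < self.causality_threshold <= 1.0:
            raise ValueError("causality_threshold must be in (0, 1]")


@dataclass
class Partition:
    model_name: str
    membership: dict[str, int]
    note: str = ""

    def same_community(self, a: str, b: str) -> bool:
        return (a in self.membership and b in self.membership
                and self.membership[a] == self.membership[b])


def build_association_graph(result: StabilityResult,
                            config: AnalysisConfig | None = None) -> nx.Graph:
    """Association network handed to the clustering stage.

    Nodes are the variables incident to at least one retained edge; edges are
    the pairs whose bootstrap selection frequency exceeds 1/2, weighted by
    that frequency.  An empty selection produces an empty graph (clustering
    is then skipped with a warning).
    """
    g = nx.Graph()
    for pair, (sel, pos) in result.counts.items():
        freq = sel / result.B
        if freq > 0.5:
            a, b = sorted(pair)
            g.add_edge(a, b, weight=freq,
                       positive_fraction=pos / sel if sel else float("nan"))
    if g.number_of_edges() == 0:
        logger.warning("no edges exceed frequency 0.5; association graph is empty")
    return g


def _to_igraph(graph: nx.Graph) -> tuple[ig.Graph, list[str]]:
    nodes = sorted(graph.nodes())
    index = {v: k for k, v in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in graph.edges()]
    weights = [graph[a][b].get("weight", 1.0) for a, b in graph.edges()]
    h = ig.Graph(n=len(nodes), edges=edges)
    h.es["weight"] = weights
    return h, nodes


def _run_model(name: str, h: ig.Graph, seed: int):
    w = h.es["weight"] if h.ecount() else None
    random.seed(seed)  # igraph's stochastic models draw from Python's random
    if name == "edge_betweenness":
        # betweenness treats weights as distances (strong ties = short paths);
        # the dendrogram is then cut at maximum *weighted* modularity, since
        # igraph would otherwise score cuts with the distance weights
        dist = [1.0 / x for x in w] if w else None
        dendro = h.community_edge_betweenness(weights=dist)
        best, best_q = None, -np.inf
        for n_comm in range(1, h.vcount() + 1):
            try:
                cand = dendro.as_clustering(n=n_comm)
            except Exception:  # noqa: BLE001 - cut levels beyond the merge history
                continue
            q = h.modularity(cand.membership, weights=w)
            if q > best_q + 1e-12:
                best, best_q = cand, q
        return best
    if name == "leading_eigenvector":
        return h.community_leading_eigenvector(weights=w)
    if name == "fast_greedy":
        return h.community_fastgreedy(weights=w).as_clustering()
    if name == "louvain":
        return h.community_multilevel(weights=w)
    if name == "label_propagation":
        return h.community_label_propagation(weights=w)
    if name == "walktrap":
        return h.community_walktrap(weights=w).as_clustering()
    if name == "infomap":
        return h.community_infomap(edge_weights=w)
    raise ValueError(f"unknown clustering model {name!r}")


def partition_all(graph: nx.Graph,
                  config: ConsensusConfig | None = None) -> list[Partition]:
    """Run all seven community-detection models on the weighted graph.

    Node order is canonicalized (lexicographic) and the stochastic models are
    seeded from ``config.seed``, so the result is reproducible and invariant
    to the input ordering.  Dendrogram-producing models are cut at maximum
    modularity.  A degenerate graph (no edges / single node) yields the
    trivial one-community-per-component partition from every model, with a
    note.
    """
    config = config or ConsensusConfig()
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    h, nodes = _to_igraph(graph)
    components = h.connected_components()
    partitions = []
    for k, name in enumerate(SEVEN_MODELS):
        membership: dict[str, int] = {}
        note = ""
        offset = 0
        for comp in components:
            sub = h.induced_subgraph(comp)
            if sub.ecount() == 0 or sub.vcount() == 1:
                for v in comp:
                    membership[nodes[v]] = offset
                    offset += 1
                note = "degenerate component(s): trivial partition"
                continue
            clustering = _run_model(name, sub, seed=config.seed * 1000 + k)
            for local, orig in enumerate(comp):
                membership[nodes[orig]] = offset + int(clustering.membership[local])
            offset += max(clustering.membership) + 1
        if note:
            logger.info("model %s: %s", name, note)
        partitions.append(Partition(name, membership, note=note))
    return partitions


def cocluster_counts(partitions: list[Partition],
                     factors: list[str],
                     responses: list[str],
                     positive_fraction: dict[frozenset, float] | None = None,
                     ) -> pd.DataFrame:
    """Co-clustering vote table: the machine twin of a clustering-results table.

    ``count(f, r)`` is the number of partitions (0..7) in which factor f and
    response r share a community.  Factors absent from the partitioned node
    set count 0 (noted in the log).  When ``positive_fraction`` (pair ->
    bootstrap positive-sign frequency) is given, a ``positive_<r>`` column is
    added per response.
    """
    node_set = set(partitions[0].membership) if partitions else set()
    rows = []
    for f in factors:
        if f not in node_set:
            logger.info("factor %r absent from the association graph; count 0", f)
        row: dict = {"factor": f}
        for r in responses:
            row[f"count_{r}"] = sum(p.same_community(f, r) for p in partitions)
            if positive_fraction is not None:
                row[f"positive_{r}"] = positive_fraction.get(frozenset((f, r)), float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def consensus_factors(table: pd.DataFrame,
                      config: ConsensusConfig | None = None) -> dict[str, list[tuple[str, int]]]:
    """Factors associated with each response by the >=min_models rule.

    Returns, per response, the (factor, count) pairs with count >=
    ``min_models``, ordered by count descending then factor name.
    """
    config = config or ConsensusConfig()
    out: dict[str, list[tuple[str, int]]] = {}
    count_cols = [c for c in table.columns if c.startswith("count_")]
    for col in count_cols:
        response = col[len("count_"):]
        hits = [(row["factor"], int(row[col]))
                for _, row in table.iterrows() if row[col] >= config.min_models]
        hits.sort(key=lambda t: (-t[1], t[0]))
        out[response] = hits
    return out


def causality_call(positive_frequency: float,
                   config: ConsensusConfig | None = None) -> str:
    """Direction call for an association: 'positive' iff the bootstrap
    positive-sign frequency reaches the causality threshold (inclusive)."""
    config = config or ConsensusConfig()
    if not 0.0 <= positive_frequency <= 1.0:
        raise ValueError("positive_frequency must be in [0, 1]")
    return "positive" if positive_frequency >= config.causality_threshold else "not-positive"
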
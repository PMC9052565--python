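"""File formats: cohort CSV + JSON data dictionary, edge-list TSV, GraphML,
partition JSON, config YAML/JSON."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .cohort import PlantedEdge, PlantedGraph, VariableSpec


def write_cohort(table: pd.DataFrame, path: str | Path,
                 dictionary: list[VariableSpec] | None = None) -> None:
    """Cohort as CSV (header row, one row per patient, empty = missing) with a
    sidecar ``<stem>.dictionary.json`` when a dictionary is given."""
    path = Path(path)
    table.to_csv(path, index=False, na_rep="")
    if dictionary is not None:
        side = path.with_suffix(".dictionary.json")
        side.write_text(json.dumps([dataclasses.asdict(v) for v in dictionary], indent=1))


def read_cohort(path: str | Path) -> tuple[pd.DataFrame, list[VariableSpec] | None]:
    path = Path(path)
    table = pd.read_csv(path)
    if table.shape[1] < 2 or len(table) == 0:
        raise ValueError(f"malformed cohort CSV: {path}")
    side = path.with_suffix(".dictionary.json")
    dictionary = None
    if side.exists():
        dictionary = [VariableSpec(**d) for d in json.loads(side.read_text())]
    return table, dictionary


def write_planted_graph(graph: PlantedGraph, tsv_path: str | Path,
                        graphml_path: str | Path | None = None) -> None:
    rows = [{"source": e.source, "target": e.target,
             "sign": e.sign, "effect_size": e.effect_size} for e in graph.edges]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if graphml_path is not None:
        g = nx.Graph()
        g.add_nodes_from(graph.nodes)
        for e in graph.edges:
            g.add_edge(e.source, e.target, sign=e.sign, effect_size=e.effect_size)
        nx.write_graphml(g, graphml_path)


def read_planted_graph(tsv_path: str | Path) -> PlantedGraph:
    df = pd.read_csv(tsv_path, sep="\t")
    edges = [PlantedEdge(r.source, r.target, r.sign, float(r.effect_size))
             for r in df.itertuples()]
    nodes = sorted({n for e in edges for n in (e.source, e.target)})
    return PlantedGraph(nodes=nodes, edges=edges)


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)


def write_partitions(partitions, path: str | Path) -> None:
    payload = {p.model_name: p.membership for p in partitions}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
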
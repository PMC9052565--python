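"""End-to-end orchestration: simulate -> encode -> stability selection at each
alpha -> consensus clustering -> Kaplan-Meier subgroups -> recovery scoring.

Both alpha levels (0.05 and 0.01) run by default, so one invocation produces
the full twin structure of the emulated study's result tables: a stable-edge
table per alpha, a clustering consensus table per alpha, and the subgroup
survival comparisons.  Every stage is seeded; a stage failure is recorded in
the report and downstream-dependent stages are skipped while independent
stages still run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .cohort import (CohortConfig, PlantedGraph, default_config,
                     generate_cohort, recovery_metrics, summarize_cohort,
                     variable_dictionary)
from .consensus import (ConsensusConfig, build_association_graph,
                        cocluster_counts, consensus_factors, partition_all)
from .encode import encode_table
from .gm import AnalysisConfig, select_stable_edges, stability_run
from .survival import subgroup_analysis, subgroup_frame

logger = logging.getLogger(__name__)

RESPONSE_NODES = ("os_days", "ttf_days")


@dataclass
class PipelineConfig:
    cohort: CohortConfig | str = field(default_factory=default_config)
    alphas: tuple[float, ...] = (0.05, 0.01)
    iterations: int = 1000
    min_count: int | None = None  # default: iterations // 2
    max_cond_size: int = 3
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alphas:
            raise ValueError("at least one alpha level is required")

    def analysis_config(self, alpha: float) -> AnalysisConfig:
        min_count = self.min_count if self.min_count is not None else self.iterations // 2
        return AnalysisConfig(alpha=alpha, iterations=self.iterations,
                              min_count=min_count, max_cond_size=self.max_cond_size,
                              seed=self.seed)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        return repr(o)
    payload = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Execute every stage and return the run report.

    The report maps stage names to their outputs (DataFrames and dataclasses)
    plus a provenance block; when ``config.out_dir`` is set all artifacts are
    also written to disk (CSV/TSV/GraphML/JSON).
    """
    config = config or PipelineConfig()
    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "provenance": {
            "seed": config.seed,
            "alphas": list(config.alphas),
            "iterations": config.iterations,
            "config_hash": _config_hash(config),
        },
        "errors": {},
        "alphas": {},
    }

    # --- cohort -----------------------------------------------------------------
    truth: PlantedGraph | None = None
    if isinstance(config.cohort, (str, Path)):
        table, dictionary = io.read_cohort(config.cohort)
        if dictionary is None:
            raise ValueError("a data dictionary sidecar is required for CSV input")
    else:
        table, truth = generate_cohort(config.cohort, seed=config.seed)
        dictionary = variable_dictionary(config.cohort)
        if out_dir is not None:
            io.write_cohort(table, out_dir / "cohort.csv", dictionary)
            io.write_planted_graph(truth, out_dir / "planted_graph.tsv",
                                   out_dir / "planted_graph.graphml")
    report["summary"] = summarize_cohort(table)

    encoded, enc_report = encode_table(table, dictionary)
    report["encoding"] = enc_report

    # --- stability selection + clustering, per alpha ------------------------------
    for alpha in config.alphas:
        acfg = config.analysis_config(alpha)
        entry: dict = {}
        report["alphas"][alpha] = entry
        try:
            stab = stability_run(encoded, acfg)
            selection = select_stable_edges(stab, acfg)
            entry["stability"] = stab
            entry["selection"] = selection
            entry["selection_table"] = selection.to_frame()
            if out_dir is not None:
                tag = f"alpha{alpha:g}".replace(".", "")
                io.write_tsv(stab.to_frame(), out_dir / f"stability_{tag}.tsv")
                io.write_tsv(selection.to_frame(), out_dir / f"edges_{tag}.tsv")
        except Exception as exc:  # noqa: BLE001 - stage isolation
            logger.exception("stability stage failed at alpha %s", alpha)
            report["errors"][f"stability_{alpha}"] = str(exc)
            continue

        try:
            assoc = build_association_graph(stab, acfg)
            entry["association_graph"] = assoc
            if assoc.number_of_edges() == 0:
                logger.warning("alpha %s: empty association graph; clustering skipped", alpha)
                report["errors"][f"cluster_{alpha}"] = "empty association graph"
            else:
                partitions = partition_all(assoc, config.consensus)
                factors = sorted(n for n in assoc.nodes() if n not in RESPONSE_NODES)
                pos = {pair: (pos_cnt / sel if sel else float("nan"))
                       for pair, (sel, pos_cnt) in stab.counts.items()}
                ctab = cocluster_counts(partitions, factors, list(RESPONSE_NODES), pos)
                entry["partitions"] = partitions
                entry["consensus_table"] = ctab
                entry["consensus_factors"] = consensus_factors(ctab, config.consensus)
                if out_dir is not None:
                    tag = f"alpha{alpha:g}".replace(".", "")
                    io.write_graphml(assoc, out_dir / f"association_{tag}.graphml")
                    io.write_partitions(partitions, out_dir / f"partitions_{tag}.json")
                    io.write_tsv(ctab, out_dir / f"consensus_{tag}.tsv")
        except Exception as exc:  # noqa: BLE001
            logger.exception("clustering stage failed at alpha %s", alpha)
            report["errors"][f"cluster_{alpha}"] = str(exc)

        if truth is not None and "selection" in entry:
            entry["recovery"] = recovery_metrics(entry["selection"], truth)

    # --- survival subgroups (independent of the network stages) -------------------
    try:
        comparisons = subgroup_analysis(table)
        report["subgroups"] = comparisons
        report["subgroup_table"] = subgroup_frame(comparisons)
        if out_dir is not None:
            io.write_tsv(report["subgroup_table"], out_dir / "subgroups.tsv")
    except Exception as exc:  # noqa: BLE001
        logger.exception("subgroup stage failed")
        report["errors"]["subgroups"] = str(exc)

    if out_dir is not None:
        _write_report_json(report, out_dir / "report.json")
    return report


def _write_report_json(report: dict, path: Path) -> None:
    def jsonable(o):
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, frozenset):
            return sorted(o)
        if isinstance(o, dict):
            return {str(k): jsonable(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [jsonable(v) for v in o]
        return o

    slim = {
        "provenance": report["provenance"],
        "errors": report["errors"],
        "summary": jsonable(report.get("summary")),
        "alphas": {
            str(a): {
                k: jsonable(v) for k, v in entry.items()
                if k in ("selection_table", "consensus_table", "consensus_factors", "recovery")
            } for a, entry in report["alphas"].items()
        },
        "subgroups": jsonable(report.get("subgroup_table")),
    }
    path.write_text(json.dumps(jsonable(slim), indent=1, default=str))
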
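"""Consolidated analysis report and the end-to-end pipeline.

:func:`run_full_analysis` chains every stage — validation, descriptive
metrics, centralities, small-worldness against the degree-preserving null
ensemble, Walktrap communities, composition summaries and per-process
connectogram exports — and collects the network-characteristics table
(node/edge counts, density, diameter, clustering coefficients, mean
shortest path and its null-ensemble mean, assortativity, modularity,
community count, gamma/lam/sigma and the small-world / assortative
verdicts) into a schema-backed :class:`AnalysisReport`.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

from pydantic import BaseModel, Field

from . import centrality as centrality_mod
from . import community as community_mod
from . import graph_metrics, process_views, smallworld
from .network_model import (
    BrainGraph,
    Roster,
    VolitionalProcess,
    bundled_roster,
    edge_count,
    load_graph,
    load_roster,
    validate,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis", "report_schema"]


class AnalysisConfig(BaseModel):
    """Pipeline configuration (flat keys, mirroring the CLI flags)."""

    graph: str | None = None  # path; None => simulate
    roster: str | None = None  # path; None => packaged roster
    simulate: bool = False  # generate a volitional-like graph instead
    n_random: int = 1000
    seed: int = 42
    t_steps: int = 6
    swaps_per_edge: float = 10.0
    clustering_for_gamma: str = "average_local"
    subnetwork_mode: str = "incident"
    out_dir: str | None = None


class AnalysisReport(BaseModel):
    """Network-characteristics table plus provenance.

    ``mean_shortest_path_rand_diff`` is recomputed from the report's own
    unrounded path fields; ``is_small_world`` is (sigma > 1) and
    ``is_assortative`` is (assortativity > 0).
    """

    network_type: str = "Undirected"
    adjacency_matrix: str = "Symmetric"
    n_nodes: int = Field(ge=0)
    n_edges_unordered: int = Field(ge=0)
    n_edges_ordered: int = Field(ge=0)
    n_random_networks: int = Field(ge=1)
    graph_density: float = Field(ge=0.0, le=1.0)
    diameter: int = Field(ge=0)
    global_clustering_coefficient: float = Field(ge=0.0, le=1.0)
    average_local_clustering: float = Field(ge=0.0, le=1.0)
    mean_shortest_path: float = Field(gt=0.0)
    mean_shortest_path_rand: float = Field(gt=0.0)
    mean_shortest_path_rand_diff: float
    assortativity: float = Field(ge=-1.0, le=1.0)
    modularity: float = Field(ge=-1.0, le=1.0)
    n_communities: int = Field(ge=1)
    gamma: float = Field(gt=0.0)
    lam: float = Field(gt=0.0)
    sigma: float = Field(gt=0.0)
    is_small_world: bool
    is_assortative: bool
    # provenance
    graph_file: str | None
    roster_file: str | None
    seed: int
    t_steps: int
    config: dict
    version: str
    timestamp: float

    def check_internal_consistency(self) -> None:
        """Assert the derived fields agree with the primary fields."""
        assert abs(
            self.mean_shortest_path_rand_diff
            - (self.mean_shortest_path - self.mean_shortest_path_rand)
        ) < 1e-12
        assert self.is_small_world == (self.sigma > 1)
        assert self.is_assortative == (self.assortativity > 0)
        assert abs(self.sigma - self.gamma / self.lam) < 1e-12


def report_schema() -> dict:
    """The published JSON Schema of :class:`AnalysisReport`."""
    return AnalysisReport.model_json_schema()


def _stage(name: str, t0: float) -> float:
    now = time.perf_counter()
    logger.info("stage %-14s %.2fs", name, now - t0)
    return now


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run every pipeline stage and assemble the analysis report.

    When ``config.out_dir`` is set, also writes ``report.json``,
    centrality TSVs, the community membership and composition TSVs, and
    Circos files for the whole network and each of the eight processes.
    """
    from . import __version__
    from .synthetic import generate_volitional_like

    t0 = time.perf_counter()
    if config.simulate:
        truth = generate_volitional_like(config.seed)
        graph, roster = truth.graph, truth.roster
    else:
        if config.graph is None:
            raise ValueError("config must name a graph file or set simulate=True")
        graph = load_graph(config.graph)
        roster = load_roster(config.roster) if config.roster else bundled_roster()

    report_val = validate(graph, roster)
    if not report_val.passed:
        raise ValueError(
            "graph/roster label mismatch: "
            f"missing={report_val.missing_from_graph[:5]} "
            f"extra={report_val.extra_in_graph[:5]}"
        )
    t0 = _stage("validate", t0)

    dens = graph_metrics.density(graph)
    pm = graph_metrics.path_metrics(graph)
    cm = graph_metrics.clustering_metrics(graph)
    assort = graph_metrics.degree_assortativity(graph)
    t0 = _stage("metrics", t0)

    table = centrality_mod.compute_centralities(graph)
    t0 = _stage("centrality", t0)

    sw = smallworld.small_worldness(
        graph,
        n_random=config.n_random,
        seed=config.seed,
        swaps_per_edge=config.swaps_per_edge,
        clustering=config.clustering_for_gamma,
    )
    t0 = _stage("smallworld", t0)

    dendro = community_mod.walktrap_dendrogram(graph, t_steps=config.t_steps)
    partition = community_mod.best_partition(dendro, graph)
    composition = community_mod.composition_summary(partition, roster)
    t0 = _stage("communities", t0)

    report = AnalysisReport(
        n_nodes=graph.n_nodes,
        n_edges_unordered=edge_count(graph, "unordered"),
        n_edges_ordered=edge_count(graph, "ordered"),
        n_random_networks=config.n_random,
        graph_density=dens,
        diameter=pm.diameter,
        global_clustering_coefficient=cm.global_transitivity,
        average_local_clustering=cm.average_local,
        mean_shortest_path=pm.mean_shortest_path,
        mean_shortest_path_rand=sw.L_rand_mean,
        mean_shortest_path_rand_diff=pm.mean_shortest_path - sw.L_rand_mean,
        assortativity=assort,
        modularity=partition.Q,
        n_communities=partition.n_communities,
        gamma=sw.gamma,
        lam=sw.lam,
        sigma=sw.sigma,
        is_small_world=sw.sigma > 1,
        is_assortative=assort > 0,
        graph_file=config.graph,
        roster_file=config.roster,
        seed=config.seed,
        t_steps=config.t_steps,
        config=config.model_dump(),
        version=__version__,
        timestamp=time.time(),
    )
    report.check_internal_consistency()

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.model_dump_json(indent=2))
        centrality_mod.write_centrality_tsv(table, roster, out / "centrality.tsv")
        centrality_mod.write_centrality_tsv(
            table, roster, out / "centrality_normalized.tsv", normalized=True
        )
        members = sorted(partition.membership.items())
        (out / "membership.tsv").write_text(
            "label\tcommunity\n"
            + "\n".join(f"{lab}\t{c}" for lab, c in members)
            + "\n"
        )
        composition["by_hemisphere"].to_csv(out / "composition_by_hemisphere.tsv", sep="\t")
        composition["by_process"].to_csv(out / "composition_by_process.tsv", sep="\t")
        records = process_views.connectogram_tables(graph, roster, table)
        process_views.export_circos(records, out / "circos" / "full")
        for process in VolitionalProcess:
            sub = process_views.process_subnetwork(
                graph, roster, process, mode=config.subnetwork_mode
            )
            rec = process_views.connectogram_tables(graph, roster, table, sub)
            process_views.export_circos(rec, out / "circos" / process.name.lower())
        _stage("export", t0)
    return report
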
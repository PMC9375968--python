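"""Per-process subnetworks and Circos connectogram export.

Each movement process (motivation ... modulation of agency) owns a set of
seed nodes in the roster; its subnetwork keeps either every edge touching a
seed node (``incident`` mode, the default — the view in which "node X is
connected to at least another node in this process" is meaningful for
non-seed nodes) or only edges between seed nodes (``induced`` mode).

The connectogram layout places all 82 nodes on a circle, left hemisphere
first then right, grouped by lobe in the fixed order FRO, INS, LIM, TEM,
PAR, OCC, SCN, with six concentric heat rings carrying the max-normalized
centralities in the outer-to-inner order authorities, betweenness, degree,
eigenvector, hubs, closeness. Export is plain-text Circos files
(karyotype, links, one heatmap track per ring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .network_model import (
    LOBE_ORDER,
    BrainGraph,
    Hemisphere,
    Roster,
    VolitionalProcess,
)

__all__ = [
    "ProcessSubnetwork",
    "RING_ORDER",
    "process_subnetwork",
    "connectogram_tables",
    "export_circos",
    "parse_link_file",
]

#: Heat-ring measures, outermost to innermost.
RING_ORDER = ["authorities", "betweenness", "degree", "eigenvector", "hubs", "closeness"]

#: Default per-lobe segment colors (Circos color names).
_LOBE_COLORS = {
    "FRO": "blue",
    "INS": "orange",
    "LIM": "purple",
    "TEM": "green",
    "PAR": "red",
    "OCC": "yellow",
    "SCN": "grey",
}


@dataclass(frozen=True)
class ProcessSubnetwork:
    process: VolitionalProcess
    seed_nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    mode: str  # "incident" | "induced"

    @property
    def touched_nodes(self) -> set[str]:
        return {lab for e in self.edges for lab in e}


def process_subnetwork(
    graph: BrainGraph,
    roster: Roster,
    process: VolitionalProcess,
    mode: str = "incident",
) -> ProcessSubnetwork:
    """Edges of one movement process.

    ``incident`` keeps every edge with at least one endpoint assigned to
    the process; ``induced`` requires both endpoints.
    """
    if not isinstance(process, VolitionalProcess):
        raise ValueError(f"unknown process {process!r}")
    if mode not in ("incident", "induced"):
        raise ValueError(f"unknown subnetwork mode {mode!r}")
    seeds = {n.label for n in roster.nodes_for_process(process)}
    if not seeds:
        warnings.warn(f"no roster nodes assigned to process {process.name}")
    if mode == "incident":
        edges = [e for e in graph.edges() if e[0] in seeds or e[1] in seeds]
    else:
        edges = [e for e in graph.edges() if e[0] in seeds and e[1] in seeds]
    return ProcessSubnetwork(
        process=process,
        seed_nodes=tuple(sorted(seeds)),
        edges=tuple(edges),
        mode=mode,
    )


def panel_summary(sub: ProcessSubnetwork, roster: Roster) -> pd.DataFrame:
    """Touched-node counts per hemisphere x lobe for one process panel."""
    rows = []
    touched = sub.touched_nodes
    for hemi in Hemisphere:
        for lobe in LOBE_ORDER:
            count = sum(
                1
                for lab in touched
                if roster[lab].hemisphere is hemi and roster[lab].lobe_group is lobe
            )
            rows.append({"hemisphere": hemi.name, "lobe_group": lobe.name, "touched": count})
    return pd.DataFrame(rows)


def _segment_order(roster: Roster) -> list:
    """Connectogram perimeter order: left hemisphere then right, by lobe."""
    key = lambda n: (
        n.hemisphere is Hemisphere.RIGHT,
        LOBE_ORDER.index(n.lobe_group),
        n.label,
    )
    return sorted(roster.nodes, key=key)


def _circos_id(label: str) -> str:
    """Circos-safe segment id (no slashes or plus signs)."""
    return label.replace("/", ".").replace("+", "p")


def connectogram_tables(
    graph: BrainGraph,
    roster: Roster,
    table: pd.DataFrame,
    subnetwork: ProcessSubnetwork | None = None,
) -> dict:
    """Segment, ring and link records for a connectogram.

    ``table`` is a centrality table containing the ``*_norm`` columns.
    Links are the full edge set, or the subnetwork's edges when given.
    """
    ordered = _segment_order(roster)
    segments = [
        {
            "id": _circos_id(n.label),
            "label": n.label,
            "hemisphere": n.hemisphere.name,
            "lobe_group": n.lobe_group.name,
            "color": _LOBE_COLORS[n.lobe_group.name],
        }
        for n in ordered
    ]
    rings = []
    for measure in RING_ORDER:
        col = table[measure + "_norm"]
        rings.append(
            {
                "measure": measure,
                "values": {n.label: float(col.loc[n.label]) for n in ordered},
            }
        )
    edges = subnetwork.edges if subnetwork is not None else tuple(graph.edges())
    links = [(a, b) for a, b in edges]
    return {"segments": segments, "rings": rings, "links": links}


def export_circos(records: dict, out_dir: str | Path) -> list[Path]:
    """Write Circos karyotype, link and per-ring heatmap files.

    Plain text, deterministic ordering; returns the written paths.
    Karyotype bands are ``chr - <id> <label> 0 1 <color>``; links are
    ``<id1> 0 1 <id2> 0 1``; heatmaps are ``<id> 0 1 <value>``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    kar = out / "karyotype.txt"
    with kar.open("w") as fh:
        for seg in records["segments"]:
            fh.write(f"chr - {seg['id']} {seg['label']} 0 1 {seg['color']}\n")
    written.append(kar)

    links = out / "links.txt"
    with links.open("w") as fh:
        for a, b in records["links"]:
            fh.write(f"{_circos_id(a)} 0 1 {_circos_id(b)} 0 1\n")
    written.append(links)

    seg_order = [seg["label"] for seg in records["segments"]]
    for i, ring in enumerate(records["rings"]):
        path = out / f"ring_{i}_{ring['measure']}.txt"
        with path.open("w") as fh:
            for lab in seg_order:
                fh.write(f"{_circos_id(lab)} 0 1 {ring['values'][lab]:.10g}\n")
        written.append(path)
    return written


def parse_link_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a Circos link file back into an id-pair edge list."""
    pairs = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.split()
        pairs.append((parts[0], parts[3]))
    return pairs
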
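"""Domain types for the volitional network: parcellation roster and graph.

The volitional network is an undirected, unweighted structural connectivity
graph over 82 Brainnetome-Atlas sub-areas implicated in voluntary movement.
Each node carries a hemisphere, a lobe group, a Brodmann-area label and the
set of movement processes it participates in (motivation through agency).

This module holds the containers (:class:`ParcelNode`, :class:`Roster`,
:class:`BrainGraph`), roster construction from bilateral area records, and
text-format graph I/O (edge-list TSV and labelled adjacency-matrix CSV).
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Hemisphere",
    "LobeGroup",
    "VolitionalProcess",
    "ParcelNode",
    "Roster",
    "BrainGraph",
    "ValidationReport",
    "GraphFormatError",
    "RosterError",
    "build_roster",
    "load_roster",
    "write_roster",
    "load_graph",
    "write_graph",
    "validate",
    "edge_count",
]


class Hemisphere(enum.Enum):
    LEFT = "L"
    RIGHT = "R"


class LobeGroup(enum.Enum):
    """Anatomical grouping used on the connectogram perimeter.

    Fixed display order: frontal, insula, limbic, temporal, parietal,
    occipital, sub-cortical nuclei.
    """

    FRO = "FRO"
    INS = "INS"
    LIM = "LIM"
    TEM = "TEM"
    PAR = "PAR"
    OCC = "OCC"
    SCN = "SCN"


#: Connectogram perimeter order of lobe groups.
LOBE_ORDER = [
    LobeGroup.FRO,
    LobeGroup.INS,
    LobeGroup.LIM,
    LobeGroup.TEM,
    LobeGroup.PAR,
    LobeGroup.OCC,
    LobeGroup.SCN,
]


class VolitionalProcess(enum.Enum):
    """The eight processes of the movement sequence, motivation to agency."""

    MOTIVATION = "Motivation"
    MOD_MOTIVATION = "Modulation of Motivation"
    PLANNING = "Planning"
    TIMING = "Timing"
    DECISION = "Decision"
    EXECUTION = "Execution"
    AGENCY = "Agency"
    MOD_AGENCY = "Modulation of Agency"


class RosterError(ValueError):
    """Invalid roster records (duplicate stems, empty process sets...)."""


class GraphFormatError(ValueError):
    """Malformed graph file (asymmetry, non-binary cells, bad shape)."""


_HEMI_SUFFIX = {"_l": Hemisphere.LEFT, "_r": Hemisphere.RIGHT}


def split_label(label: str) -> tuple[str, Hemisphere]:
    """Split a node label into (stem, hemisphere) from its ``_l``/``_r`` suffix."""
    low = label[-2:].lower()
    if low not in _HEMI_SUFFIX:
        raise RosterError(
            f"label {label!r} lacks a hemisphere suffix ('_l' or '_r')"
        )
    return label[:-2], _HEMI_SUFFIX[low]


def normalize_label(label: str) -> str:
    """Canonicalize a hemisphere suffix to lowercase ``_l``/``_r``.

    Labels without a hemisphere suffix (e.g. synthetic ``n07``) pass
    through unchanged; roster construction, not loading, enforces the
    suffix where one is required.
    """
    label = label.strip()
    if label[-2:].lower() in _HEMI_SUFFIX:
        return label[:-2] + label[-2:].lower()
    return label


@dataclass(frozen=True)
class ParcelNode:
    """One parcellation sub-area in one hemisphere."""

    label: str
    hemisphere: Hemisphere
    lobe_group: LobeGroup
    brodmann_label: str
    processes: frozenset[VolitionalProcess]

    def __post_init__(self) -> None:
        if not self.processes:
            raise RosterError(f"node {self.label!r} has an empty process set")
        _, hemi = split_label(self.label)
        if hemi is not self.hemisphere:
            raise RosterError(
                f"node {self.label!r}: hemisphere {self.hemisphere.name} "
                "disagrees with the label suffix"
            )

    @property
    def stem(self) -> str:
        return split_label(self.label)[0]


@dataclass(frozen=True)
class Roster:
    """Ordered collection of :class:`ParcelNode` with unique labels."""

    nodes: tuple[ParcelNode, ...]
    index: Mapping[str, int] = field(init=False, compare=False, repr=False)

    def __post_init__(self) -> None:
        idx = {node.label: i for i, node in enumerate(self.nodes)}
        if len(idx) != len(self.nodes):
            seen: set[str] = set()
            dup = next(n.label for n in self.nodes if n.label in seen or seen.add(n.label))
            raise RosterError(f"duplicate label in roster: {dup!r}")
        object.__setattr__(self, "index", idx)

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    def __getitem__(self, label: str) -> ParcelNode:
        return self.nodes[self.index[label]]

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.nodes]

    def nodes_for_process(self, process: VolitionalProcess) -> list[ParcelNode]:
        return [n for n in self.nodes if process in n.processes]


@dataclass(frozen=True)
class BrainGraph:
    """Simple undirected labelled graph: symmetric 0/1 adjacency, zero diagonal."""

    labels: tuple[str, ...]
    adjacency: np.ndarray  # (n, n) uint8, symmetric, zero diagonal

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        n = len(self.labels)
        if adj.shape != (n, n):
            raise GraphFormatError(
                f"adjacency shape {adj.shape} does not match {n} labels"
            )
        if not np.isin(adj, (0, 1)).all():
            raise GraphFormatError("adjacency entries must be 0 or 1")
        if not np.array_equal(adj, adj.T):
            raise GraphFormatError("adjacency matrix must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise GraphFormatError("adjacency diagonal must be zero (no self-loops)")
        if len(set(self.labels)) != n:
            raise GraphFormatError("duplicate node labels")
        adj = adj.astype(np.uint8)
        adj.setflags(write=False)
        object.__setattr__(self, "adjacency", adj)

    @classmethod
    def from_edges(
        cls, labels: Sequence[str], edges: Iterable[tuple[str, str]]
    ) -> "BrainGraph":
        labels = tuple(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        adj = np.zeros((len(labels), len(labels)), dtype=np.uint8)
        for a, b in edges:
            i, j = index[a], index[b]
            if i == j:
                continue
            adj[i, j] = adj[j, i] = 1
        return cls(labels=labels, adjacency=adj)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def edges(self) -> list[tuple[str, str]]:
        """Undirected edge list, each edge once, in row-major label order."""
        ii, jj = np.nonzero(np.triu(self.adjacency))
        return [(self.labels[i], self.labels[j]) for i, j in zip(ii, jj)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BrainGraph):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(
            self.adjacency, other.adjacency
        )

    def __hash__(self) -> int:
        return hash((self.labels, self.adjacency.tobytes()))


def edge_count(graph: BrainGraph, convention: str = "unordered") -> int:
    """Edge count in either convention.

    ``unordered`` counts each undirected edge once; ``ordered`` counts
    nonzero adjacency entries (twice the unordered count), the convention
    under which the study's 82-node network has 2330 edges.
    """
    ordered = int(graph.adjacency.sum())
    if convention == "ordered":
        return ordered
    if convention == "unordered":
        return ordered // 2
    raise ValueError(f"unknown edge-count convention {convention!r}")


# --------------------------------------------------------------------------
# Roster construction


def _node_sort_key(node: ParcelNode) -> tuple:
    return (
        LOBE_ORDER.index(node.lobe_group),
        node.hemisphere.value,
        node.label,
    )


def build_roster(records: Sequence[Mapping]) -> Roster:
    """Expand area records to a bilateral roster of :class:`ParcelNode`.

    Each record maps an anatomical area to its atlas sub-area label stems::

        {"area_name": ..., "sub_area_labels": ["A4hf", ...],
         "brodmann_label": "BA4", "lobe_group": "FRO",
         "processes": ["EXECUTION"]}

    Every stem is expanded to both hemispheric homologues (``_l``/``_r``
    suffixes); a stem listed under several processes yields a single node
    per hemisphere whose process set is the union. Node order is
    deterministic: lobe group (connectogram order), then hemisphere, then
    label.
    """
    stems: dict[str, dict] = {}
    for rec in records:
        procs = [
            p if isinstance(p, VolitionalProcess) else VolitionalProcess[p]
            for p in rec["processes"]
        ]
        if not procs:
            raise RosterError(
                f"record {rec.get('area_name', '?')!r} lists no processes"
            )
        lobe = (
            rec["lobe_group"]
            if isinstance(rec["lobe_group"], LobeGroup)
            else LobeGroup[rec["lobe_group"]]
        )
        for raw in rec["sub_area_labels"]:
            stem = raw
            if raw[-2:].lower() in _HEMI_SUFFIX:  # tolerate suffixed input
                stem = raw[:-2]
            entry = stems.setdefault(
                stem,
                {"lobe": lobe, "ba": rec["brodmann_label"], "procs": set()},
            )
            if entry["lobe"] is not lobe:
                raise RosterError(
                    f"stem {stem!r} listed with conflicting lobe groups "
                    f"{entry['lobe'].name} and {lobe.name}"
                )
            if entry["ba"] != rec["brodmann_label"]:
                raise RosterError(
                    f"stem {stem!r} listed with conflicting Brodmann labels "
                    f"{entry['ba']!r} and {rec['brodmann_label']!r}"
                )
            entry["procs"].update(procs)

    nodes = []
    for stem, entry in stems.items():
        for suffix, hemi in (("_l", Hemisphere.LEFT), ("_r", Hemisphere.RIGHT)):
            nodes.append(
                ParcelNode(
                    label=stem + suffix,
                    hemisphere=hemi,
                    lobe_group=entry["lobe"],
                    brodmann_label=entry["ba"],
                    processes=frozenset(entry["procs"]),
                )
            )
    nodes.sort(key=_node_sort_key)
    return Roster(nodes=tuple(nodes))


# --------------------------------------------------------------------------
# Roster TSV I/O (columns: label, hemisphere, lobe_group, brodmann_label,
# processes — the last semicolon-separated)

_ROSTER_COLUMNS = ["label", "hemisphere", "lobe_group", "brodmann_label", "processes"]


def write_roster(roster: Roster, path: str | Path) -> None:
    lines = ["\t".join(_ROSTER_COLUMNS)]
    for node in roster:
        procs = ";".join(
            sorted(p.name for p in node.processes)
        )
        lines.append(
            "\t".join(
                [
                    node.label,
                    node.hemisphere.name,
                    node.lobe_group.name,
                    node.brodmann_label,
                    procs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_roster(path: str | Path) -> Roster:
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    if header != _ROSTER_COLUMNS:
        raise GraphFormatError(
            f"roster header {header} != expected {_ROSTER_COLUMNS}"
        )
    nodes = []
    for ln in lines[1:]:
        label, hemi, lobe, ba, procs = ln.split("\t")
        nodes.append(
            ParcelNode(
                label=normalize_label(label),
                hemisphere=Hemisphere[hemi],
                lobe_group=LobeGroup[lobe],
                brodmann_label=ba,
                processes=frozenset(
                    VolitionalProcess[p] for p in procs.split(";") if p
                ),
            )
        )
    return Roster(nodes=tuple(nodes))


def bundled_roster() -> Roster:
    """The packaged 82-node roster (both hemispheres, eight processes)."""
    return load_roster(Path(__file__).parent / "data" / "roster_table1.tsv")


# --------------------------------------------------------------------------
# Graph I/O


def load_graph(
    path: str | Path, format: str | None = None, symmetrize: bool = False
) -> BrainGraph:
    """Load a graph from an edge-list TSV or a labelled adjacency-matrix CSV.

    ``format`` is ``"edge_list_tsv"`` or ``"matrix_csv"``; when *None* it is
    inferred from the file suffix. Self-loops are dropped with a warning and
    duplicate edges collapsed. An asymmetric matrix is an error unless
    ``symmetrize`` is set, in which case the union of directions is taken.
    """
    path = Path(path)
    if format is None:
        format = "matrix_csv" if path.suffix.lower() == ".csv" else "edge_list_tsv"
    if format == "edge_list_tsv":
        return _load_edge_list(path)
    if format == "matrix_csv":
        return _load_matrix_csv(path, symmetrize=symmetrize)
    raise GraphFormatError(f"unknown graph format {format!r}")


def _load_edge_list(path: Path) -> BrainGraph:
    pairs: list[tuple[str, str]] = []
    labels: dict[str, None] = {}
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise GraphFormatError(
                f"{path}:{lineno}: expected 2 tab-separated labels, got {len(parts)}"
            )
        a, b = (normalize_label(p) for p in parts)
        if a == b:
            warnings.warn(f"{path}:{lineno}: dropping self-loop on {a!r}")
            continue
        labels.setdefault(a)
        labels.setdefault(b)
        pairs.append((a, b))
    return BrainGraph.from_edges(list(labels), pairs)


def _load_matrix_csv(path: Path, symmetrize: bool) -> BrainGraph:
    rows = [ln.split(",") for ln in path.read_text().splitlines() if ln.strip()]
    header = [normalize_label(c) for c in rows[0][1:]]
    n = len(header)
    if len(rows) - 1 != n:
        raise GraphFormatError(
            f"{path}: matrix is not square ({len(rows) - 1} rows, {n} columns)"
        )
    adj = np.zeros((n, n), dtype=np.uint8)
    for i, row in enumerate(rows[1:]):
        if normalize_label(row[0]) != header[i]:
            raise GraphFormatError(
                f"{path}: row label {row[0]!r} != column label {header[i]!r}"
            )
        if len(row) - 1 != n:
            raise GraphFormatError(
                f"{path}: row {i + 2} has {len(row) - 1} cells, expected {n}"
            )
        for j, cell in enumerate(row[1:]):
            val = cell.strip()
            if val not in ("0", "1"):
                raise GraphFormatError(
                    f"{path}: non-binary cell {val!r} at row {i + 2}, column {j + 2}"
                )
            adj[i, j] = int(val)
    if not np.array_equal(adj, adj.T):
        if not symmetrize:
            i, j = np.argwhere(adj != adj.T)[0]
            raise GraphFormatError(
                f"{path}: matrix is asymmetric (e.g. [{header[i]!r},{header[j]!r}]"
                f"={adj[i, j]} but transpose={adj[j, i]}); pass symmetrize=True "
                "to take the union of directions"
            )
        warnings.warn(f"{path}: symmetrizing asymmetric matrix (union of directions)")
        adj = np.maximum(adj, adj.T)
    if np.any(np.diag(adj) != 0):
        warnings.warn(f"{path}: dropping self-loops from diagonal")
        np.fill_diagonal(adj, 0)
    return BrainGraph(labels=tuple(header), adjacency=adj)


def write_graph(graph: BrainGraph, path: str | Path, format: str | None = None) -> None:
    """Write a graph as edge-list TSV or labelled adjacency-matrix CSV."""
    path = Path(path)
    if format is None:
        format = "matrix_csv" if path.suffix.lower() == ".csv" else "edge_list_tsv"
    if format == "edge_list_tsv":
        lines = [f"{a}\t{b}" for a, b in graph.edges()]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "matrix_csv":
        lines = ["," + ",".join(graph.labels)]
        for i, lab in enumerate(graph.labels):
            lines.append(lab + "," + ",".join(str(int(v)) for v in graph.adjacency[i]))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise GraphFormatError(f"unknown graph format {format!r}")


# --------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class ValidationReport:
    passed: bool
    n_nodes: int
    n_edges_unordered: int
    n_edges_ordered: int
    components: int
    missing_from_graph: tuple[str, ...]
    extra_in_graph: tuple[str, ...]
    warnings: tuple[str, ...]


def _component_count(graph: BrainGraph) -> int:
    from scipy.sparse import csgraph, csr_matrix

    if graph.n_nodes == 0:
        return 0
    n, _ = csgraph.connected_components(
        csr_matrix(graph.adjacency), directed=False
    )
    return int(n)


def validate(graph: BrainGraph, roster: Roster) -> ValidationReport:
    """Check label agreement between graph and roster; warn on disconnection."""
    graph_labels = set(graph.labels)
    roster_labels = set(roster.labels)
    missing = tuple(sorted(roster_labels - graph_labels))
    extra = tuple(sorted(graph_labels - roster_labels))
    components = _component_count(graph)
    warns = []
    if components > 1:
        warns.append(f"graph has {components} connected components")
    passed = not missing and not extra
    return ValidationReport(
        passed=passed,
        n_nodes=graph.n_nodes,
        n_edges_unordered=edge_count(graph, "unordered"),
        n_edges_ordered=edge_count(graph, "ordered"),
        components=components,
        missing_from_graph=missing,
        extra_in_graph=extra,
        warnings=tuple(warns),
    )
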
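"""Ingestion and normalization of receptor–receptor interaction records.

A GPCR heteroreceptor network is an undirected simple graph: nodes are
receptor protomers (short uppercase mnemonics such as ``DRD2`` or ``OPRM``,
each tagged with its GPCR class), edges are experimentally supported
heteromer interactions.  Curated edge tables arrive as TSV/CSV (with
optional evidence columns) or Cytoscape SIF; reciprocal detections and
homodimer rows show up as duplicated edges and self-loops, which are
stripped here before any topology is computed.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

log = logging.getLogger("hetnet")

#: Evidence tags for receptor–receptor interaction detection methods.
EVIDENCE_METHODS = frozenset(
    {"coIP", "BRET", "FRET", "SRET", "TR-FRET", "BiFC", "PLA", "FCCS"}
)


class Family(str, Enum):
    """GPCR class of a protomer.

    F1 = class A (rhodopsin-like), F2 = class B (secretin-like),
    F3 = class C (metabotropic glutamate-like).
    """

    F1 = "F1"
    F2 = "F2"
    F3 = "F3"
    UNKNOWN = "unknown"


_FAMILY_ALIASES = {
    "A": Family.F1, "F1": Family.F1, "1": Family.F1, "CLASSA": Family.F1,
    "B": Family.F2, "F2": Family.F2, "2": Family.F2, "CLASSB": Family.F2,
    "C": Family.F3, "F3": Family.F3, "3": Family.F3, "CLASSC": Family.F3,
    "UNKNOWN": Family.UNKNOWN, "": Family.UNKNOWN,
}


def parse_family(text: str | Family | None) -> Family:
    """Map a family label (``A``/``B``/``C`` or ``F1``/``F2``/``F3``) to :class:`Family`."""
    if text is None:
        return Family.UNKNOWN
    if isinstance(text, Family):
        return text
    key = str(text).strip().upper().replace(" ", "")
    try:
        return _FAMILY_ALIASES[key]
    except KeyError:
        raise ValueError(f"unrecognized GPCR family label: {text!r}") from None


@dataclass(frozen=True)
class ReceptorProtomer:
    """A receptor protomer: one node of the heteromer network."""

    id: str
    family: Family = Family.UNKNOWN
    display_name: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protomer id must be non-empty")


@dataclass(frozen=True)
class HeteromerEdge:
    """An undirected heteromer interaction between two distinct protomers."""

    a: str
    b: str
    methods: frozenset[str] = frozenset()
    n_publications: int = 0
    controversial: bool = False

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-loop edge not allowed: {self.a}")
        if self.n_publications < 0:
            raise ValueError("n_publications must be non-negative")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.a, self.b))


@dataclass(frozen=True)
class RawEdgeRecord:
    """One parsed row of an edge table, before normalization.

    ``b is None`` marks an isolated-node record (single-token SIF row).
    """

    a: str
    b: str | None
    attributes: Mapping[str, str] = field(default_factory=dict)
    line: int = 0


@dataclass
class NormalizationReport:
    n_records: int = 0
    n_self_loops_dropped: int = 0
    n_duplicates_merged: int = 0


class EdgeTableFormatError(ValueError):
    """Malformed edge-table row (names the offending line)."""


class HetNetGraph:
    """Undirected simple graph of receptor protomers and heteromer edges.

    Thin wrapper over :class:`networkx.Graph`; node attributes hold
    ``family`` / ``display_name``, edge attributes hold ``methods``,
    ``n_publications`` and ``controversial``.  Isolated (degree-0) nodes are
    legitimate members: the network keeps protomers with no verified partner.
    """

    def __init__(self, graph: nx.Graph | None = None,
                 normalization: NormalizationReport | None = None) -> None:
        self.nx = graph if graph is not None else nx.Graph()
        self.normalization = normalization

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nx.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.nx.number_of_edges()

    def node_ids(self) -> list[str]:
        return sorted(self.nx.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self.nx

    def __len__(self) -> int:
        return self.n_nodes

    def protomer(self, node: str) -> ReceptorProtomer:
        data = self.nx.nodes[node]
        return ReceptorProtomer(
            id=node,
            family=parse_family(data.get("family", Family.UNKNOWN)),
            display_name=data.get("display_name"),
        )

    def protomers(self) -> list[ReceptorProtomer]:
        return [self.protomer(n) for n in self.node_ids()]

    def heteromer_edges(self) -> list[HeteromerEdge]:
        out = []
        for a, b, data in self.nx.edges(data=True):
            a, b = sorted((a, b))
            out.append(HeteromerEdge(
                a=a, b=b,
                methods=frozenset(data.get("methods", ())),
                n_publications=int(data.get("n_publications", 0)),
                controversial=bool(data.get("controversial", False)),
            ))
        return sorted(out, key=lambda e: (e.a, e.b))

    @classmethod
    def from_edges(cls, pairs: Iterable[tuple[str, str]],
                   families: Mapping[str, Family | str] | None = None,
                   nodes: Iterable[str] = ()) -> "HetNetGraph":
        """Build a normalized graph directly from unordered id pairs."""
        records = [RawEdgeRecord(a, b) for a, b in pairs]
        records += [RawEdgeRecord(n, None) for n in nodes]
        attrs = None
        if families is not None:
            attrs = {k: ReceptorProtomer(k.upper(), parse_family(v))
                     for k, v in families.items()}
        return normalize_graph(records, node_attrs=attrs)


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".sif":
        return "sif"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def read_edge_table(path: str | Path, dialect: str | None = None) -> list[RawEdgeRecord]:
    """Parse an edge table into raw records, preserving input order.

    Dialects: ``tsv``/``csv`` (optional header naming ``protomer_a``,
    ``protomer_b`` and extra attribute columns) and ``sif`` (whitespace
    delimited ``source relation target [target ...]``; a single-token row is
    an isolated node).  Rows that do not yield two identifiers raise
    :class:`EdgeTableFormatError` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge table not found: {path}")
    if dialect is None:
        dialect = _infer_dialect(path)
    if dialect not in {"tsv", "csv", "sif"}:
        raise ValueError(f"unknown edge-table dialect: {dialect!r}")

    text = path.read_text()
    records: list[RawEdgeRecord] = []
    if dialect == "sif":
        for lineno, line in enumerate(text.splitlines(), start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) == 1:
                records.append(RawEdgeRecord(tokens[0], None, line=lineno))
            elif len(tokens) == 2:
                raise EdgeTableFormatError(
                    f"{path}:{lineno}: SIF row has a relation but no target")
            else:
                source = tokens[0]  # tokens[1] is the relation type, ignored
                for target in tokens[2:]:
                    records.append(RawEdgeRecord(source, target, line=lineno))
    else:
        delim = "\t" if dialect == "tsv" else ","
        rows = list(csv.reader(text.splitlines(), delimiter=delim))
        header: list[str] | None = None
        start = 0
        for i, row in enumerate(rows):
            if row and any(cell.strip() for cell in row):
                cells = [c.strip().lower() for c in row]
                if "protomer_a" in cells:
                    header = [c.strip() for c in row]
                    start = i + 1
                break
        for lineno, row in enumerate(rows[start:], start=start + 1):
            if not row or not any(cell.strip() for cell in row):
                continue
            cells = [c.strip() for c in row]
            if header is not None:
                named = dict(zip(header, cells))
                a = named.pop("protomer_a", "")
                b = named.pop("protomer_b", "")
                attrs = {k: v for k, v in named.items() if v != ""}
            else:
                a = cells[0]
                b = cells[1] if len(cells) > 1 else ""
                attrs = {f"col{j + 1}": v for j, v in enumerate(cells[2:], start=2)}
            if not a or not b:
                raise EdgeTableFormatError(
                    f"{path}:{lineno}: row needs two protomer identifiers")
            records.append(RawEdgeRecord(a, b, attrs, line=lineno))
    if not records:
        log.warning("edge table %s produced no records", path)
    return records


def read_node_attrs(path: str | Path, dialect: str | None = None
                    ) -> dict[str, ReceptorProtomer]:
    """Read a node-attribute table (columns ``id``, ``family``, optional
    ``display_name``) into a mapping of uppercase id to protomer."""
    path = Path(path)
    delim = "," if (dialect or _infer_dialect(path)) == "csv" else "\t"
    out: dict[str, ReceptorProtomer] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or "id" not in [f.strip() for f in reader.fieldnames]:
            raise EdgeTableFormatError(f"{path}: attribute table needs an 'id' column")
        for row in reader:
            rid = (row.get("id") or "").strip().upper()
            if not rid:
                continue
            out[rid] = ReceptorProtomer(
                id=rid,
                family=parse_family(row.get("family")),
                display_name=(row.get("display_name") or None),
            )
    return out


def _parse_bool(text: str | bool) -> bool:
    if isinstance(text, bool):
        return text
    return str(text).strip().lower() in {"true", "1", "yes", "y"}


def _parse_methods(text) -> frozenset[str]:
    if not text:
        return frozenset()
    if isinstance(text, (set, frozenset, list, tuple)):
        return frozenset(str(m) for m in text)
    return frozenset(m.strip() for m in str(text).split(";") if m.strip())


def normalize_graph(records: Sequence[RawEdgeRecord],
                    node_attrs: Mapping[str, ReceptorProtomer] | None = None,
                    allow_isolated: bool = True) -> HetNetGraph:
    """Normalize raw records into an undirected simple :class:`HetNetGraph`.

    Ids are upper-cased; self-loops (homodimer rows) are dropped; unordered
    duplicate edges are merged — evidence-method sets are unioned,
    ``n_publications`` takes the maximum (never summed, so duplicated rows
    cannot inflate support) and ``controversial`` is OR-ed.  Nodes present
    only in the attribute table enter as isolated nodes.  Idempotent: a
    normalized graph passes through unchanged.
    """
    g = nx.Graph()
    report = NormalizationReport(n_records=len(records))
    for rec in records:
        a = rec.a.strip().upper()
        if rec.b is None:
            g.add_node(a)
            continue
        b = rec.b.strip().upper()
        g.add_nodes_from((a, b))
        if a == b:
            report.n_self_loops_dropped += 1
            continue
        methods = _parse_methods(rec.attributes.get("methods"))
        n_pub = int(rec.attributes.get("n_publications", 0) or 0)
        contro = _parse_bool(rec.attributes.get("controversial", False))
        if g.has_edge(a, b):
            report.n_duplicates_merged += 1
            data = g.edges[a, b]
            data["methods"] = data["methods"] | methods
            data["n_publications"] = max(data["n_publications"], n_pub)
            data["controversial"] = data["controversial"] or contro
        else:
            g.add_edge(a, b, methods=methods, n_publications=n_pub,
                       controversial=contro)
    for node in g.nodes:
        g.nodes[node]["family"] = Family.UNKNOWN
    if node_attrs:
        for rid, prot in node_attrs.items():
            rid = rid.upper()
            if rid not in g:
                if not allow_isolated:
                    log.warning(
                        "attribute-only id %s absent from edge records; "
                        "added as isolated node", rid)
                g.add_node(rid)
            g.nodes[rid]["family"] = parse_family(prot.family)
            if prot.display_name:
                g.nodes[rid]["display_name"] = prot.display_name
    return HetNetGraph(g, report)


@dataclass
class FamilySummary:
    """Per-family node counts and the intra/interfamily edge partition.

    Edges with both endpoints in the same known family land in that family's
    intrafamily bucket; edges whose endpoints belong to two different known
    families are ``interfamily``; edges touching an unlabeled protomer are
    counted under ``unknown``.  Both partitions sum exactly to N and E.
    """

    node_counts: dict[str, int]
    edge_counts: dict[str, int]

    @property
    def total_nodes(self) -> int:
        return sum(self.node_counts.values())

    @property
    def total_edges(self) -> int:
        return sum(self.edge_counts.values())


def family_summary(graph: HetNetGraph) -> FamilySummary:
    """Tabulate family composition: node counts per GPCR class and the
    partition of edges into F1–F1 / F2–F2 / F3–F3 / interfamily."""
    g = graph.nx if isinstance(graph, HetNetGraph) else graph
    node_counts = {"F1": 0, "F2": 0, "F3": 0, "unknown": 0}
    fam_of: dict[str, Family] = {}
    for node, data in g.nodes(data=True):
        fam = parse_family(data.get("family", Family.UNKNOWN))
        fam_of[node] = fam
        key = fam.value if fam is not Family.UNKNOWN else "unknown"
        node_counts[key] += 1
    edge_counts = {"F1": 0, "F2": 0, "F3": 0, "interfamily": 0, "unknown": 0}
    for a, b in g.edges:
        fa, fb = fam_of[a], fam_of[b]
        if Family.UNKNOWN in (fa, fb):
            edge_counts["unknown"] += 1
        elif fa is fb:
            edge_counts[fa.value] += 1
        else:
            edge_counts["interfamily"] += 1
    return FamilySummary(node_counts, edge_counts)


# -- serialization -------------------------------------------------------

def write_graph(graph: HetNetGraph, path: str | Path, dialect: str = "tsv",
                attrs_path: str | Path | None = None) -> None:
    """Write a graph to ``tsv``, ``sif`` or ``json``.

    ``json`` is lossless (nodes, families, edge evidence).  ``tsv`` writes
    the edge table (evidence columns included) and, when ``attrs_path`` is
    given, a companion node-attribute table so isolated nodes and families
    round-trip.  ``sif`` keeps topology only; isolated nodes become
    single-token rows.
    """
    path = Path(path)
    edges = graph.heteromer_edges()
    if dialect == "json":
        payload = {
            "nodes": [
                {"id": p.id, "family": p.family.value,
                 "display_name": p.display_name}
                for p in graph.protomers()
            ],
            "edges": [
                {"a": e.a, "b": e.b, "methods": sorted(e.methods),
                 "n_publications": e.n_publications,
                 "controversial": e.controversial}
                for e in edges
            ],
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    if dialect == "tsv":
        lines = ["protomer_a\tprotomer_b\tmethods\tn_publications\tcontroversial"]
        for e in edges:
            lines.append("\t".join([
                e.a, e.b, ";".join(sorted(e.methods)),
                str(e.n_publications), str(e.controversial).lower(),
            ]))
        path.write_text("\n".join(lines) + "\n")
        if attrs_path is not None:
            alines = ["id\tfamily\tdisplay_name"]
            for p in graph.protomers():
                alines.append("\t".join([p.id, p.family.value, p.display_name or ""]))
            Path(attrs_path).write_text("\n".join(alines) + "\n")
        return
    if dialect == "sif":
        lines = [f"{e.a} pp {e.b}" for e in edges]
        connected = {n for e in edges for n in (e.a, e.b)}
        lines += [n for n in graph.node_ids() if n not in connected]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return
    raise ValueError(f"unknown graph dialect: {dialect!r}")


def read_graph(path: str | Path, dialect: str | None = None,
               attrs_path: str | Path | None = None) -> HetNetGraph:
    """Read a graph written by :func:`write_graph` (or any edge table)."""
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else _infer_dialect(path)
    if dialect == "json":
        payload = json.loads(path.read_text())
        g = nx.Graph()
        for node in payload.get("nodes", ()):
            g.add_node(node["id"], family=parse_family(node.get("family")))
            if node.get("display_name"):
                g.nodes[node["id"]]["display_name"] = node["display_name"]
        for e in payload.get("edges", ()):
            g.add_edge(e["a"], e["b"],
                       methods=frozenset(e.get("methods", ())),
                       n_publications=int(e.get("n_publications", 0)),
                       controversial=bool(e.get("controversial", False)))
        return HetNetGraph(g)
    records = read_edge_table(path, dialect=dialect)
    attrs = read_node_attrs(attrs_path) if attrs_path is not None else None
    return normalize_graph(records, node_attrs=attrs)
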
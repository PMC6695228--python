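"""Relation-typed Gene Ontology graphs parsed from OBO 1.2 flat files.

The Gene Ontology ships as a flat-text OBO document of ``[Term]`` stanzas.
Each stanza contributes a node; ``is_a`` and ``relationship`` lines
contribute directed, labelled edges whose label (is_a, part_of, has_part,
regulates, ...) is preserved verbatim.  The graph built here is the
substrate for every traversal policy downstream: it records the three
sub-ontology namespaces (cellular_component, biological_process,
molecular_function), keeps obsolete terms as edge-free nodes, and resolves
``alt_id`` aliases so that edges written against secondary accessions land
on the primary node.
"""

from __future__ import annotations

import json
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

GO_ACCESSION = re.compile(r"^GO:\d{7}$")

NAMESPACES = ("cellular_component", "biological_process", "molecular_function")

#: namespace -> GAF aspect letter
ASPECT_OF_NAMESPACE = {
    "cellular_component": "C",
    "biological_process": "P",
    "molecular_function": "F",
}

#: Table of semantic-correspondence classes per relation label.  Scoping
#: relations order two terms by generality; mereological relations are the
#: part-whole subset of those; spatiotemporal and active relations carry no
#: scoping information and are never traversed by scoping policies.
CORRESPONDENCE_CLASS = {
    "is_a": "scoping",
    "part_of": "mereological",
    "has_part": "mereological",
    "happens_during": "spatiotemporal",
    "ends_during": "spatiotemporal",
    "occurs_in": "spatiotemporal",
    "regulates": "active",
    "positively_regulates": "active",
    "negatively_regulates": "active",
}


class OboParseError(ValueError):
    """Malformed OBO input; carries the 1-based line number of the offence."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class TermNode:
    """One GO term: accession, label, sub-ontology, obsolescence, aliases."""

    id: str
    name: str = ""
    namespace: str = ""
    obsolete: bool = False
    alt_ids: frozenset[str] = frozenset()


@dataclass(frozen=True, order=True)
class RelationEdge:
    """Directed stanza-owner -> stanza-target edge with its verbatim label."""

    subject: str
    relation: str
    object: str


class OntologyGraph:
    """Container for term nodes and relation-typed edges.

    Obsolete terms are present in :attr:`nodes` but never appear as an edge
    endpoint.  Edges referring to secondary accessions are rewritten onto the
    primary id via the alias table; edges whose target never resolves are
    dropped and recorded in :attr:`dangling`.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, TermNode] = {}
        self.edges: list[RelationEdge] = []
        self.alias: dict[str, str] = {}
        self.relation_labels: set[str] = set()  # from [Typedef] stanzas
        self.dangling: list[str] = []
        self.duplicates_dropped: int = 0
        self._out: dict[str, list[RelationEdge]] = defaultdict(list)
        self._in: dict[str, list[RelationEdge]] = defaultdict(list)

    # -- construction -----------------------------------------------------

    def add_node(self, node: TermNode) -> None:
        self.nodes[node.id] = node
        for alt in node.alt_ids:
            self.alias[alt] = node.id

    def add_edge(self, subject: str, relation: str, obj: str) -> bool:
        """Resolve aliases and append the edge; returns False if dropped."""
        subject = self.resolve(subject)
        obj = self.resolve(obj)
        if subject is None or obj is None:
            return False
        edge = RelationEdge(subject, relation, obj)
        if edge in self._edge_set:
            self.duplicates_dropped += 1
            return False
        self._edge_set.add(edge)
        self.edges.append(edge)
        self._out[subject].append(edge)
        self._in[obj].append(edge)
        return True

    _edge_set: set[RelationEdge]

    # -- lookup ------------------------------------------------------------

    def resolve(self, term_id: str) -> str | None:
        """Map a primary or secondary accession to its primary id."""
        if term_id in self.nodes:
            return term_id
        return self.alias.get(term_id)

    def __contains__(self, term_id: str) -> bool:
        return self.resolve(term_id) is not None

    def __len__(self) -> int:
        return len(self.nodes)

    def out_edges(self, term_id: str) -> list[RelationEdge]:
        return self._out.get(term_id, [])

    def in_edges(self, term_id: str) -> list[RelationEdge]:
        return self._in.get(term_id, [])

    def edges_with_relation(self, relation: str) -> Iterator[RelationEdge]:
        return (e for e in self.edges if e.relation == relation)

    def namespace_index(self) -> dict[str, set[str]]:
        index: dict[str, set[str]] = {ns: set() for ns in NAMESPACES}
        for node in self.nodes.values():
            if node.namespace in index:
                index[node.namespace].add(node.id)
        return index

    def terms(self, namespace: str | None = None,
              include_obsolete: bool = False) -> list[str]:
        """Sorted term ids, optionally restricted to one sub-ontology."""
        out = []
        for node in self.nodes.values():
            if node.obsolete and not include_obsolete:
                continue
            if namespace is not None and node.namespace != namespace:
                continue
            out.append(node.id)
        return sorted(out)


def parse_obo(path: str | Path, *, restrict_namespace: str | None = None) -> OntologyGraph:
    """Parse an OBO 1.2 flat file into an :class:`OntologyGraph`.

    Recognised ``[Term]`` keys: id, name, namespace, alt_id, is_a,
    relationship, is_obsolete; other keys are ignored.  ``[Typedef]``
    stanzas contribute to the known relation-label set only.  Obsolete
    terms are kept as nodes but contribute no edges; edges pointing at
    unknown accessions are dropped into the graph's dangling list.

    Parameters
    ----------
    path:
        OBO file; must begin with a header containing a ``format-version``
        line before the first stanza.
    restrict_namespace:
        If given, drop edges whose endpoints lie in different sub-ontologies
        or outside this namespace (go-core retains such edges by default).
    """
    if restrict_namespace is not None and restrict_namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace {restrict_namespace!r}")

    text = Path(path).read_text()
    graph = OntologyGraph()
    graph._edge_set = set()

    # (subject, relation, object, line_number); attached after all nodes exist
    pending_edges: list[tuple[str, str, str, int]] = []

    stanza_type: str | None = None
    stanza_start = 0
    cur: dict[str, list[str]] = defaultdict(list)
    header_seen = False
    in_header = True

    def flush(line_no: int) -> None:
        nonlocal cur
        if stanza_type == "Typedef":
            for tid in cur.get("id", []):
                graph.relation_labels.add(tid)
        elif stanza_type == "Term":
            ids = cur.get("id", [])
            if not ids:
                raise OboParseError("[Term] stanza without an id", stanza_start)
            tid = ids[0]
            obsolete = any(v.split("!")[0].strip() == "true"
                           for v in cur.get("is_obsolete", []))
            node = TermNode(
                id=tid,
                name=(cur.get("name") or [""])[0],
                namespace=(cur.get("namespace") or [""])[0],
                obsolete=obsolete,
                alt_ids=frozenset(v.split("!")[0].strip()
                                  for v in cur.get("alt_id", [])),
            )
            graph.add_node(node)
            if not obsolete:
                for value, line in cur.get("_is_a_lines", []):  # type: ignore[misc]
                    target = value.split("!")[0].strip()
                    pending_edges.append((tid, "is_a", target, line))
                for value, line in cur.get("_rel_lines", []):  # type: ignore[misc]
                    parts = value.split("!")[0].split()
                    if len(parts) != 2:
                        raise OboParseError(
                            f"malformed relationship line {value!r}", line)
                    pending_edges.append((tid, parts[0], parts[1], line))
        cur = defaultdict(list)

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            if in_header and not header_seen:
                raise OboParseError("missing OBO header (format-version)", line_no)
            in_header = False
            flush(line_no)
            stanza_type = line.strip("[]")
            stanza_start = line_no
            continue
        if ":" not in line:
            raise OboParseError(f"malformed line {line!r}", line_no)
        key, value = line.split(":", 1)
        key, value = key.strip(), value.strip()
        if in_header:
            if key == "format-version":
                header_seen = True
            continue
        if key == "is_a":
            cur["_is_a_lines"].append((value, line_no))  # type: ignore[arg-type]
        elif key == "relationship":
            cur["_rel_lines"].append((value, line_no))  # type: ignore[arg-type]
        else:
            cur[key].append(value)
    if not header_seen:
        raise OboParseError("missing OBO header (format-version)", 1)
    flush(len(text.splitlines()) + 1)

    for subject, relation, target, line in pending_edges:
        resolved = graph.resolve(target)
        if resolved is None:
            graph.dangling.append(
                f"line {line}: edge ({subject}, {relation}, {target}) "
                "targets an unknown term; dropped")
            continue
        if graph.nodes[resolved].obsolete:
            graph.dangling.append(
                f"line {line}: edge ({subject}, {relation}, {resolved}) "
                "targets an obsolete term; dropped")
            continue
        if restrict_namespace is not None:
            ns_s = graph.nodes[subject].namespace
            ns_o = graph.nodes[resolved].namespace
            if ns_s != restrict_namespace or ns_o != restrict_namespace:
                continue
        graph.add_edge(subject, relation, resolved)
    return graph


@dataclass
class RelationCensus:
    """Edge counts per relation label, total and per sub-ontology.

    Cross-namespace edges are assigned to the column of the edge *subject*'s
    namespace, so per-namespace counts always sum to the total.
    """

    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def total(self, relation: str) -> int:
        return self.counts.get(relation, {}).get("total", 0)

    def to_frame(self):
        import pandas as pd

        cols = ["total", *NAMESPACES]
        rows = {rel: [c.get(k, 0) for k in cols]
                for rel, c in sorted(self.counts.items())}
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def relation_census(graph: OntologyGraph,
                    watch: Iterable[str] = ()) -> RelationCensus:
    """Count edges per relation label; watched absent labels report zero."""
    census = RelationCensus()
    for label in watch:
        census.counts[label] = {"total": 0, **{ns: 0 for ns in NAMESPACES}}
    for edge in graph.edges:
        row = census.counts.setdefault(
            edge.relation, {"total": 0, **{ns: 0 for ns in NAMESPACES}})
        row["total"] += 1
        ns = graph.nodes[edge.subject].namespace
        if ns in NAMESPACES:
            row[ns] += 1
    return census


def write_mapping_table(mapping: Mapping[str, Iterable[str]],
                        path: str | Path, fmt: str = "tsv") -> None:
    """Serialize a term -> ancestor-set table; round-trip safe.

    TSV is two columns (term, ancestor), one pair per line, sorted
    lexicographically; terms with empty ancestor sets are omitted from TSV
    (they carry no pairs) but retained in JSON.
    """
    path = Path(path)
    if fmt == "tsv":
        lines = ["# term\tancestor"]
        pairs = sorted((t, a) for t, anc in mapping.items() for a in anc)
        lines += [f"{t}\t{a}" for t, a in pairs]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        path.write_text(json.dumps(
            {t: sorted(anc) for t, anc in sorted(mapping.items())}, indent=0))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_mapping_table(path: str | Path) -> dict[str, set[str]]:
    """Inverse of :func:`write_mapping_table` (format sniffed)."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        return {t: set(anc) for t, anc in json.loads(text).items()}
    mapping: dict[str, set[str]] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        term, ancestor = line.split("\t")
        mapping.setdefault(term, set()).add(ancestor)
    return mapping
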
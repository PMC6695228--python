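"""GAF 2.x gene-association files and annotation-set expansion.

A GAF row associates a gene product (column 2) with a GO term (column 5).
For enrichment we reduce records to a gene -> term-set table, drop NOT-
qualified rows, and expand each gene's terms with their ancestors under a
chosen traversal policy — the "true path rule" applied explicitly, so that
a gene annotated to a fine-grained term also counts for every broader term
the policy can reach.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .ontology import ASPECT_OF_NAMESPACE, GO_ACCESSION, OntologyGraph
from .scoping import AncestorMap

GAF_COLUMNS = 17


class GafFormatError(ValueError):
    """Malformed GAF input; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class AnnotationRecord:
    """One GAF 2.x row; columns beyond the commonly used ones kept verbatim."""

    db: str
    object_id: str
    symbol: str
    qualifiers: tuple[str, ...]
    go_id: str
    evidence: str
    aspect: str
    taxon: str
    columns: tuple[str, ...]  # the full 17-column row

    @property
    def negated(self) -> bool:
        return "NOT" in self.qualifiers

    @classmethod
    def from_columns(cls, cols: Sequence[str]) -> "AnnotationRecord":
        return cls(
            db=cols[0], object_id=cols[1], symbol=cols[2],
            qualifiers=tuple(q for q in cols[3].split("|") if q),
            go_id=cols[4], evidence=cols[6], aspect=cols[8],
            taxon=cols[12], columns=tuple(cols),
        )

    def to_line(self) -> str:
        return "\t".join(self.columns)


def read_gaf(path: str | Path) -> list[AnnotationRecord]:
    """Parse a GAF 2.x file; comment lines skipped, column count enforced."""
    records: list[AnnotationRecord] = []
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip() or raw.startswith("!"):
            continue
        cols = raw.split("\t")
        if len(cols) != GAF_COLUMNS:
            raise GafFormatError(
                f"expected {GAF_COLUMNS} columns, found {len(cols)}", line_no)
        rec = AnnotationRecord.from_columns(cols)
        if not GO_ACCESSION.match(rec.go_id):
            raise GafFormatError(f"bad GO accession {rec.go_id!r}", line_no)
        records.append(rec)
    return records


@dataclass
class AnnotationSet:
    """Gene -> GO-term-set table, raw or ancestor-expanded."""

    annotations: dict[str, frozenset[str]]
    expanded: bool = False
    provenance: str = ""
    dropped_terms: int = 0  # terms unknown to the map during expansion

    @classmethod
    def from_records(cls, records: Iterable[AnnotationRecord],
                     evidence_exclude: Iterable[str] = (),
                     provenance: str = "") -> "AnnotationSet":
        """Build the raw gene->terms table.

        NOT-qualified records never contribute (they assert the absence of
        an association); records whose evidence code is in
        ``evidence_exclude`` are dropped as well.
        """
        excluded = set(evidence_exclude)
        table: dict[str, set[str]] = {}
        for rec in records:
            if rec.negated or rec.evidence in excluded:
                continue
            table.setdefault(rec.object_id, set()).add(rec.go_id)
        return cls({g: frozenset(t) for g, t in table.items()},
                   expanded=False, provenance=provenance)

    def genes(self) -> set[str]:
        return set(self.annotations)

    def __getitem__(self, gene: str) -> frozenset[str]:
        return self.annotations[gene]

    def genes_with_term(self, term: str) -> set[str]:
        return {g for g, terms in self.annotations.items() if term in terms}


def expand_annotations(ann: AnnotationSet, amap: AncestorMap) -> AnnotationSet:
    """Union each gene's term set with the ancestors of each term.

    Terms absent from the map (obsolete or from another release) contribute
    no ancestors and are counted in ``dropped_terms``; the terms themselves
    are kept only when the map knows them.  Expansion is idempotent because
    ancestor maps are transitively closed.
    """
    dropped = 0
    table: dict[str, frozenset[str]] = {}
    for gene, terms in ann.annotations.items():
        out: set[str] = set()
        for term in terms:
            if term in amap:
                out.add(term)
                out.update(amap[term])
            else:
                dropped += 1
        table[gene] = frozenset(out)
    return AnnotationSet(table, expanded=True,
                         provenance=f"{ann.provenance}+{amap.policy.label}",
                         dropped_terms=dropped)


def identity_gaf(graph: OntologyGraph, namespace: str | None = None,
                 path: str | Path | None = None) -> str:
    """A GAF in which each term annotates itself as if it were a gene.

    Feeding this file to any gene-level slim mapper turns it into a
    term-level mapper: the mapped file reads off, per term, which slim
    targets the mapper chose.  One line per non-obsolete term.
    """
    lines = ["!gaf-version: 2.1"]
    for tid in graph.terms(namespace=namespace):
        node = graph.nodes[tid]
        aspect = ASPECT_OF_NAMESPACE.get(node.namespace, "")
        cols = ["GOcats", tid, tid, "", tid, "GO_REF:0000000", "IEA", "",
                aspect, node.name, "", "term", "taxon:0000", "20160112",
                "GOcats", "", ""]
        lines.append("\t".join(cols))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_annotation_table(ann: AnnotationSet, path: str | Path) -> None:
    """Two-column (gene, term) TSV of an annotation set, sorted."""
    lines = ["# gene\tterm"]
    lines += [f"{g}\t{t}"
              for g, terms in sorted(ann.annotations.items())
              for t in sorted(terms)]
    Path(path).write_text("\n".join(lines) + "\n")
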
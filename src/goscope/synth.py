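"""Seeded generators for toy ontologies, annotation files and DE tables.

Every generator is deterministic in (spec, seed) and records ground truth
in a ledger as it builds the artifact, so downstream modules can be tested
against values the generator *knows* rather than values the package
computed.  The ontology generator only ever draws scoping edges from a
later-created term to an earlier-created term (has_part stored in the
opposite, whole->part direction), which makes the corrected scoped
subgraph acyclic by construction while still exercising the has_part
reinterpretation genuinely.

Ledger ancestor sets are accumulated in creation order directly from the
drawn parent lists — an independent computation from the traversal module,
usable as an oracle against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ontology import ASPECT_OF_NAMESPACE

SCOPING_CHOICES = ("is_a", "part_of", "has_part", "regulates")


class FixtureSpecError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Knobs for one synthetic study fixture; defaults are the test conditions."""

    seed: int = 0
    nodes_per_namespace: dict[str, int] = field(default_factory=lambda: {
        "biological_process": 60,
        "cellular_component": 30,
        "molecular_function": 20,
    })
    relation_mix: dict[str, float] = field(default_factory=lambda: {
        "is_a": 0.70, "part_of": 0.15, "has_part": 0.10, "regulates": 0.05,
    })
    max_out_degree: int = 3
    gene_count: int = 200
    signal_gene_count: int = 30
    planted_odds_ratio: float = 8.0
    annotations_per_gene: int = 2
    category_fraction: float = 0.15   # target share of terms under the root
    de_significant_fraction: float = 0.30
    de_effect_size: float = 2.0       # mean |log2 fold change| when significant

    def validate(self) -> None:
        if abs(sum(self.relation_mix.values()) - 1.0) > 1e-9:
            raise FixtureSpecError("relation mix proportions must sum to 1")
        if any(v < 0 for v in self.relation_mix.values()):
            raise FixtureSpecError("relation mix proportions must be >= 0")
        if any(n < 0 for n in self.nodes_per_namespace.values()):
            raise FixtureSpecError("node counts must be non-negative")
        if self.max_out_degree < 1:
            raise FixtureSpecError("max out-degree must be >= 1")
        if self.signal_gene_count > self.gene_count:
            raise FixtureSpecError("more signal genes than genes")


@dataclass
class FixtureLedger:
    """Ground truth recorded while generating one fixture."""

    edges: list[tuple[str, str, str]] = field(default_factory=list)
    relation_counts: dict[str, int] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)
    ancestors_gocats: dict[str, set[str]] = field(default_factory=dict)
    ancestors_no_hp: dict[str, set[str]] = field(default_factory=dict)
    planted_root: str = ""
    category_members: set[str] = field(default_factory=set)
    signal_genes: set[str] = field(default_factory=set)
    gene_annotations: dict[str, set[str]] = field(default_factory=dict)
    de_truth: dict[str, tuple[int, bool]] = field(default_factory=dict)
    de_categories: dict[str, str] = field(default_factory=dict)

    def terms(self) -> list[str]:
        return sorted(self.namespaces)

    def write_json(self, path: str | Path) -> None:
        payload = asdict(self)
        for key in ("category_members", "signal_genes"):
            payload[key] = sorted(payload[key])
        for key in ("ancestors_gocats", "ancestors_no_hp", "gene_annotations"):
            payload[key] = {k: sorted(v) for k, v in payload[key].items()}
        Path(path).write_text(json.dumps(payload, indent=0))


def _term_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def generate_ontology(spec: FixtureSpec) -> tuple[str, FixtureLedger]:
    """Emit an OBO document and the ledger of every truth about it."""
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0])
    ledger = FixtureLedger()
    labels = list(spec.relation_mix)
    probs = np.array([spec.relation_mix[r] for r in labels])

    counter = 0
    all_created: list[str] = []
    stanza_rel_lines: dict[str, list[str]] = {}
    stanza_isa_lines: dict[str, list[str]] = {}
    order: list[str] = []

    for namespace, count in spec.nodes_per_namespace.items():
        local: list[str] = []
        for i in range(count):
            tid = _term_id(counter)
            counter += 1
            ledger.namespaces[tid] = namespace
            stanza_isa_lines[tid] = []
            stanza_rel_lines[tid] = []
            order.append(tid)
            parents_g: set[str] = set()
            parents_nh: set[str] = set()
            if local:
                n_parents = int(rng.integers(1, min(spec.max_out_degree,
                                                    len(local)) + 1))
                chosen = rng.choice(len(local), size=n_parents, replace=False)
                for j in sorted(int(c) for c in chosen):
                    parent = local[j]
                    relation = labels[int(rng.choice(len(labels), p=probs))]
                    if relation == "is_a":
                        ledger.edges.append((tid, "is_a", parent))
                        stanza_isa_lines[tid].append(parent)
                        parents_g.add(parent)
                        parents_nh.add(parent)
                    elif relation == "part_of":
                        ledger.edges.append((tid, "part_of", parent))
                        stanza_rel_lines[tid].append(f"part_of {parent}")
                        parents_g.add(parent)
                        parents_nh.add(parent)
                    elif relation == "has_part":
                        # stored whole->part: subject is the earlier, broader term
                        ledger.edges.append((parent, "has_part", tid))
                        stanza_rel_lines[parent].append(f"has_part {tid}")
                        parents_g.add(parent)
                    else:  # regulates: non-scoping, may cross namespaces
                        target = all_created[int(rng.integers(len(all_created)))]
                        ledger.edges.append((tid, "regulates", target))
                        stanza_rel_lines[tid].append(f"regulates {target}")
                    ledger.relation_counts[relation] = \
                        ledger.relation_counts.get(relation, 0) + 1
            # creation-order accumulation: parents were all created earlier
            ledger.ancestors_gocats[tid] = set().union(
                *({p} | ledger.ancestors_gocats[p] for p in parents_g)) \
                if parents_g else set()
            ledger.ancestors_no_hp[tid] = set().union(
                *({p} | ledger.ancestors_no_hp[p] for p in parents_nh)) \
                if parents_nh else set()
            local.append(tid)
            all_created.append(tid)

    _plant_category(spec, ledger)

    lines = ["format-version: 1.2", "data-version: synthetic-fixture", ""]
    for tid in order:
        lines += [f"[Term]", f"id: {tid}",
                  f"name: synthetic term {tid[3:]}",
                  f"namespace: {ledger.namespaces[tid]}"]
        lines += [f"is_a: {p} ! parent" for p in stanza_isa_lines[tid]]
        lines += [f"relationship: {r} ! related" for r in stanza_rel_lines[tid]]
        lines.append("")
    for rel in ("part_of", "has_part", "regulates"):
        lines += ["[Typedef]", f"id: {rel}", f"name: {rel}", ""]
    return "\n".join(lines), ledger


def _plant_category(spec: FixtureSpec, ledger: FixtureLedger) -> None:
    """Choose the category root whose subgraph is closest to the target share."""
    terms = ledger.terms()
    if not terms:
        return
    target = spec.category_fraction * len(terms)
    sizes: dict[str, int] = {t: 1 for t in terms}  # each term is in its own category
    for t in terms:
        for anc in ledger.ancestors_gocats[t]:
            sizes[anc] += 1
    root = min(terms, key=lambda t: (abs(sizes[t] - target), t))
    ledger.planted_root = root
    ledger.category_members = {
        t for t in terms if t == root or root in ledger.ancestors_gocats[t]}


def generate_gaf(spec: FixtureSpec, ledger: FixtureLedger) -> str:
    """Emit a GAF 2.1 file with the planted term-category enrichment.

    Signal genes draw each annotation from inside the planted category with
    probability q chosen so that the per-annotation odds ratio against the
    uniform background equals ``planted_odds_ratio``; background genes draw
    uniformly over all terms.
    """
    rng = np.random.default_rng([spec.seed, 1])
    terms = ledger.terms()
    inside = sorted(ledger.category_members)
    outside = sorted(set(terms) - ledger.category_members)
    p_bg = len(inside) / len(terms) if terms else 0.0
    if inside and outside and 0 < p_bg < 1:
        odds = spec.planted_odds_ratio * p_bg / (1 - p_bg)
        q = odds / (1 + odds)
    else:
        q = p_bg

    lines = ["!gaf-version: 2.1"]
    genes = [f"GENE{i + 1:04d}" for i in range(spec.gene_count)]
    ledger.signal_genes = set(genes[:spec.signal_gene_count])
    for gene in genes:
        signal = gene in ledger.signal_genes
        annotated: set[str] = set()
        for _ in range(spec.annotations_per_gene):
            if signal and inside and outside:
                pool = inside if rng.random() < q else outside
            else:
                pool = terms
            annotated.add(pool[int(rng.integers(len(pool)))])
        ledger.gene_annotations[gene] = annotated
        for term in sorted(annotated):
            aspect = ASPECT_OF_NAMESPACE.get(ledger.namespaces[term], "")
            cols = ["SYNTH", gene, gene, "", term, "GO_REF:0000000", "IEA",
                    "", aspect, "", "", "protein", "taxon:0000", "20160112",
                    "SYNTH", "", ""]
            lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


_TS_CATEGORIES = (
    ("early_positive", 0.08), ("early_negative", 0.08),
    ("late_positive", 0.08), ("late_negative", 0.08),
    ("transient_positive", 0.08), ("transient_negative", 0.08),
    ("consistent_positive", 0.06), ("consistent_negative", 0.06),
    ("none", 0.40),
)


def _draw_padj(rng: np.random.Generator, significant: bool) -> float:
    if significant:
        return float(10 ** rng.uniform(-8, np.log10(0.009)))
    return float(rng.uniform(0.02, 1.0))


def _draw_lfc(rng: np.random.Generator, spec: FixtureSpec, sign: int,
              significant: bool) -> float:
    if significant:
        return sign * float(abs(rng.normal(spec.de_effect_size, 0.5)) + 0.1)
    return float(rng.normal(0.0, 0.2))


def generate_de_table(spec: FixtureSpec, ledger: FixtureLedger,
                      contrasts: int = 1) -> list[pd.DataFrame]:
    """Emit one or two DESeq2-style result tables with planted truth.

    One contrast plants per-gene (sign, significance); two contrasts plant
    the early/late/transient/consistent time-series categories, recorded in
    the ledger.
    """
    if contrasts not in (1, 2):
        raise FixtureSpecError("contrasts must be 1 or 2")
    rng = np.random.default_rng([spec.seed, 2, contrasts])
    genes = [f"GENE{i + 1:04d}" for i in range(spec.gene_count)]

    if contrasts == 1:
        rows = []
        for gene in genes:
            significant = bool(rng.random() < spec.de_significant_fraction)
            sign = 1 if rng.random() < 0.5 else -1
            ledger.de_truth[gene] = (sign if significant else 0, significant)
            rows.append((gene, _draw_lfc(rng, spec, sign, significant),
                         _draw_padj(rng, significant)))
        return [pd.DataFrame(rows, columns=["gene", "log2FoldChange", "padj"])]

    names = [c for c, _ in _TS_CATEGORIES]
    probs = np.array([p for _, p in _TS_CATEGORIES])
    rows1, rows2 = [], []
    for gene in genes:
        cat = names[int(rng.choice(len(names), p=probs))]
        ledger.de_categories[gene] = cat
        kind, _, signname = cat.partition("_")
        sign = 1 if signname == "positive" else -1
        sig1 = kind in ("early", "transient", "consistent")
        sig2 = kind in ("late", "transient", "consistent")
        sign1 = sign
        sign2 = {"transient": -sign}.get(kind, sign)
        rows1.append((gene, _draw_lfc(rng, spec, sign1, sig1),
                      _draw_padj(rng, sig1)))
        rows2.append((gene, _draw_lfc(rng, spec, sign2, sig2),
                      _draw_padj(rng, sig2)))
    cols = ["gene", "log2FoldChange", "padj"]
    return [pd.DataFrame(rows1, columns=cols), pd.DataFrame(rows2, columns=cols)]


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> FixtureLedger:
    """Generate ontology + GAF + DE tables into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obo, ledger = generate_ontology(spec)
    (outdir / "fixture.obo").write_text(obo)
    (outdir / "fixture.gaf").write_text(generate_gaf(spec, ledger))
    for i, table in enumerate(generate_de_table(spec, ledger, contrasts=2), 1):
        table.to_csv(outdir / f"de_contrast{i}.tsv", sep="\t", index=False)
    ledger.write_json(outdir / "ledger.json")
    return ledger
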
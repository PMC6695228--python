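import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from goscope import parse_obo

HEADER = "format-version: 1.2\n\n"


def obo_text(stanzas):
    """Assemble an OBO document from (id, namespace, lines) triples."""
    chunks = [HEADER]
    for tid, namespace, lines in stanzas:
        chunk = [f"[Term]", f"id: {tid}", f"name: name {tid}",
                 f"namespace: {namespace}", *lines, ""]
        chunks.append("\n".join(chunk))
    return "\n".join(chunks)


@pytest.fixture
def write_obo(tmp_path):
    def _write(stanzas, name="test.obo"):
        path = tmp_path / name
        path.write_text(obo_text(stanzas))
        return path
    return _write


@pytest.fixture
def toy_hp_graph(write_obo):
    """W is_a R; Q is_a R; P is_a Q; D1 is_a W; (W, has_part, P).

    Hand-enumerable corrected closure: anc(P) = {Q, R, W}, anc(D1) = {W, R};
    the has_part edge's problem sets are PA = {P, Q}, PD = {W, D1}.
    """
    path = write_obo([
        ("GO:0000001", "cellular_component", []),                      # R
        ("GO:0000002", "cellular_component",
         ["is_a: GO:0000001", "relationship: has_part GO:0000004"]),   # W
        ("GO:0000003", "cellular_component", ["is_a: GO:0000001"]),    # Q
        ("GO:0000004", "cellular_component", ["is_a: GO:0000003"]),    # P
        ("GO:0000005", "cellular_component", ["is_a: GO:0000002"]),    # D1
    ])
    return parse_obo(path)


@pytest.fixture
def chain_graph(write_obo):
    """The published is_a chain: connective tissue development -> ... ->
    developmental process."""
    path = write_obo([
        ("GO:0032502", "biological_process", []),
        ("GO:0048856", "biological_process", ["is_a: GO:0032502"]),
        ("GO:0009888", "biological_process", ["is_a: GO:0048856"]),
        ("GO:0061448", "biological_process", ["is_a: GO:0009888"]),
    ])
    return parse_obo(path)


@pytest.fixture
def hp_only_graph(write_obo):
    """Single reinterpretable edge: (nucleus, has_part, chromosome)."""
    path = write_obo([
        ("GO:0005634", "cellular_component",
         ["relationship: has_part GO:0005694"]),  # nucleus
        ("GO:0005694", "cellular_component", []),  # chromosome
    ])
    return parse_obo(path)


@pytest.fixture
def hp_sensitive_fixture(write_obo, tmp_path):
    """Ontology + GAF where annotated terms reach the category root only
    through a has_part edge.

    Root R anchors branch W; the signal leaves L1..L6 sit under bridge term
    B, and B connects upward only via (W, has_part, B).  A decoy branch D
    with its own leaves keeps the root tested but unenriched for background
    genes.  Signal genes annotate the L leaves; background genes annotate
    the decoy leaves.
    """
    stanzas = [
        ("GO:0000001", "cellular_component", []),                      # R
        ("GO:0000002", "cellular_component",
         ["is_a: GO:0000001", "relationship: has_part GO:0000003"]),   # W
        ("GO:0000003", "cellular_component", []),                      # B
        ("GO:0000010", "cellular_component", []),                      # D root
    ]
    signal_terms = []
    for i in range(6):
        tid = f"GO:00001{i:02d}"
        stanzas.append((tid, "cellular_component", ["is_a: GO:0000003"]))
        signal_terms.append(tid)
    decoy_terms = []
    for i in range(6):
        tid = f"GO:00002{i:02d}"
        stanzas.append((tid, "cellular_component", ["is_a: GO:0000010"]))
        decoy_terms.append(tid)
    path = write_obo(stanzas, "hp_sensitive.obo")

    lines = ["!gaf-version: 2.1"]

    def gaf_line(gene, term):
        cols = ["SYNTH", gene, gene, "", term, "GO_REF:0000000", "IEA", "",
                "C", "", "", "protein", "taxon:0000", "20160112", "SYNTH",
                "", ""]
        return "\t".join(cols)

    signal_genes = [f"SIG{i:03d}" for i in range(20)]
    for i, gene in enumerate(signal_genes):
        lines.append(gaf_line(gene, signal_terms[i % len(signal_terms)]))
    background = [f"BG{i:03d}" for i in range(80)]
    for i, gene in enumerate(background):
        lines.append(gaf_line(gene, decoy_terms[i % len(decoy_terms)]))
    # a couple of background genes annotated directly under the root branch
    # keep the root term tested under the traditional policy too
    for gene in background[:4]:
        lines.append(gaf_line(gene, "GO:0000002"))
    gaf_path = tmp_path / "hp_sensitive.gaf"
    gaf_path.write_text("\n".join(lines) + "\n")
    return {
        "graph": parse_obo(path),
        "gaf": gaf_path,
        "root": "GO:0000001",
        "signal_genes": set(signal_genes),
        "universe": set(signal_genes) | set(background),
    }
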
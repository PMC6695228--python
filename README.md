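# goscope

Scoping-semantics-aware Gene Ontology traversal, mapping audits, and
annotation enrichment.

## The problem

Gene Ontology (GO) annotation enrichment depends on *mapping* fine-grained
terms onto broader ones by walking relation edges in the ontology graph.
`is_a` and `part_of` edges point from the narrower term to the broader term,
so following them upward is safe.  `has_part` does the opposite: the edge
subject is the **whole** and the object the **part** (every *nucleus*
has_part *chromosome*), so a mapper that follows it blindly walks *down* in
scope and fabricates mappings such as "nuclear envelope → plasma membrane".
The common fixes both hurt: label-blind mappers (the Map2Slim failure mode)
produce false mappings, while dropping `has_part` entirely — the
traditional, go-basic-style choice — silently loses every specific-to-general
mapping whose path crosses such an edge.

`goscope` implements the corrective: treat each `has_part` edge as
**part_of_some**, i.e. traverse it from part to whole, so that *every*
scoping edge points from narrower to broader term.  The resulting scoped
subgraph of go-core stays acyclic, no information is discarded, and ancestor
maps built from it strictly contain the traditional ones.  The package also
quantifies exactly what is at stake: for each `has_part` edge *e* with whole
*w* and part *p* it forms the problematic ancestors and descendants

```
PA_e = (anc(p) ∪ {p}) − (anc(w) ∪ {w})
PD_e = (desc(w) ∪ {w}) − (desc(p) ∪ {p})
```

whose product `PD_e × PA_e` is the set of term mappings the native edge
direction could fabricate; unioning over edges gives the estimated potential
false mappings (epM_F), compared against the true mapping pairs M_T =
{(d, a) : a ∈ anc(d)} and against the pairs a label-blind traversal emits.

Downstream, gene sets from differential-expression contrasts are tested for
term over-representation with the one-sided hypergeometric tail and
Benjamini–Hochberg FDR, and the corrected traversal is scored against the
traditional one by counting, over the traditionally significant terms, how
many adjusted p-values strictly improve — a coin-toss count tested with the
exact one-sided binomial tail at p = 1/2, ties excluded.

## Worked example

Generate a seeded synthetic ontology + annotation fixture and audit it:

```bash
$ goscope fixtures --seed 11 --out demo
wrote fixture with 110 terms, 200 genes to demo

$ goscope census demo/fixture.obo
        total   cellular_component      biological_process      molecular_function
has_part        23      7       13      3
is_a    165     43      93      29
part_of 25      5       15      5
regulates       9       3       4       2

$ goscope audit demo/fixture.obo --relation has_part
scope  relation  estimated_false  true_mappings  intersection  net_false  true_without_relation  lost
all    has_part  1384             741            346           1038       591                    150

$ goscope acyclic demo/fixture.obo
acyclic
```

Reading the audit row: the fixture's 23 `has_part` edges could fabricate
1384 candidate mappings if followed natively, of which 1038 are not real
mappings under the corrected traversal (`net_false`); conversely, dropping
`has_part` shrinks the 741 true mapping pairs to 591 — 150 specific-to-
general mappings (20%) are lost by the traditional policy.  The corrected
graph is acyclic, so it supports ordinary DAG traversal.

The improvement statistic is exposed directly; for instance, 182 improved
adjusted p-values out of 217 paired comparisons gives

```python
>>> from goscope import binomial_improvement_test
>>> print(f"{binomial_improvement_test(182, 217):.3g}")
1.86e-25
```

Other entry points: `goscope ancestors` (term→ancestors tables per policy:
`gocats`, `no_hp`, `go-basic-scoping`), `goscope categories` (map terms to
category roots), `goscope naive-error` (label-blind-mapper error table),
`goscope expand` / `goscope enrich` / `goscope compare` (GAF expansion,
hypergeometric enrichment, paired-policy comparison), and
`goscope timeseries` (term-set algebra across time-series contrasts).

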
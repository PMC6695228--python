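# Methods

## The graph model

go-core-style OBO 1.2 documents are parsed into a relation-typed directed
graph: one node per `[Term]` stanza, one labelled edge per `is_a` or
`relationship` line, labels preserved verbatim.  Terms carry one of the
three sub-ontology namespaces (cellular_component, biological_process,
molecular_function).  Obsolete terms stay in the node table but are barred
from edges: an edge written from or into an obsolete stanza is dropped and
recorded as a warning.  `alt_id` lines populate an alias table and edge
targets written against secondary accessions are rewritten onto the primary
id before attachment; targets that never resolve are dropped as dangling
with the source line number.  Duplicate (subject, relation, object) triples
are deduplicated with a counter.  `intersection_of` lines and all stanza
keys other than id/name/namespace/alt_id/is_a/relationship/is_obsolete are
ignored — the asserted is_a/relationship lines carry the graph structure the
analyses need.  `[Typedef]` stanzas only register known relation labels;
unknown labels parse fine and are simply non-scoping.

## Scoping policies

A policy is (i) a set of relation labels that count as scoping and (ii) a
per-label direction rule saying which end of a stored edge is the broader
term.  The defaults follow the relation semantics: the stanza subject is
the narrower term for `is_a` and `part_of`, and the broader term (the
whole) for `has_part`.  Three named policies:

* **gocats** — {is_a, part_of, has_part} with `has_part` reinterpreted as
  part_of_some, i.e. traversed object→subject (part→whole);
* **no_hp** — {is_a, part_of}: the traditional traversal that drops
  has_part;
* **go-basic-scoping** — same relation set as no_hp, provided as a separate
  name because it describes a restriction to the relations go-basic
  retains rather than a choice made on go-core.

Ancestor sets are the transitive closure of the policy's narrower→broader
edges, computed by reverse-topological accumulation on the scoped digraph;
a cycle raises an error naming one explicit cycle (cycle detection is also
exposed separately as a check that returns the cycle rather than raising).
Ancestor sets exclude the term itself.  Cross-namespace scoping edges are
traversed by default, matching go-core's structure; a namespace restriction
is available for per-sub-ontology audits.  Category maps send a term to
every requested root found in {term} ∪ anc(term) — the root anchors its own
category, so genes annotated directly to a category root still count for
it.  Output orderings are sorted everywhere so repeated runs produce
byte-identical files.

## The mapping audit

For a `has_part` edge with whole *w* and part *p*, the problematic
ancestors are PA = (anc(p) ∪ {p}) − (anc(w) ∪ {w}) and the problematic
descendants PD = (desc(w) ∪ {w}) − (desc(p) ∪ {p}); the edge's potential
false mappings are PD × PA minus self-pairs, and the estimated total
(epM_F) is the union over edges.  Both closures are taken over the
*corrected* scoping graph, because the audit intersects these pairs with
the true mapping pairs M_T from that same graph; a sensitivity flag can
switch the closures to {is_a, part_of}.  Net potential false mappings are
pM_F = epM_F − |M_T ∩ epM_F|, and information loss is |M_T| minus the pair
count with the relation dropped.  When a namespace scope is requested, the
*pairs* are filtered (both endpoints must carry the namespace) while edges
and closures remain graph-wide, so paths detouring through another
namespace still contribute in-scope pairs.

The naive mapper emulation follows every stored relationship line in its
subject→object direction regardless of label — has_part and regulates
traversed as if they were is_a.  Because stored directions can form cycles,
reachability is computed on the strongly-connected-component condensation.
Its error table intersects the naive pairs (per scope) with the graph-wide
corrected pair set; the primary error fraction divides the non-intersecting
remainder by the naive pair count in scope, which is the convention under
which correct + potentially-false sums to the naive total.  The alternative
ratio dividing by the corrected scoping pair count is reported as a
secondary field.  Self-mappings are excluded from every pair set.

## Annotations and enrichment

GAF 2.x rows are reduced to gene → term-set tables keyed by the column-2
object id (no symbol-level merging).  NOT-qualified rows are excluded from
these tables (they assert an absence); no evidence-code filter is applied
by default, with an optional exclude list.  Expansion unions each gene's
terms with their ancestors under a chosen policy's map; terms unknown to
the map contribute nothing and are counted.  Since the maps are
transitively closed, expansion is idempotent, and the no_hp expansion of
every gene is a subset of its corrected-policy expansion.  An identity GAF
(each term annotating itself as a pseudo-gene) is provided to turn
gene-level slim mappers into term-level mappers for external comparisons.

Enrichment of a gene set against a universe uses the one-sided
hypergeometric tail P(X ≥ k) for each term annotated to at least one
universe gene, followed by Benjamini–Hochberg adjustment across all tested
terms (scipy and statsmodels supply the tail and the step-up adjustment).
The universe defaults to all annotated genes; unannotated universe genes
are dropped with a warning.  Significance is adjusted p ≤ 0.01 (the ≤
convention, configurable).  Only over-representation is tested.

The policy comparison takes the traditional result as reference: over its
significant terms, exact adjusted-p ties are excluded, terms missing from
the corrected result count as not improved, and the number of strict
improvements is scored with the exact one-sided binomial tail at p = 1/2.
With zero comparable terms after tie exclusion the test is undefined and
raises.  Uniquely significant terms on each side are reported alongside.

Differential-expression tables (gene, log2FoldChange, padj) are classified
at adjusted p ≤ α into positive/negative/all by fold-change sign; rows with
missing padj are skipped with a warning and a significant row with exactly
zero fold change is rejected as contradictory.  Across two consecutive
contrasts, genes are classified early (significant in the first only),
late (second only), transient (both, opposite signs) or consistent (both,
same sign), each split by sign — transient and consistent take the first
interval's sign, late the second's.  The time-series term-set algebra
derives, per tissue, unique = early_gocats − early_no_hp − transient_no_hp
(likewise for late) and supported = unique ∩ consistent_no_hp.  The
operand of the supported-set intersection is genuinely ambiguous (the
unique set versus the full corrected-policy difference); both are computed,
with the unique-set variant primary and the other exposed under a
`*_supported_full` key.

## Synthetic fixtures

The generators emulate the study's inputs at desk scale: a three-namespace
ontology (default 60 BP / 30 CC / 20 MF terms) with a relation mix of 70%
is_a, 15% part_of, 10% has_part, 5% regulates and max out-degree 3; a GAF
over 200 genes with 2 annotations each; and DESeq2-like result tables.
Scoping edges are drawn only from later-created to earlier-created terms —
has_part stored in the opposite, whole→part direction — so the corrected
scoped subgraph is acyclic by construction while still exercising the
reinterpretation.  A category root is chosen as the term whose subgraph
share is closest to 15% of all terms; 30 of the 200 genes are signal genes
whose per-annotation draws favour in-category terms at an odds ratio of 8
against the uniform background.  These defaults give a planted effect
strong enough that recovery failures indicate real traversal or statistics
bugs rather than sampling noise, while a zero-signal variant provides null
calibration material.  DE tables plant 30% significant genes with mean
|log2 fold change| 2; significant padj values are drawn log-uniformly in
[10⁻⁸, 9·10⁻³] and non-significant ones uniformly in [0.02, 1].

Each artifact uses its own seeded random stream (seed-keyed generators for
ontology, GAF and DE tables), so identical spec + seed reproduces
byte-identical files, and a ledger records every truth as it is generated —
edge lists, ancestor closures accumulated in creation order (an
implementation-independent computation), category membership, per-gene
annotations and DE truth — so tests compare the package's outputs against
recorded ground truth rather than against itself.

What the fixtures do *not* emulate: real GO's term-depth and fan-in
distributions, annotation evidence-code structure, inter-gene correlation,
or the heterogeneous relation composition of paths in go-core.  Passing the
fixture-based suite therefore demonstrates correctness of the set algebra,
traversal semantics and statistics, not that effect sizes measured on the
fixtures transfer to a real release; release-scale audit counts require
running the same commands on an actual go-core OBO file.

## Numerical and design notes

* Exact tails only: hypergeometric and binomial p-values come from exact
  distribution functions, not normal approximations; BH adjustment is the
  standard step-up capped at 1.
* Tie detection in the paired comparison uses exact floating equality of
  the adjusted p-values, which is the intended semantics of excluding
  identical values computed from identical inputs.
* Problem sizes in the default suite: 50 fixtures of ≤ 55 terms for oracle
  equivalence (brute-force reachability cross-checks), 100 replicates of
  the 110-term/200-gene fixture for planted recovery, 200 null draws for
  calibration — sizes chosen so exhaustive brute-force verification remains
  the oracle of record.
* Known limitations: OWL/go-plus inputs are out of scope; relation labels
  beyond the curated correspondence table are treated as non-scoping rather
  than heuristically classified; the naive-mapper emulation models
  label-blind traversal semantics directly rather than wrapping an external
  Map2Slim binary.
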
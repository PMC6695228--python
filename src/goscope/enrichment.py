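"""Annotation enrichment and the paired traversal-policy comparison.

Enrichment is the standard one-sided over-representation test: for a gene
set of size n drawn from a universe of N annotated genes, a term carried by
K universe genes and k set genes gets the hypergeometric tail
P(X >= k), followed by Benjamini-Hochberg adjustment across all tested
terms.  The policy comparison then asks, over the terms the traditional
({is_a, part_of}) traversal already calls significant, how often the
corrected traversal (has_part reinterpreted as part_of_some) produces a
strictly smaller adjusted p-value; under the null of no systematic effect
improvements are coin flips, so the count is scored with an exact one-sided
binomial tail at p = 1/2 (ties excluded).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gaf import AnnotationSet


class ClassificationError(ValueError):
    pass


@dataclass
class GeneSetPartition:
    """Signed gene sets for one contrast, or time-series categories.

    For a single contrast only ``positive``/``negative`` are filled; the
    time-series classifier fills the eight early/late/transient/consistent
    signed sets instead (sign of transient genes follows the first
    interval's fold change).
    """

    label: str
    positive: frozenset[str] = frozenset()
    negative: frozenset[str] = frozenset()
    categories: dict[str, frozenset[str]] = field(default_factory=dict)
    skipped: int = 0
    excluded: int = 0

    @property
    def all(self) -> frozenset[str]:
        return self.positive | self.negative


def classify_de_genes(table: pd.DataFrame, alpha: float = 0.01,
                      label: str = "") -> GeneSetPartition:
    """Split significantly changing genes by fold-change sign.

    ``table`` needs columns gene, log2FoldChange, padj.  Rows with missing
    adjusted p are skipped (DESeq2 emits NA for independently filtered
    genes); a significant row with a fold change of exactly zero is
    contradictory and raises.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    pos, neg = set(), set()
    skipped = 0
    for row in table.itertuples(index=False):
        padj = float(row.padj)
        if math.isnan(padj):
            skipped += 1
            continue
        if padj > alpha:
            continue
        lfc = float(row.log2FoldChange)
        if lfc > 0:
            pos.add(row.gene)
        elif lfc < 0:
            neg.add(row.gene)
        else:
            raise ClassificationError(
                f"gene {row.gene}: significant (padj={padj}) with zero fold change")
    if skipped:
        warnings.warn(f"{skipped} rows with missing padj skipped")
    return GeneSetPartition(label or "contrast", frozenset(pos), frozenset(neg),
                            skipped=skipped)


def classify_time_series(interval1: pd.DataFrame, interval2: pd.DataFrame,
                         alpha: float = 0.01,
                         label: str = "") -> GeneSetPartition:
    """Classify genes across two consecutive contrasts.

    early: significant in the first interval only; late: in the second
    only; transient: significant in both with opposite signs; consistent:
    significant in both with the same sign.  Signed variants carry the
    first interval's sign for early/transient/consistent and the second's
    for late.  Genes present in only one table are excluded with a warning.
    """
    p1 = classify_de_genes(interval1, alpha, "interval1")
    p2 = classify_de_genes(interval2, alpha, "interval2")
    g1 = set(interval1["gene"])
    g2 = set(interval2["gene"])
    shared = g1 & g2
    excluded = len(g1 ^ g2)
    if excluded:
        warnings.warn(f"{excluded} genes present in only one table excluded")

    cats: dict[str, set[str]] = {
        f"{c}_{s}": set()
        for c in ("early", "late", "transient", "consistent")
        for s in ("positive", "negative")}
    for gene in shared:
        s1 = (1 if gene in p1.positive else -1 if gene in p1.negative else 0)
        s2 = (1 if gene in p2.positive else -1 if gene in p2.negative else 0)
        if s1 and not s2:
            cats[f"early_{'positive' if s1 > 0 else 'negative'}"].add(gene)
        elif s2 and not s1:
            cats[f"late_{'positive' if s2 > 0 else 'negative'}"].add(gene)
        elif s1 and s2:
            kind = "consistent" if s1 == s2 else "transient"
            cats[f"{kind}_{'positive' if s1 > 0 else 'negative'}"].add(gene)
    part = GeneSetPartition(
        label or "time-series",
        positive=frozenset(cats["early_positive"] | cats["late_positive"]
                           | cats["transient_positive"]
                           | cats["consistent_positive"]),
        negative=frozenset(cats["early_negative"] | cats["late_negative"]
                           | cats["transient_negative"]
                           | cats["consistent_negative"]),
        categories={k: frozenset(v) for k, v in cats.items()},
        excluded=excluded)
    return part


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """One-sided over-representation tail P(X >= k), X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order preserving."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    arr = np.asarray(pvalues, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


@dataclass
class EnrichmentResult:
    """Per-term hypergeometric enrichment table for one gene set."""

    table: pd.DataFrame  # term, k, K, n, N, pvalue, padj, significant
    alpha: float
    label: str = ""
    dropped_genes: int = 0

    def significant_terms(self) -> set[str]:
        return set(self.table.loc[self.table["significant"], "term"])

    def padj_of(self) -> dict[str, float]:
        return dict(zip(self.table["term"], self.table["padj"]))


def enrich(genes: set[str], universe: set[str], ann: AnnotationSet,
           alpha: float = 0.01, label: str = "") -> EnrichmentResult:
    """Hypergeometric over-representation of every annotated term.

    ``ann`` should be ancestor-expanded so the true-path rule applies.
    Universe genes without annotations are dropped (with a warning); every
    term annotated to at least one remaining universe gene is tested, and
    BH adjustment runs across all tested terms.
    """
    if not genes:
        raise ValueError("empty gene set")
    if not genes <= universe:
        raise ValueError("gene set is not a subset of the universe")
    annotated = universe & ann.genes()
    dropped = len(universe) - len(annotated)
    if dropped:
        warnings.warn(f"{dropped} universe genes without annotations dropped")
    set_genes = genes & annotated
    N, n = len(annotated), len(set_genes)

    term_universe: dict[str, int] = {}
    term_set: dict[str, int] = {}
    for gene in annotated:
        in_set = gene in set_genes
        for term in ann[gene]:
            term_universe[term] = term_universe.get(term, 0) + 1
            if in_set:
                term_set[term] = term_set.get(term, 0) + 1
    terms = sorted(term_universe)
    ks = [term_set.get(t, 0) for t in terms]
    Ks = [term_universe[t] for t in terms]
    pvals = [hypergeom_pvalue(k, K, n, N) for k, K in zip(ks, Ks)]
    padj = bh_adjust(pvals)
    table = pd.DataFrame({
        "term": terms, "k": ks, "K": Ks, "n": n, "N": N,
        "pvalue": pvals, "padj": padj,
        "significant": [p <= alpha for p in padj],
    })
    return EnrichmentResult(table, alpha, label, dropped)


def binomial_improvement_test(n_improved: int, n_compared: int) -> float:
    """Exact one-sided tail P(X >= n_improved), X ~ Binomial(n_compared, 1/2)."""
    if n_compared < 1:
        raise ValueError("binomial test undefined for zero comparisons")
    if not 0 <= n_improved <= n_compared:
        raise ValueError("n_improved must lie in [0, n_compared]")
    return float(stats.binom.sf(n_improved - 1, n_compared, 0.5))


@dataclass
class EnrichmentComparison:
    """Paired comparison of two enrichment runs on the same gene set."""

    n_significant_reference: int
    n_ties: int
    n_improved: int
    binomial_pvalue: float
    unique_reference: frozenset[str]  # significant only under the reference
    unique_alternate: frozenset[str]  # significant only under the alternate

    @property
    def n_compared(self) -> int:
        return self.n_significant_reference - self.n_ties

    @property
    def n_not_improved(self) -> int:
        return self.n_compared - self.n_improved


def compare_enrichments(reference: EnrichmentResult,
                        alternate: EnrichmentResult,
                        alpha: float = 0.01) -> EnrichmentComparison:
    """Score the alternate traversal against the reference one.

    Over terms the reference calls significant (adjusted p <= alpha):
    exact adjusted-p ties are excluded, terms absent from the alternate
    count as not improved, and the improvement count is scored with the
    exact one-sided binomial tail at p = 1/2.  Raises when every compared
    term is a tie (the test is undefined).
    """
    ref_padj = reference.padj_of()
    alt_padj = alternate.padj_of()
    if not set(ref_padj) & set(alt_padj):
        warnings.warn("reference and alternate share no tested terms")
    ref_sig = {t for t, p in ref_padj.items() if p <= alpha}
    alt_sig = {t for t, p in alt_padj.items() if p <= alpha}

    ties = improved = 0
    for term in ref_sig:
        if term not in alt_padj:
            continue  # absent from alternate: counted as not improved
        if alt_padj[term] == ref_padj[term]:
            ties += 1
        elif alt_padj[term] < ref_padj[term]:
            improved += 1
    n_compared = len(ref_sig) - ties
    if n_compared == 0:
        raise ValueError(
            "no reference-significant terms" if not ref_sig
            else "all compared terms tied; improvement test undefined")
    return EnrichmentComparison(
        n_significant_reference=len(ref_sig),
        n_ties=ties,
        n_improved=improved,
        binomial_pvalue=binomial_improvement_test(improved, n_compared),
        unique_reference=frozenset(ref_sig - alt_sig),
        unique_alternate=frozenset(alt_sig - ref_sig),
    )


@dataclass
class TimeSeriesTermSets:
    """Significantly enriched term sets across a two-interval time series."""

    early_gocats: frozenset[str]      # first interval, corrected traversal
    early_no_hp: frozenset[str]       # first interval, traditional traversal
    late_gocats: frozenset[str]       # second interval, corrected traversal
    late_no_hp: frozenset[str]        # second interval, traditional traversal
    transient_no_hp: frozenset[str]   # transient gene set, traditional
    consistent_no_hp: frozenset[str]  # consistent gene set, traditional


def time_series_term_sets(inputs: TimeSeriesTermSets) -> dict[str, frozenset[str]]:
    """Set algebra isolating what the corrected traversal adds per interval.

    * early_unique  = early_gocats − early_no_hp − transient_no_hp
    * late_unique   = late_gocats − late_no_hp − transient_no_hp
    * *_supported   = *_unique ∩ consistent_no_hp (primary variant); the
      variant intersecting the full corrected set before transient removal
      is reported under ``*_supported_full``.
    """
    early_unique = (inputs.early_gocats - inputs.early_no_hp
                    - inputs.transient_no_hp)
    late_unique = (inputs.late_gocats - inputs.late_no_hp
                   - inputs.transient_no_hp)
    early_full = inputs.early_gocats - inputs.early_no_hp
    late_full = inputs.late_gocats - inputs.late_no_hp
    return {
        "early_unique": frozenset(early_unique),
        "early_supported": frozenset(early_unique & inputs.consistent_no_hp),
        "early_supported_full": frozenset(early_full & inputs.consistent_no_hp),
        "late_unique": frozenset(late_unique),
        "late_supported": frozenset(late_unique & inputs.consistent_no_hp),
        "late_supported_full": frozenset(late_full & inputs.consistent_no_hp),
    }
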
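"""Quantifying what each traversal policy gets wrong, or loses.

Three bookkeeping exercises over ordered (descendant, ancestor) term pairs:

* **Per-edge false-mapping potential.**  Every ``has_part`` edge, read in
  its stored whole->part direction, invites mappings from the whole's side
  of the graph onto the part's side.  For an edge with whole ``w`` and part
  ``p`` the *problematic ancestors* are the terms above the part that are
  not above the whole, and the *problematic descendants* are the terms
  below the whole that are not below the part; their Cartesian product is
  the set of term mappings the native edge direction could fabricate.
* **True mappings and information loss.**  The set of all (descendant,
  ancestor) pairs under the corrected policy measures the retrievable
  mapping information; recomputing it with has_part dropped shows how many
  pairs the traditional policy loses.
* **Naive-mapper emulation.**  A mapper that follows *every* stored edge
  direction regardless of label (the Map2Slim failure mode) produces a
  pair set whose difference from the corrected scoping pairs is its
  potential error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .ontology import NAMESPACES, OntologyGraph, RelationEdge
from .scoping import (AncestorMap, ScopingPolicy, build_ancestor_map,
                      build_descendant_map)

Pair = tuple[str, str]


@dataclass
class MappingPairSet:
    """A set of ordered (descendant, ancestor) pairs with a provenance tag."""

    pairs: frozenset[Pair]
    label: str = ""

    def __post_init__(self) -> None:
        self.pairs = frozenset((d, a) for d, a in self.pairs if d != a)

    def __len__(self) -> int:
        return len(self.pairs)

    def __and__(self, other: "MappingPairSet") -> "MappingPairSet":
        return MappingPairSet(self.pairs & other.pairs,
                              f"({self.label} & {other.label})")

    def __sub__(self, other: "MappingPairSet") -> "MappingPairSet":
        return MappingPairSet(self.pairs - other.pairs,
                              f"({self.label} - {other.label})")


@dataclass
class EdgeProblemSets:
    """Problematic ancestors/descendants induced by one has_part edge."""

    edge: RelationEdge
    problematic_ancestors: frozenset[str]
    problematic_descendants: frozenset[str]


@dataclass
class AuditReport:
    """Per-scope tallies of estimated/net false mappings and lost mappings."""

    scope: str
    relation: str
    estimated_false: int          # pair count from per-edge products (epM_F)
    true_mappings: int            # corrected-policy pair count (M_T)
    intersection: int             # |true ∩ estimated-false|
    net_false: int                # estimated_false - intersection (pM_F)
    true_without_relation: int    # pair count with the relation dropped
    lost: int                     # true_mappings - true_without_relation

    @property
    def false_fraction(self) -> float:
        return self.net_false / self.true_mappings if self.true_mappings else 0.0

    @property
    def lost_fraction(self) -> float:
        return self.lost / self.true_mappings if self.true_mappings else 0.0


@dataclass
class NaiveErrorReport:
    """Per-scope comparison of naive (label-blind) pairs vs corrected pairs."""

    rows: dict[str, dict[str, float]] = field(default_factory=dict)

    def frame(self):
        import pandas as pd

        return pd.DataFrame.from_dict(self.rows, orient="index")


def _scope_filter(graph: OntologyGraph, pairs: frozenset[Pair],
                  scope: str | None) -> frozenset[Pair]:
    """Keep pairs whose *both* endpoints carry the given namespace."""
    if scope is None:
        return pairs
    members = {tid for tid, n in graph.nodes.items() if n.namespace == scope}
    return frozenset((d, a) for d, a in pairs if d in members and a in members)


def edge_problem_sets(graph: OntologyGraph, policy: ScopingPolicy,
                      edge: RelationEdge,
                      amap: AncestorMap | None = None,
                      dmap: AncestorMap | None = None) -> EdgeProblemSets:
    """Problem sets for one subject-broader (has_part-style) edge.

    Ancestor and descendant closures are taken over the corrected scoping
    graph of *policy* (pass a no_hp policy for sensitivity analyses).  With
    whole ``w`` = edge subject and part ``p`` = edge object:

    * PA = (anc(p) ∪ {p}) − (anc(w) ∪ {w})
    * PD = (desc(w) ∪ {w}) − (desc(p) ∪ {p})
    """
    if edge not in graph._edge_set:
        raise KeyError(f"edge {edge} not in graph")
    if edge.relation not in policy.subject_is_broader:
        raise ValueError(
            f"{edge.relation!r} edges have no stored-direction scope problem")
    amap = amap if amap is not None else build_ancestor_map(graph, policy)
    dmap = dmap if dmap is not None else build_descendant_map(graph, policy)
    whole, part = edge.subject, edge.object
    pa = (set(amap.get(part)) | {part}) - (set(amap.get(whole)) | {whole})
    pd_ = (set(dmap.get(whole)) | {whole}) - (set(dmap.get(part)) | {part})
    return EdgeProblemSets(edge, frozenset(pa), frozenset(pd_))


def edge_false_pairs(eps: EdgeProblemSets) -> MappingPairSet:
    """Cartesian product PD x PA, self-pairs removed."""
    pairs = frozenset((d, a)
                      for d in eps.problematic_descendants
                      for a in eps.problematic_ancestors if d != a)
    return MappingPairSet(pairs, f"pM_F,e[{eps.edge.subject}->{eps.edge.object}]")


def estimated_false_mappings(graph: OntologyGraph, policy: ScopingPolicy,
                             relation: str = "has_part",
                             scope: str | None = None) -> MappingPairSet:
    """Union over all edges of *relation* of their per-edge false pairs.

    ``scope`` restricts the *pairs* (both endpoints must carry the
    namespace); edges are always enumerated graph-wide so that paths
    through other namespaces still contribute in-scope pairs.
    """
    amap = build_ancestor_map(graph, policy)
    dmap = build_descendant_map(graph, policy)
    union: set[Pair] = set()
    for edge in graph.edges_with_relation(relation):
        eps = edge_problem_sets(graph, policy, edge, amap, dmap)
        union |= edge_false_pairs(eps).pairs
    return MappingPairSet(_scope_filter(graph, frozenset(union), scope),
                          f"epM_F[{relation},{scope or 'all'}]")


def true_mappings(graph: OntologyGraph, policy: ScopingPolicy,
                  scope: str | None = None) -> MappingPairSet:
    """All ordered (descendant, ancestor) pairs under the policy (M_T)."""
    amap = build_ancestor_map(graph, policy)
    return MappingPairSet(_scope_filter(graph, frozenset(amap.pairs()), scope),
                          f"M_T[{policy.label},{scope or 'all'}]")


def audit_relation(graph: OntologyGraph, relation: str = "has_part",
                   scope: str | None = None,
                   policy: ScopingPolicy | None = None) -> AuditReport:
    """Tally false-mapping potential and information loss for one relation.

    ``policy`` defaults to the corrected scoping policy; the comparison
    policy drops *relation* from the scoping set to measure what the
    traditional traversal loses.
    """
    policy = policy or ScopingPolicy.gocats()
    epmf = estimated_false_mappings(graph, policy, relation, scope)
    mt = true_mappings(graph, policy, scope)
    without = policy.with_relations(policy.scoping_relations - {relation})
    mt_without = true_mappings(graph, without, scope)
    inter = len(mt.pairs & epmf.pairs)
    return AuditReport(
        scope=scope or "all",
        relation=relation,
        estimated_false=len(epmf),
        true_mappings=len(mt),
        intersection=inter,
        net_false=len(epmf) - inter,
        true_without_relation=len(mt_without),
        lost=len(mt) - len(mt_without),
    )


def naive_mapping_pairs(graph: OntologyGraph,
                        scope: str | None = None) -> MappingPairSet:
    """Pairs a label-blind mapper would emit.

    Every stored relationship line is followed in its subject->object
    direction regardless of label, so has_part and regulates edges are
    traversed as if they were is_a.  Cycles are tolerated (reachability is
    computed on the condensation), and self-mappings are ignored.
    """
    dg = nx.DiGraph()
    for tid, node in graph.nodes.items():
        if not node.obsolete:
            dg.add_node(tid)
    for edge in graph.edges:
        if edge.subject in dg and edge.object in dg:
            dg.add_edge(edge.subject, edge.object)
    cond = nx.condensation(dg)
    reach: dict[int, set[int]] = {}
    for comp in reversed(list(nx.topological_sort(cond))):
        acc: set[int] = set()
        for succ in cond.successors(comp):
            acc.add(succ)
            acc.update(reach[succ])
        reach[comp] = acc
    members = cond.nodes(data="members")
    pairs: set[Pair] = set()
    for comp, nodes in members:
        targets: set[str] = set()
        for rcomp in reach[comp] | {comp}:
            targets.update(members[rcomp])
        for d in nodes:
            for a in targets:
                if d != a:
                    pairs.add((d, a))
    return MappingPairSet(_scope_filter(graph, frozenset(pairs), scope),
                          f"M_pair,naive[{scope or 'all'}]")


def naive_error_report(graph: OntologyGraph,
                       policy: ScopingPolicy | None = None) -> NaiveErrorReport:
    """Compare naive label-blind pairs against corrected scoping pairs.

    For each scope (all plus the three sub-ontologies) the naive pair set,
    restricted to endpoints within scope, is intersected with the *graph-
    wide* corrected pair set: ``correct`` is the intersection, the
    remainder is potentially false, and the primary error fraction divides
    by the naive pair count in scope.  The alternative ratio that divides
    by the corrected scoping pair count is reported alongside.
    """
    policy = policy or ScopingPolicy.gocats()
    gocats_all = true_mappings(graph, policy, scope=None)
    report = NaiveErrorReport()
    for scope in (None, *NAMESPACES):
        naive = naive_mapping_pairs(graph, scope)
        gocats_scope = true_mappings(graph, policy, scope)
        correct = naive.pairs & gocats_all.pairs
        false = naive.pairs - gocats_all.pairs
        n_naive = len(naive.pairs)
        report.rows[scope or "all"] = {
            "naive_pairs": n_naive,
            "scoping_pairs": len(gocats_scope),
            "potentially_false": len(false),
            "correct": len(correct),
            "error_fraction": (len(false) / n_naive) if n_naive else 0.0,
            "error_vs_scoping": (len(false) / len(gocats_scope)
                                 if len(gocats_scope) else 0.0),
        }
    return report
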
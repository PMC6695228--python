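"""Scoping policies and transitive ancestor computation.

A *scoping relation* orders two terms by generality.  In go-core, ``is_a``
and ``part_of`` edges point from the narrower term (the stanza subject)
toward the broader term, while ``has_part`` points the other way: the
subject is the whole and the object the part.  Traversing ``has_part`` in
its stored direction therefore walks *down* in scope, which is what breaks
naive mappers.  The corrected policy reinterprets each ``has_part`` edge as
``part_of_some`` — the part is treated as (possibly) part of the whole —
so that every traversed edge points from narrower to broader and the
resulting scoped subgraph stays acyclic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import networkx as nx

from .ontology import CORRESPONDENCE_CLASS, OntologyGraph

DEFAULT_SCOPING = frozenset({"is_a", "part_of", "has_part"})

#: per-label direction rule: which end of a stored edge is the broader term
SUBJECT_IS_BROADER = frozenset({"has_part"})


class CycleError(ValueError):
    """Scoped subgraph contains a directed cycle; names one cycle."""

    def __init__(self, cycle: list[str]):
        super().__init__("cycle among scoping edges: " + " -> ".join(cycle))
        self.cycle = cycle


@dataclass(frozen=True)
class ScopingPolicy:
    """Which relation labels count as scoping, and in which direction.

    With the defaults, the edge subject is the narrower term for ``is_a``
    and ``part_of``, and the broader term for ``has_part``.  When
    ``reinterpret_has_part`` is true (the corrected behaviour), subject-
    broader edges are traversed object->subject, i.e. as ``part_of_some``;
    when false they are traversed in the stored, scope-incongruent
    direction — useful only for emulating broken traversals.
    """

    scoping_relations: frozenset[str] = DEFAULT_SCOPING
    subject_is_broader: frozenset[str] = SUBJECT_IS_BROADER
    reinterpret_has_part: bool = True
    label: str = "gocats"

    @classmethod
    def gocats(cls) -> "ScopingPolicy":
        """Default corrected policy: {is_a, part_of, has_part-reinterpreted}."""
        return cls()

    @classmethod
    def no_hp(cls) -> "ScopingPolicy":
        """Traditional policy: drop has_part entirely."""
        return cls(scoping_relations=frozenset({"is_a", "part_of"}),
                   label="no_hp")

    @classmethod
    def go_basic_scoping(cls) -> "ScopingPolicy":
        """Restrict to the relations go-basic retains ({is_a, part_of})."""
        return cls(scoping_relations=frozenset({"is_a", "part_of"}),
                   label="go-basic-scoping")

    @classmethod
    def named(cls, name: str) -> "ScopingPolicy":
        try:
            return {"gocats": cls.gocats, "no_hp": cls.no_hp,
                    "go-basic-scoping": cls.go_basic_scoping}[name]()
        except KeyError:
            raise ValueError(f"unknown policy {name!r}") from None

    def with_relations(self, labels: Iterable[str]) -> "ScopingPolicy":
        return replace(self, scoping_relations=frozenset(labels), label="custom")

    def correspondence_class(self, relation: str) -> str:
        return CORRESPONDENCE_CLASS.get(relation, "other")


def scoping_digraph(graph: OntologyGraph, policy: ScopingPolicy,
                    namespace: str | None = None) -> nx.DiGraph:
    """Directed graph with every scoping edge oriented narrower -> broader.

    Cross-namespace scoping edges are traversed by default; pass
    ``namespace`` to keep only edges internal to one sub-ontology.
    """
    dg = nx.DiGraph()
    for tid, node in graph.nodes.items():
        if node.obsolete:
            continue
        if namespace is not None and node.namespace != namespace:
            continue
        dg.add_node(tid)
    for edge in graph.edges:
        if edge.relation not in policy.scoping_relations:
            continue
        if edge.subject not in dg or edge.object not in dg:
            continue
        if edge.relation in policy.subject_is_broader:
            if policy.reinterpret_has_part:
                narrower, broader = edge.object, edge.subject
            else:  # stored (incongruent) direction, for error emulation
                narrower, broader = edge.subject, edge.object
        else:
            narrower, broader = edge.subject, edge.object
        dg.add_edge(narrower, broader)
    return dg


def scoped_parents(graph: OntologyGraph, policy: ScopingPolicy,
                   term: str) -> set[str]:
    """Broader-scope neighbours of *term* one scoping edge away."""
    tid = graph.resolve(term)
    if tid is None:
        raise KeyError(f"unknown term {term!r}")
    parents: set[str] = set()
    for e in graph.out_edges(tid):
        if e.relation not in policy.scoping_relations:
            continue
        if e.relation in policy.subject_is_broader:
            if not policy.reinterpret_has_part:
                parents.add(e.object)
        else:
            parents.add(e.object)
    if policy.reinterpret_has_part:
        for e in graph.in_edges(tid):
            if (e.relation in policy.scoping_relations
                    and e.relation in policy.subject_is_broader):
                parents.add(e.subject)
    parents.discard(tid)
    return parents


@dataclass
class AncestorMap:
    """Transitively closed term -> ancestor-set table under one policy."""

    mapping: dict[str, frozenset[str]]
    policy: ScopingPolicy
    namespace: str | None = None

    def __getitem__(self, term: str) -> frozenset[str]:
        return self.mapping[term]

    def __contains__(self, term: str) -> bool:
        return term in self.mapping

    def get(self, term: str, default=frozenset()):
        return self.mapping.get(term, default)

    def items(self):
        return self.mapping.items()

    def pairs(self) -> set[tuple[str, str]]:
        """All ordered (descendant, ancestor) pairs; self-pairs excluded."""
        return {(t, a) for t, anc in self.mapping.items() for a in anc if a != t}


def _closure(dg: nx.DiGraph) -> dict[str, frozenset[str]]:
    """Reachability sets via reverse topological accumulation."""
    try:
        order = list(nx.topological_sort(dg))
    except nx.NetworkXUnfeasible:
        cycle = [u for u, _ in nx.find_cycle(dg)]
        raise CycleError(cycle + [cycle[0]]) from None
    reach: dict[str, frozenset[str]] = {}
    for node in reversed(order):
        acc: set[str] = set()
        for succ in dg.successors(node):
            acc.add(succ)
            acc.update(reach[succ])
        acc.discard(node)
        reach[node] = frozenset(acc)
    return reach


def build_ancestor_map(graph: OntologyGraph, policy: ScopingPolicy,
                       namespace: str | None = None) -> AncestorMap:
    """One transitively-closed ancestor set per non-obsolete term.

    The {is_a, part_of} policy yields the traditional ("no_hp") map; the
    default policy yields the corrected map with has_part reinterpreted.
    Raises :class:`CycleError` when the scoped subgraph is cyclic.
    """
    dg = scoping_digraph(graph, policy, namespace)
    return AncestorMap(_closure(dg), policy, namespace)


def build_descendant_map(graph: OntologyGraph, policy: ScopingPolicy,
                         namespace: str | None = None) -> AncestorMap:
    """Term -> set of narrower terms (reverse of the ancestor map)."""
    dg = scoping_digraph(graph, policy, namespace).reverse(copy=False)
    return AncestorMap(_closure(dg), policy, namespace)


def ancestors(graph: OntologyGraph, policy: ScopingPolicy, term: str) -> set[str]:
    """Transitive closure of :func:`scoped_parents`; excludes *term*."""
    tid = graph.resolve(term)
    if tid is None:
        raise KeyError(f"unknown term {term!r}")
    dg = scoping_digraph(graph, policy)
    if not nx.is_directed_acyclic_graph(dg):
        cycle = [u for u, _ in nx.find_cycle(dg)]
        raise CycleError(cycle + [cycle[0]])
    return set(nx.descendants(dg, tid))


def descendants(graph: OntologyGraph, policy: ScopingPolicy, term: str) -> set[str]:
    """Terms narrower in scope than *term* under the policy."""
    tid = graph.resolve(term)
    if tid is None:
        raise KeyError(f"unknown term {term!r}")
    dg = scoping_digraph(graph, policy)
    return set(nx.ancestors(dg, tid))


def check_acyclic(graph: OntologyGraph,
                  policy: ScopingPolicy) -> list[str] | None:
    """Return None when the scoped subgraph is acyclic, else one cycle."""
    dg = scoping_digraph(graph, policy)
    try:
        cycle = nx.find_cycle(dg)
    except nx.NetworkXNoCycle:
        return None
    nodes = [u for u, _ in cycle]
    return nodes + [nodes[0]]


def category_map(graph: OntologyGraph, policy: ScopingPolicy,
                 roots: Iterable[str]) -> dict[str, frozenset[str]]:
    """Map every term to the category roots it falls under.

    A term belongs to root ``r`` iff ``r`` is the term itself or one of its
    scoped ancestors; a root thus anchors its own category.  Terms under no
    root map to the empty set.
    """
    root_set = set()
    for r in roots:
        rid = graph.resolve(r)
        if rid is None:
            raise KeyError(f"unknown category root {r!r}")
        root_set.add(rid)
    amap = build_ancestor_map(graph, policy)
    return {t: frozenset(root_set & (set(anc) | {t}))
            for t, anc in amap.items()}


def restricted_map(amap: AncestorMap,
                   keep: Mapping[str, frozenset[str]] | set[str]) -> AncestorMap:
    """Filter a map to terms (and ancestors) in ``keep``; utility for audits."""
    keep_set = set(keep)
    return AncestorMap(
        {t: frozenset(a for a in anc if a in keep_set)
         for t, anc in amap.items() if t in keep_set},
        amap.policy, amap.namespace)
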
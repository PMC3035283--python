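"""Ancestor and offspring set computation on an :class:`OntologyDAG`.

Two implementations are provided deliberately:

* :func:`ancestor_set` / :func:`offspring_set` — per-term iterative
  depth-first traversal with a visited set (the reference implementation;
  counts unique nodes, never paths).
* :func:`reachability_table` — one memoized pass over a topological order,
  linear in nodes + edges times average set size; used for whole-ontology
  runs and checked against the per-term form in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UnknownTermError
from .ontology import OntologyDAG


@dataclass(frozen=True)
class ReachabilityResult:
    """Ancestor and offspring sets for one term.

    Both sets are strict: the term itself belongs to neither. Acyclicity
    guarantees the two sets are disjoint.
    """

    term_id: str
    ancestors: frozenset[str]
    offspring: frozenset[str]

    @property
    def n_ancestors(self) -> int:
        return len(self.ancestors)

    @property
    def n_offspring(self) -> int:
        return len(self.offspring)


def _resolve_active(dag: OntologyDAG, term_id: str) -> str:
    resolved = dag.resolve(term_id)
    if resolved is None:
        raise UnknownTermError(f"unknown term {term_id!r}")
    if dag.terms[resolved].is_obsolete:
        raise UnknownTermError(f"term {term_id!r} is obsolete")
    return resolved


def ancestor_set(dag: OntologyDAG, term_id: str) -> frozenset[str]:
    """All terms strictly above ``term_id``, up to and including the root.

    Depth-first walk over child->parent edges; a visited set deduplicates
    terms reachable along multiple paths.
    """
    start = _resolve_active(dag, term_id)
    visited: set[str] = set()
    stack = list(dag.terms[start].parents)
    while stack:
        node = stack.pop()
        if node in visited:
            continue
        visited.add(node)
        stack.extend(dag.terms[node].parents)
    return frozenset(visited)


def offspring_set(dag: OntologyDAG, term_id: str) -> frozenset[str]:
    """All terms strictly below ``term_id`` (neighbors are children only)."""
    start = _resolve_active(dag, term_id)
    visited: set[str] = set()
    stack = list(dag.children(start))
    while stack:
        node = stack.pop()
        if node in visited:
            continue
        visited.add(node)
        stack.extend(dag.children(node))
    return frozenset(visited)


def reachability_table(dag: OntologyDAG) -> dict[str, ReachabilityResult]:
    """Ancestor/offspring sets for every non-obsolete term in one pass.

    Ancestors accumulate root-down (a term's ancestors are the union of each
    parent plus that parent's ancestors); offspring accumulate leaf-up over
    the reversed order. Results agree with the per-term traversals.
    """
    order = dag.topological_order()
    ancestors: dict[str, frozenset[str]] = {}
    for term_id in order:
        acc: set[str] = set()
        for parent in dag.terms[term_id].parents:
            acc.add(parent)
            acc.update(ancestors[parent])
        ancestors[term_id] = frozenset(acc)
    offspring: dict[str, frozenset[str]] = {}
    for term_id in reversed(order):
        acc = set()
        for child in dag.children(term_id):
            if dag.terms[child].is_obsolete:
                continue
            acc.add(child)
            acc.update(offspring[child])
        offspring[term_id] = frozenset(acc)
    return {
        term_id: ReachabilityResult(
            term_id=term_id,
            ancestors=ancestors[term_id],
            offspring=offspring[term_id],
        )
        for term_id in order
    }
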
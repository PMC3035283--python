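"""Ontology model and OBO 1.2 flat-file I/O.

The central object is :class:`OntologyDAG`: a rooted, acyclic, child->parent
directed graph of :class:`Term` records. Construction always validates
acyclicity, edge integrity and single-rootedness; a DAG that loads is safe
for every downstream traversal.

Only ``is_a`` edges are followed by default. ``part_of`` relationships can be
opted in via ``edge_types`` — which relations define "parent" changes every
ancestor/offspring count, so the choice is explicit rather than implicit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Sequence

import networkx as nx

from .errors import (
    AmbiguousNamespaceError,
    CyclicOntologyError,
    DanglingEdgeError,
    RootResolutionError,
    UnknownTermError,
)

#: Namespaces recognised in OBO files; anything else maps to "other".
KNOWN_NAMESPACES = frozenset(
    {"molecular_function", "biological_process", "cellular_component"}
)

#: Relationship types that may define parenthood.
SUPPORTED_EDGE_TYPES = frozenset({"is_a", "part_of"})

DEFAULT_EDGE_TYPES = frozenset({"is_a"})


@dataclass(frozen=True)
class Term:
    """One ontology node.

    ``parents`` holds the term_ids one direct edge toward the root. Obsolete
    terms never have parents and are excluded from every metric.
    """

    term_id: str
    name: str = ""
    namespace: str = "other"
    is_obsolete: bool = False
    parents: frozenset[str] = field(default_factory=frozenset)


class OntologyDAG:
    """Validated rooted DAG of terms with child->parent edges.

    Parameters
    ----------
    terms
        Mapping term_id -> :class:`Term`. Parent links live on the terms.
    root_id
        Identifier of the namespace root (zero parents).
    alt_ids
        Mapping of alternate/merged identifiers to their primary term_id.

    Raises
    ------
    DanglingEdgeError
        If any parent link points at an undefined term.
    CyclicOntologyError
        If the edge set contains a directed cycle.
    RootResolutionError
        If ``root_id`` is inconsistent with the parentless terms, or a
        non-obsolete term cannot reach the root.
    """

    def __init__(
        self,
        terms: Mapping[str, Term],
        root_id: str,
        alt_ids: Mapping[str, str] | None = None,
    ) -> None:
        self.terms: dict[str, Term] = dict(terms)
        self.root_id = root_id
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        self._children: dict[str, set[str]] = {t: set() for t in self.terms}
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        if self.root_id not in self.terms:
            raise RootResolutionError(
                f"declared root {self.root_id!r} is not a term in the ontology"
            )
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parents:
                if parent not in self.terms:
                    raise DanglingEdgeError(
                        f"term {term.term_id!r} references undefined parent {parent!r}"
                    )
                g.add_edge(term.term_id, parent)
                self._children[parent].add(term.term_id)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            member = cycle[0][0]
            raise CyclicOntologyError(
                f"ontology contains a cycle through term {member!r}"
            )
        root_term = self.terms[self.root_id]
        if root_term.parents:
            raise RootResolutionError(
                f"root {self.root_id!r} has parents {sorted(root_term.parents)}"
            )
        orphans = [
            t.term_id
            for t in self.terms.values()
            if not t.parents and not t.is_obsolete and t.term_id != self.root_id
        ]
        if orphans:
            raise RootResolutionError(
                "multiple root candidates after filtering: "
                + ", ".join(sorted([self.root_id, *orphans]))
            )
        self._graph = g

    # -- queries --------------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str | None:
        """Map a possibly-alternate identifier to its primary term_id.

        Returns ``None`` when the identifier is unknown entirely.
        """
        if term_id in self.terms:
            return term_id
        return self.alt_ids.get(term_id)

    def term(self, term_id: str) -> Term:
        resolved = self.resolve(term_id)
        if resolved is None:
            raise UnknownTermError(f"unknown term {term_id!r}")
        return self.terms[resolved]

    def parents(self, term_id: str) -> frozenset[str]:
        return self.term(term_id).parents

    def children(self, term_id: str) -> frozenset[str]:
        resolved = self.resolve(term_id)
        if resolved is None:
            raise UnknownTermError(f"unknown term {term_id!r}")
        return frozenset(self._children[resolved])

    def active_terms(self) -> Iterator[Term]:
        """Iterate over non-obsolete terms in insertion order."""
        return (t for t in self.terms.values() if not t.is_obsolete)

    def topological_order(self) -> list[str]:
        """Active term ids ordered root-first (parents before children)."""
        order = [
            t
            for t in nx.topological_sort(self._graph.reverse(copy=False))
            if not self.terms[t].is_obsolete
        ]
        return order

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyDAG):
            return NotImplemented
        return (
            self.terms == other.terms
            and self.root_id == other.root_id
            and self.alt_ids == other.alt_ids
        )


# ---------------------------------------------------------------------------
# OBO parsing


def _coerce_edge_types(edge_types: Iterable[str] | None) -> frozenset[str]:
    types = frozenset(edge_types) if edge_types is not None else DEFAULT_EDGE_TYPES
    unknown = types - SUPPORTED_EDGE_TYPES
    if unknown:
        raise ValueError(
            f"unsupported edge types {sorted(unknown)}; "
            f"supported: {sorted(SUPPORTED_EDGE_TYPES)}"
        )
    return types


def _strip_comment(line: str) -> str:
    # OBO trailing comments start with " ! "
    idx = line.find("!")
    return (line[:idx] if idx >= 0 else line).strip()


def parse_obo(
    stream: IO[str] | str,
    namespace_filter: str | None = None,
    edge_types: Iterable[str] | None = None,
) -> OntologyDAG:
    """Parse an OBO 1.2 flat file into a validated :class:`OntologyDAG`.

    Parameters
    ----------
    stream
        Text stream or string containing OBO stanzas.
    namespace_filter
        Restrict to one namespace. Required when the file contains terms from
        more than one namespace.
    edge_types
        Relation names that define parenthood; subset of ``{"is_a",
        "part_of"}``; default ``{"is_a"}``.

    Returns
    -------
    OntologyDAG
        Obsolete terms are retained but flagged; ``alt_id`` entries resolve to
        their primary term via :meth:`OntologyDAG.resolve`.

    Raises
    ------
    CyclicOntologyError, DanglingEdgeError, RootResolutionError
        On structural violations (see :class:`OntologyDAG`).
    AmbiguousNamespaceError
        If several namespaces are present and no filter was given.
    """
    types = _coerce_edge_types(edge_types)
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    stanzas: list[dict[str, list[str]]] = []
    current: dict[str, list[str]] | None = None
    in_term = False
    for raw in stream:
        line = _strip_comment(raw)
        if not line:
            continue
        if line.startswith("["):
            in_term = line == "[Term]"
            current = {} if in_term else None
            if in_term:
                stanzas.append(current)  # type: ignore[arg-type]
            continue
        if current is None:
            continue
        key, _, value = line.partition(":")
        current.setdefault(key.strip(), []).append(value.strip())

    terms: dict[str, Term] = {}
    alt_ids: dict[str, str] = {}
    namespaces_seen: set[str] = set()
    for stanza in stanzas:
        if "id" not in stanza:
            continue
        term_id = stanza["id"][0]
        name = stanza.get("name", [""])[0]
        namespace = stanza.get("namespace", ["other"])[0]
        if namespace not in KNOWN_NAMESPACES:
            namespace = "other"
        obsolete = stanza.get("is_obsolete", ["false"])[0].lower() == "true"
        parents: set[str] = set()
        if not obsolete:
            if "is_a" in types:
                parents.update(stanza.get("is_a", []))
            if "part_of" in types:
                for rel in stanza.get("relationship", []):
                    rel_type, _, target = rel.partition(" ")
                    if rel_type == "part_of" and target:
                        parents.add(target.strip())
        if not obsolete:
            namespaces_seen.add(namespace)
        if namespace_filter is not None and namespace != namespace_filter:
            continue
        terms[term_id] = Term(
            term_id=term_id,
            name=name,
            namespace=namespace,
            is_obsolete=obsolete,
            parents=frozenset(parents),
        )
        for alt in stanza.get("alt_id", []):
            alt_ids[alt] = term_id

    if namespace_filter is None and len(namespaces_seen) > 1:
        raise AmbiguousNamespaceError(
            "file contains multiple namespaces "
            f"({', '.join(sorted(namespaces_seen))}); pass namespace_filter"
        )
    if not terms:
        raise RootResolutionError("no terms after parsing/filtering")

    roots = [
        t.term_id for t in terms.values() if not t.parents and not t.is_obsolete
    ]
    if len(roots) != 1:
        raise RootResolutionError(
            f"expected exactly one root, found {len(roots)}: {sorted(roots)}"
        )
    return OntologyDAG(terms, root_id=roots[0], alt_ids=alt_ids)


def build_dag(
    edges: Sequence[tuple[str, str]],
    root_id: str,
    namespace: str = "other",
) -> OntologyDAG:
    """Construct a DAG from ``(child_id, parent_id)`` pairs.

    Terms are declared implicitly by appearing in an edge (or as the root).
    Validation contract matches :func:`parse_obo`.
    """
    if not root_id:
        raise ValueError("root_id must be a nonempty string")
    ids: dict[str, set[str]] = {root_id: set()}
    for child, parent in edges:
        if not child or not parent:
            raise ValueError(f"edge ids must be nonempty, got ({child!r}, {parent!r})")
        ids.setdefault(child, set()).add(parent)
        ids.setdefault(parent, set())
    terms = {
        term_id: Term(
            term_id=term_id,
            name=term_id,
            namespace=namespace,
            parents=frozenset(parents),
        )
        for term_id, parents in ids.items()
    }
    return OntologyDAG(terms, root_id=root_id)


def serialize_obo(dag: OntologyDAG) -> str:
    """Render a DAG back to OBO 1.2 text.

    Round-trips term ids, names, namespaces, obsolete flags and is_a edges
    through :func:`parse_obo`. All parent links are emitted as ``is_a``.
    """
    chunks = ["format-version: 1.2\n"]
    for term in dag.terms.values():
        lines = [f"[Term]", f"id: {term.term_id}", f"name: {term.name}"]
        if term.namespace != "other":
            lines.append(f"namespace: {term.namespace}")
        for alt, primary in sorted(dag.alt_ids.items()):
            if primary == term.term_id:
                lines.append(f"alt_id: {alt}")
        for parent in sorted(term.parents):
            lines.append(f"is_a: {parent}")
        if term.is_obsolete:
            lines.append("is_obsolete: true")
        chunks.append("\n".join(lines) + "\n")
    return "\n".join(chunks)
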
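"""Term function-specificity metrics.

Four per-term measures:

* ``n_ancestors`` — unique terms above, up to and including the root.
* ``offsp_n`` — normalized offspring, ``ln((M + 1) / (k + 1))`` where ``k``
  is the term's offspring count and ``M`` the maximum (the root's offspring
  count). Zero at the root, maximal (``ln(M + 1)``) for leaves; reported in
  nats.
* ``go_prop`` — 1 minus offspring over reachable terms
  (offspring + ancestors); 0 for the root, 1 for leaves, undefined for an
  isolated term with neither.
* ``ic`` — information content, ``-log2(p(t))`` in bits, where ``p(t)`` is
  the fraction of annotation units assigned to the term or any of its
  offspring. Undefined when the term's closure carries no annotation.

Undefined values are represented as ``None``, never as 0 or infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

from .annotations import AnnotationSet
from .errors import BoundsError, UnknownTermError
from .ontology import OntologyDAG
from .traversal import offspring_set, reachability_table


@dataclass(frozen=True)
class SpecificityRecord:
    """Per-term metric bundle; ``None`` marks an undefined value."""

    term_id: str
    n_ancestors: int
    n_offspring: int
    offsp_n: float
    go_prop: float | None
    p: float | None
    ic: float | None


@dataclass(frozen=True)
class MetricConfig:
    """Configuration for a batch metric run.

    ``max_offspring`` is M in the offspring normalization; when ``None`` it
    is derived as the root's offspring count. The IC log base is fixed at 2
    (bits) so printed values stay comparable. ``count_mode`` selects between
    deduplicated closure counting (default; keeps p <= 1 and monotone) and
    the literal sum of per-term counts, which can double-count units
    annotated at several depths.
    """

    max_offspring: int | None = None
    count_mode: Literal["unique", "sum"] = "unique"


def offsp_n(k: int, M: int) -> float:
    """Normalized offspring measure, in nats.

    Strictly decreasing in ``k``; 0 at ``k == M`` and ``ln(M + 1)`` at
    ``k == 0``.
    """
    if M < 1:
        raise BoundsError(f"max offspring M must be >= 1, got {M}")
    if k < 0 or k > M:
        raise BoundsError(f"offspring count k={k} outside [0, {M}]")
    return math.log((M + 1) / (k + 1))


def go_proportion(n_offspring: int, n_ancestors: int) -> float | None:
    """1 minus offspring / (offspring + ancestors); ``None`` on 0/0."""
    if n_offspring < 0 or n_ancestors < 0:
        raise BoundsError("counts must be nonnegative")
    total = n_offspring + n_ancestors
    if total == 0:
        return None
    return 1.0 - n_offspring / total


def term_probability(dag: OntologyDAG, ann: AnnotationSet, term_id: str) -> float:
    """Probability of a term occurring in the annotation data set.

    Counts the distinct units annotated to the term or to any of its
    offspring, divided by the total number of units. A unit annotated to
    several terms inside that closure is counted once.
    """
    resolved = dag.resolve(term_id)
    if resolved is None:
        raise UnknownTermError(f"unknown term {term_id!r}")
    closure = set(offspring_set(dag, resolved))
    closure.add(resolved)
    hits = sum(1 for terms in ann.by_gene.values() if terms & closure)
    return hits / ann.n_genes


def information_content(p: float) -> float | None:
    """IC in bits: ``-log2(p)``; 0 at p = 1, ``None`` (undefined) at p = 0."""
    if p < 0 or p > 1:
        raise BoundsError(f"probability {p} outside [0, 1]")
    if p == 0:
        return None
    if p == 1:
        return 0.0  # avoid -0.0
    return -math.log2(p)


def compute_all(
    dag: OntologyDAG,
    ann: AnnotationSet | None = None,
    cfg: MetricConfig | None = None,
) -> dict[str, SpecificityRecord]:
    """All metrics for every non-obsolete term.

    Annotation counts are propagated bottom-up over a topological order in a
    single pass: each term's closure unit set is the union of its direct
    units and its children's closure sets. Without ``ann``, the ``p``/``ic``
    fields are ``None`` and only the structural metrics are filled in.
    """
    cfg = cfg or MetricConfig()
    table = reachability_table(dag)
    root_offspring = table[dag.root_id].n_offspring
    M = cfg.max_offspring if cfg.max_offspring is not None else root_offspring
    if M < max(1, root_offspring):
        raise BoundsError(
            f"max_offspring {M} is smaller than the root's offspring count "
            f"{root_offspring}"
        )

    closure_units: dict[str, frozenset[str]] = {}
    direct: dict[str, set[str]] = {t: set() for t in table}
    if ann is not None:
        for gene, terms in ann.by_gene.items():
            for term in terms:
                if term in direct:
                    direct[term].add(gene)
        for term_id in reversed(dag.topological_order()):
            units = set(direct[term_id])
            for child in dag.children(term_id):
                if child in closure_units:
                    units.update(closure_units[child])
            closure_units[term_id] = frozenset(units)

    records: dict[str, SpecificityRecord] = {}
    for term_id, reach in table.items():
        p: float | None = None
        ic: float | None = None
        if ann is not None:
            if cfg.count_mode == "unique":
                count = len(closure_units[term_id])
            else:
                # literal "add the counts" reading: sums per-term direct
                # counts across the closure, so overlapping units can push
                # p past 1 (capped for IC)
                count = len(direct[term_id]) + sum(
                    len(direct[t]) for t in reach.offspring
                )
            p = count / ann.n_genes
            ic = information_content(min(p, 1.0)) if p > 0 else None
        records[term_id] = SpecificityRecord(
            term_id=term_id,
            n_ancestors=reach.n_ancestors,
            n_offspring=reach.n_offspring,
            offsp_n=offsp_n(reach.n_offspring, M),
            go_prop=go_proportion(reach.n_offspring, reach.n_ancestors),
            p=p,
            ic=ic,
        )
    return records
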
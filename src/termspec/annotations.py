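"""Readers for gene/protein -> ontology-term annotation tables.

Two dialects are supported:

* NCBI ``gene2go`` TSV (``#tax_id GeneID GO_ID Evidence Qualifier GO_term
  PubMed Category``), plus the minimal two-column ``GeneID``/``GOTerm``
  form;
* GAF 2.x (17 tab-separated columns, ``!`` comment lines).

Both return the same :class:`AnnotationSet`: a deduplicated mapping from an
opaque annotation unit (gene or protein identifier — the math only needs
distinct units) to its set of directly annotated term ids.

Rows with a NOT qualifier are dropped: a NOT annotation is evidence of
absence and would corrupt term probabilities. Annotations to unknown or
obsolete terms are dropped and counted, never silently discarded.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Mapping

from .errors import EmptyAnnotationError, SchemaError
from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

#: gene2go Category column values -> OBO namespace names.
_CATEGORY_TO_NAMESPACE = {
    "function": "molecular_function",
    "process": "biological_process",
    "component": "cellular_component",
}

#: GAF aspect column values -> OBO namespace names.
_ASPECT_TO_NAMESPACE = {
    "F": "molecular_function",
    "P": "biological_process",
    "C": "cellular_component",
}


@dataclass(frozen=True)
class AnnotationSet:
    """Deduplicated direct annotations, unit -> set of term ids.

    ``n_genes`` is the number of distinct annotation units that survived
    filtering; it is the denominator for term probabilities, so the root's
    probability is 1 by construction when all units annotate within the
    namespace.
    """

    by_gene: Mapping[str, frozenset[str]]
    namespace: str = "other"
    n_dropped_terms: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.by_gene)

    def __post_init__(self) -> None:
        for gene, terms in self.by_gene.items():
            if not terms:
                raise ValueError(f"annotation unit {gene!r} has no terms")


def _open_maybe_gz(source: IO[str] | str | Path) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return path.open("rt", encoding="utf-8")


def _is_not_qualified(qualifier: str) -> bool:
    parts = {p.strip().upper() for p in qualifier.split("|")}
    return "NOT" in parts


def _collect(
    rows: Iterator[tuple[str, str]],
    dag: OntologyDAG,
    source_label: str,
) -> AnnotationSet:
    by_gene: dict[str, set[str]] = {}
    dropped = 0
    for gene_id, term_id in rows:
        resolved = dag.resolve(term_id)
        if resolved is None or dag.terms[resolved].is_obsolete:
            dropped += 1
            continue
        by_gene.setdefault(gene_id, set()).add(resolved)
    if dropped:
        logger.warning(
            "%s: dropped %d annotation(s) to unknown or obsolete terms",
            source_label,
            dropped,
        )
    if not by_gene:
        raise EmptyAnnotationError(
            f"{source_label}: no annotations survived parsing and filtering"
        )
    namespace = dag.terms[dag.root_id].namespace
    return AnnotationSet(
        by_gene={g: frozenset(t) for g, t in by_gene.items()},
        namespace=namespace,
        n_dropped_terms=dropped,
    )


def read_gene2go(
    source: IO[str] | str | Path,
    dag: OntologyDAG,
    taxon_filter: int | str | None = None,
) -> AnnotationSet:
    """Read a gene2go-dialect TSV into an :class:`AnnotationSet`.

    The header line names the columns. The full NCBI dialect is recognised
    by its ``GO_ID`` and ``Category`` columns (Category rows outside the
    DAG's namespace are filtered out); the minimal dialect needs only
    ``GeneID`` and ``GOTerm``.

    Parameters
    ----------
    source
        Path or text stream; ``.gz`` paths are decompressed.
    dag
        Companion ontology used to resolve alt_ids, drop unknown/obsolete
        terms and (for the minimal dialect) infer the namespace.
    taxon_filter
        Keep only rows whose ``#tax_id`` matches; ignored when the file has
        no taxon column.

    Raises
    ------
    SchemaError
        If no recognised gene/term column pair is present.
    EmptyAnnotationError
        If nothing survives filtering.
    """
    stream = _open_maybe_gz(source)
    header_line = stream.readline()
    if not header_line.strip():
        raise SchemaError("gene2go: empty input, expected a header line")
    columns = [c.strip() for c in header_line.lstrip("#").rstrip("\n").split("\t")]
    index = {name: i for i, name in enumerate(columns)}

    gene_col = index.get("GeneID")
    term_col = index.get("GO_ID", index.get("GOTerm"))
    if gene_col is None or term_col is None:
        raise SchemaError(
            "gene2go: need GeneID plus GO_ID or GOTerm columns; "
            f"found: {columns}"
        )
    tax_col = index.get("tax_id")
    qual_col = index.get("Qualifier")
    cat_col = index.get("Category")
    namespace = dag.terms[dag.root_id].namespace
    taxon = str(taxon_filter) if taxon_filter is not None else None

    def rows() -> Iterator[tuple[str, str]]:
        width = max(gene_col, term_col)
        for lineno, raw in enumerate(stream, start=2):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) <= width:
                raise SchemaError(
                    f"gene2go line {lineno}: expected at least {width + 1} "
                    f"columns, got {len(fields)}"
                )
            if taxon is not None and tax_col is not None and fields[tax_col] != taxon:
                continue
            if qual_col is not None and len(fields) > qual_col:
                if _is_not_qualified(fields[qual_col]):
                    continue
            if cat_col is not None and len(fields) > cat_col:
                row_ns = _CATEGORY_TO_NAMESPACE.get(fields[cat_col].lower())
                if row_ns is not None and namespace != "other" and row_ns != namespace:
                    continue
            yield fields[gene_col], fields[term_col]

    return _collect(rows(), dag, "gene2go")


def read_gaf(source: IO[str] | str | Path, dag: OntologyDAG) -> AnnotationSet:
    """Read a GAF 2.x file into an :class:`AnnotationSet`.

    DB_Object_ID (column 2) is the annotation unit; column 5 is the term.
    NOT-qualified rows are dropped and the aspect column filters rows to the
    DAG's namespace.
    """
    stream = _open_maybe_gz(source)
    namespace = dag.terms[dag.root_id].namespace

    def rows() -> Iterator[tuple[str, str]]:
        for lineno, raw in enumerate(stream, start=1):
            if not raw.strip() or raw.startswith("!"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 15:
                raise SchemaError(
                    f"GAF line {lineno}: expected >= 15 columns, got {len(fields)}"
                )
            if _is_not_qualified(fields[3]):
                continue
            row_ns = _ASPECT_TO_NAMESPACE.get(fields[8])
            if row_ns is not None and namespace != "other" and row_ns != namespace:
                continue
            yield fields[1], fields[4]

    return _collect(rows(), dag, "GAF")
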
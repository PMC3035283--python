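"""Deterministic test fixtures: a frozen toy ontology and a seeded
generator of GO-like random DAGs with annotation tables.

Everything here is reproducible from a seed alone, so the full test suite
runs without downloading any ontology release or annotation snapshot.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .annotations import AnnotationSet
from .errors import SpecError
from .ontology import OntologyDAG, Term, serialize_obo


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for :func:`generate`. Identical specs (seed included)
    produce byte-identical DAGs and annotation tables."""

    n_terms: int = 60
    max_parents_per_term: int = 3
    n_units: int = 200
    annotation_depth_bias: float = 1.0
    seed: int = 0


def figure1_fixture() -> tuple[OntologyDAG, AnnotationSet]:
    """The frozen toy ontology and its 11-unit annotation table.

    Topology (child -> parent)::

        GO:Term_1 (root)
        ├── GO:Term_2          7 direct units
        └── GO:Term_3          1 direct unit
            ├── GO:Term_4      2 direct units
            └── GO:Term_5      1 direct unit

    Eleven distinct units in total. GO:Term_3's closure covers 1 + 3 = 4
    units, so its probability is 4/11; the root covers all 11, so its
    probability is 1 and its information content 0.
    """
    names = {
        "GO:Term_1": "root function",
        "GO:Term_2": "broad function A",
        "GO:Term_3": "broad function B",
        "GO:Term_4": "narrow function B1",
        "GO:Term_5": "narrow function B2",
    }
    parents = {
        "GO:Term_1": frozenset(),
        "GO:Term_2": frozenset({"GO:Term_1"}),
        "GO:Term_3": frozenset({"GO:Term_1"}),
        "GO:Term_4": frozenset({"GO:Term_3"}),
        "GO:Term_5": frozenset({"GO:Term_3"}),
    }
    terms = {
        tid: Term(
            term_id=tid,
            name=names[tid],
            namespace="molecular_function",
            parents=parents[tid],
        )
        for tid in names
    }
    dag = OntologyDAG(terms, root_id="GO:Term_1")
    by_gene = {
        "unit01": frozenset({"GO:Term_3"}),
        "unit02": frozenset({"GO:Term_4"}),
        "unit03": frozenset({"GO:Term_4"}),
        "unit04": frozenset({"GO:Term_5"}),
        "unit05": frozenset({"GO:Term_2"}),
        "unit06": frozenset({"GO:Term_2"}),
        "unit07": frozenset({"GO:Term_2"}),
        "unit08": frozenset({"GO:Term_2"}),
        "unit09": frozenset({"GO:Term_2"}),
        "unit10": frozenset({"GO:Term_2"}),
        "unit11": frozenset({"GO:Term_2"}),
    }
    ann = AnnotationSet(by_gene=by_gene, namespace="molecular_function")
    return dag, ann


def generate(spec: SyntheticSpec) -> tuple[OntologyDAG, AnnotationSet]:
    """Seeded GO-like random DAG plus annotation table.

    The DAG is layered by construction: term ``i`` draws 1 to
    ``max_parents_per_term`` parents uniformly from terms ``0..i-1``, which
    guarantees acyclicity and a single root cheaply. Annotation units pick
    1-3 terms with probability weighted by ``(1 + depth) **
    annotation_depth_bias`` so deeper terms attract more annotations, as in
    real corpora.
    """
    if spec.n_terms < 2:
        raise SpecError(f"n_terms must be >= 2, got {spec.n_terms}")
    if spec.max_parents_per_term < 1:
        raise SpecError(
            f"max_parents_per_term must be >= 1, got {spec.max_parents_per_term}"
        )
    if spec.n_units < 1:
        raise SpecError(f"n_units must be >= 1, got {spec.n_units}")
    if spec.annotation_depth_bias < 0:
        raise SpecError("annotation_depth_bias must be >= 0")

    rng = random.Random(spec.seed)
    width = max(4, len(str(spec.n_terms)))
    ids = [f"SYN:{i:0{width}d}" for i in range(spec.n_terms)]
    parents: dict[str, frozenset[str]] = {ids[0]: frozenset()}
    depth: dict[str, int] = {ids[0]: 0}
    for i in range(1, spec.n_terms):
        k = rng.randint(1, min(spec.max_parents_per_term, i))
        chosen = rng.sample(ids[:i], k)
        parents[ids[i]] = frozenset(chosen)
        depth[ids[i]] = 1 + max(depth[p] for p in chosen)
    terms = {
        tid: Term(
            term_id=tid,
            name=f"synthetic term {tid}",
            namespace="molecular_function",
            parents=parents[tid],
        )
        for tid in ids
    }
    dag = OntologyDAG(terms, root_id=ids[0])

    weights = [(1 + depth[t]) ** spec.annotation_depth_bias for t in ids]
    by_gene: dict[str, frozenset[str]] = {}
    unit_width = max(4, len(str(spec.n_units)))
    for u in range(spec.n_units):
        n_terms = rng.randint(1, min(3, len(ids)))
        chosen_terms = set()
        while len(chosen_terms) < n_terms:
            chosen_terms.add(rng.choices(ids, weights=weights, k=1)[0])
        by_gene[f"unit{u:0{unit_width}d}"] = frozenset(chosen_terms)
    ann = AnnotationSet(by_gene=by_gene, namespace="molecular_function")
    return dag, ann


def write_fixture(
    dag: OntologyDAG, ann: AnnotationSet, directory: str | Path
) -> tuple[Path, Path]:
    """Write a DAG + annotation set as an OBO file and a gene2go TSV.

    Both files round-trip through :func:`termspec.ontology.parse_obo` and
    :func:`termspec.annotations.read_gene2go` back to equal objects.

    Returns the ``(obo_path, tsv_path)`` pair.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    obo_path = directory / "ontology.obo"
    tsv_path = directory / "annotations.tsv"
    try:
        obo_path.write_text(serialize_obo(dag), encoding="utf-8")
        lines = ["GeneID\tGOTerm"]
        for gene in sorted(ann.by_gene):
            for term in sorted(ann.by_gene[gene]):
                lines.append(f"{gene}\t{term}")
        tsv_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"writing fixture under {directory}: {exc}") from exc
    return obo_path, tsv_path
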
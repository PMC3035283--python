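# termspec

Function-specificity metrics for ontology terms. Given an OBO-format
ontology (e.g. the Gene Ontology molecular-function namespace) and an
optional gene/protein→term annotation table, `termspec` computes four
per-term specificity measures:

| Metric | Definition | Range |
|---|---|---|
| `n_ancestors` | unique terms above, up to and including the root | 0 (root) … |
| `offsp_n` | normalized offspring, `ln((M+1)/(k+1))` with `k` the term's offspring count and `M` the root's | 0 (root) … `ln(M+1)` (leaf), nats |
| `go_prop` | `1 − offspring/(offspring + ancestors)` | 0 (root) … 1 (leaf); NA on 0/0 |
| `ic` | information content `−log₂ p(t)`, where `p(t)` is the fraction of annotation units assigned to the term or any of its offspring | 0 (root) …, bits; NA if the term never occurs |

Ancestor/offspring counts are over unique nodes (never paths); annotation
units are deduplicated inside a term's closure so `p(t) ≤ 1` and IC stays
monotone along edges (`--count-mode sum` reproduces the literal
add-the-counts reading instead).

## CLI

Compute a per-term metric table (TSV, `NA` for undefined values, `#`
metadata header):

```sh
# emit the built-in toy ontology + 11-unit annotation table, then score it
termspec compute --seed-fixtures fixtures/
termspec compute fixtures/ontology.obo fixtures/annotations.tsv --out metrics.tsv

# real data: GO molecular function + NCBI gene2go, is_a + part_of parents
termspec compute go.obo gene2go --namespace molecular_function \
    --edge-types is_a,part_of --taxon 9606 --out metrics.tsv
```

Annotation input is NCBI gene2go TSV (full 8-column or minimal
`GeneID`/`GOTerm` dialect) or GAF 2.x via `--format gaf`; `.gz` files are
accepted. Exit codes: 1 for ontology validation failures (cycles, dangling
edges, ambiguous roots), 2 for file/schema problems.

Correlate the metrics (Pearson + Spearman, pairwise-complete over NA):

```sh
termspec correlate metrics.tsv --out corr.tsv --plot scatter.png
```

## Library

```python
import termspec as ts

dag = ts.parse_obo(open("go.obo"), namespace_filter="molecular_function")
ann = ts.read_gene2go("gene2go", dag, taxon_filter=9606)
records = ts.compute_all(dag, ann)          # term_id -> SpecificityRecord
records["GO:0005518"].ic
```

`termspec.synthetic` provides the frozen toy fixture
(`figure1_fixture()`) and a seeded generator of GO-like layered random
DAGs with annotation tables (`generate(SyntheticSpec(...))`) for testing.

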
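"""Metric table serialization and the metric-correlation report.

The per-term table is a TSV with a fixed column order, one row per
non-obsolete term, floats at 6 significant digits and undefined values as
``NA``. Lines starting with ``#`` carry run metadata (M, edge types,
dropped-annotation counts) so a table is self-describing.

The correlation report computes Pearson and Spearman matrices over the four
specificity metrics, pairwise-complete: for each metric pair only rows where
both values are defined enter, and the per-pair n is reported. Terms with
undefined IC are expected (any term absent from the data set), so listwise
deletion would bias the structural-metric correlations.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd
from scipy import stats

from .metrics import SpecificityRecord

#: Fixed output column order for the per-term table.
TABLE_COLUMNS = (
    "term_id",
    "name",
    "n_ancestors",
    "n_offspring",
    "offsp_n",
    "go_prop",
    "p",
    "ic",
)

#: Metrics entering the correlation report.
CORRELATION_METRICS = ("n_ancestors", "offsp_n", "go_prop", "ic")


def _fmt(value: float | int | None) -> str:
    if value is None:
        return "NA"
    if isinstance(value, int):
        return str(value)
    return f"{value:.6g}"


def format_metric_table(
    records: Mapping[str, SpecificityRecord],
    names: Mapping[str, str],
    metadata: Iterable[str] = (),
) -> str:
    """Render records as TSV text with ``#`` metadata header lines."""
    lines = [f"# {m}" for m in metadata]
    lines.append("\t".join(TABLE_COLUMNS))
    for term_id in records:
        r = records[term_id]
        lines.append(
            "\t".join(
                [
                    r.term_id,
                    names.get(term_id, ""),
                    str(r.n_ancestors),
                    str(r.n_offspring),
                    _fmt(r.offsp_n),
                    _fmt(r.go_prop),
                    _fmt(r.p),
                    _fmt(r.ic),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def read_metric_table(source: IO[str] | str | Path) -> pd.DataFrame:
    """Load a TSV produced by :func:`format_metric_table`.

    ``NA`` becomes NaN; metadata lines are skipped.
    """
    df = pd.read_csv(
        source,
        sep="\t",
        comment="#",
        na_values=["NA"],
        keep_default_na=False,
        dtype={"term_id": str, "name": str},
    )
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metric table missing columns: {missing}")
    return df


def correlation_report(
    table: pd.DataFrame, metrics: Iterable[str] = CORRELATION_METRICS
) -> dict[str, pd.DataFrame]:
    """Pairwise-complete Pearson/Spearman matrices plus per-pair n.

    Returns ``{"pearson": ..., "spearman": ..., "n": ...}``; all three are
    symmetric with unit (or full-n) diagonals. Metrics whose column is
    entirely undefined are dropped with a warning by the caller.

    Raises
    ------
    ValueError
        If fewer than 3 rows have defined values for some retained pair.
    """
    metrics = [m for m in metrics if m in table.columns]
    usable = [m for m in metrics if table[m].notna().sum() > 0]
    pearson = pd.DataFrame(index=usable, columns=usable, dtype=float)
    spearman = pd.DataFrame(index=usable, columns=usable, dtype=float)
    counts = pd.DataFrame(index=usable, columns=usable, dtype=int)
    for a in usable:
        for b in usable:
            pair = table[[a, b]].dropna()
            n = len(pair)
            counts.loc[a, b] = n
            if n < 3:
                raise ValueError(
                    f"need >= 3 rows with defined values for ({a}, {b}); got {n}"
                )
            if a == b:
                pearson.loc[a, b] = 1.0
                spearman.loc[a, b] = 1.0
                continue
            x = pair[a].to_numpy(dtype=float)
            y = pair[b].to_numpy(dtype=float)
            pr = stats.pearsonr(x, y).statistic
            sr = stats.spearmanr(x, y).statistic
            pearson.loc[a, b] = pr if math.isfinite(pr) else float("nan")
            spearman.loc[a, b] = sr if math.isfinite(sr) else float("nan")
    return {"pearson": pearson, "spearman": spearman, "n": counts}


def format_correlation_report(matrices: Mapping[str, pd.DataFrame]) -> str:
    """Render the three matrices as one TSV document with ``#`` section
    headers."""
    chunks = []
    for key in ("pearson", "spearman", "n"):
        df = matrices[key]
        chunks.append(f"# {key}")
        chunks.append(df.to_csv(sep="\t", index_label="metric").rstrip("\n"))
    return "\n".join(chunks) + "\n"


def scatter_matrix_plot(table: pd.DataFrame, out_path: str | Path) -> Path:
    """Save a scatter-plot matrix of the four metrics to ``out_path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = [m for m in CORRELATION_METRICS if table[m].notna().sum() > 0]
    n = len(cols)
    fig, axes = plt.subplots(n, n, figsize=(2.2 * n, 2.2 * n))
    for i, yi in enumerate(cols):
        for j, xj in enumerate(cols):
            ax = axes[i][j] if n > 1 else axes
            if i == j:
                ax.hist(table[xj].dropna(), bins=20, color="steelblue")
            else:
                pair = table[[xj, yi]].dropna()
                ax.scatter(pair[xj], pair[yi], s=4, alpha=0.5)
            if i == n - 1:
                ax.set_xlabel(xj, fontsize=8)
            if j == 0:
                ax.set_ylabel(yi, fontsize=8)
            ax.tick_params(labelsize=6)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
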
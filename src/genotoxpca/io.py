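"""Readers and writers for the pipeline's tab-separated formats.

Two layouts are supported:

* long-format expression tables (columns ``chemical, dose, time, replicate,
  gene, value``), one row per animal x gene;
* wide-format ratio matrices in the supplementary-table layout: a leading
  dose-point label column followed by one column per gene.

Both readers accept ASCII hyphens and Unicode minus signs in numbers, and
match gene symbols case-insensitively against the requested panel.
"""
from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import FormatError
from .types import (
    EXPRESSION_COLUMNS,
    ExpressionTable,
    GenePanel,
    RatioMatrix,
    Scale,
)

#: Unicode dash variants occasionally used as minus signs in typeset tables.
_MINUS_VARIANTS = {"−": "-", "–": "-", "—": "-"}


def _normalize_minus(text: str) -> str:
    for bad, good in _MINUS_VARIANTS.items():
        text = text.replace(bad, good)
    return text


def _read_tsv(path: str | Path) -> pd.DataFrame:
    raw = Path(path).read_text(encoding="utf-8")
    raw = _normalize_minus(raw)
    stripped = [ln for ln in raw.splitlines() if ln.strip() and not ln.startswith("#")]
    if len(stripped) < 2:
        raise FormatError(f"{path}: no data rows")
    try:
        return pd.read_csv(
            _stdio.StringIO(raw),
            sep="\t",
            comment="#",
            float_precision="round_trip",
        )
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc


def load_expression_table(
    path: str | Path,
    layout: Mapping[str, str] | None = None,
    scale: Scale | str = Scale.LOG2,
) -> ExpressionTable:
    """Read a long-format expression TSV.

    *layout* optionally maps canonical column names (``chemical``, ``dose``,
    ``time``, ``replicate``, ``gene``, ``value``) to the names used in the
    file.
    """
    df = _read_tsv(path)
    layout = dict(layout or {})
    rename = {}
    for canonical in EXPRESSION_COLUMNS:
        source = layout.get(canonical, canonical)
        if source not in df.columns:
            raise FormatError(f"{path}: missing required column {source!r}")
        rename[source] = canonical
    df = df.rename(columns=rename)
    return ExpressionTable(df, scale=Scale(scale))


def save_expression_table(table: ExpressionTable, path: str | Path) -> None:
    df = table.data.copy()
    df["dose"] = df["dose"].map(lambda d: d.value)
    df["time"] = df["time"].map(lambda t: t.value)
    df.to_csv(path, sep="\t", index=False)


def load_ratio_matrix(
    path: str | Path, panel: GenePanel | None = None
) -> RatioMatrix:
    """Read a wide-format (supplementary-table style) ratio matrix.

    The first column holds dose-point labels; remaining columns are genes.
    When *panel* is given, columns are reordered to panel order and renamed
    to the panel's capitalization.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a label column plus gene columns")
    df = df.set_index(df.columns[0])
    df.index.name = "dose_point"
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric ratio values ({exc})") from exc
    n_rep = None
    rep_cols = [c for c in df.columns if c.lower() == "n_replicates"]
    if rep_cols:
        n_rep = df[rep_cols[0]].astype(int)
        df = df.drop(columns=rep_cols)
    matrix = RatioMatrix(df, n_replicates=n_rep)
    if panel is not None:
        matrix = matrix.reorder_to_panel(panel)
    return matrix


def save_ratio_matrix(matrix: RatioMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    if matrix.n_replicates is not None:
        df["n_replicates"] = matrix.n_replicates.astype(int)
    df.to_csv(path, sep="\t", index=True, index_label="dose_point")


def save_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index=True, index_label="dose_point")


def load_scores(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path).set_index("dose_point")
    for col in ("pc1", "pc2"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    return df


def load_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV of dose-point id -> class label."""
    from .types import ChemClass

    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected dose_point and class columns")
    ids = df.iloc[:, 0].astype(str)
    labels = df.iloc[:, 1].map(lambda s: ChemClass(str(s).strip().upper()))
    return pd.Series(labels.to_numpy(), index=pd.Index(ids, name="dose_point"))


def save_labels(labels: pd.Series, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "dose_point": labels.index,
            "class": [getattr(v, "value", v) for v in labels],
        }
    )
    out.to_csv(path, sep="\t", index=False)
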
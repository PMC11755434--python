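"""Per-cell state scores: mean MES, mean EPITH, their ratio, and STEM.

Each score is the plain arithmetic mean of the cell's log-normalized
expression over the (present) genes of a panel — no rank transformation and
no background-gene correction.  The MES/EPITH ratio summarizes the hybrid
E/M balance of a cell; because mean EPITH can be exactly zero in sparse
single-cell data, the ratio is guarded with a small epsilon and cells near
the guard are flagged as unstable.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model_io import (
    CellMetadata,
    ExpressionMatrix,
    ValidationError,
    align,
    logger,
)
from .panels import GenePanel, panels_by_category, resolve_panel

#: default ratio guard; mean_epith below 10*eps flags the ratio as unstable
RATIO_EPS = 1e-8

SCORE_COLUMNS = ("mean_mes", "mean_epith", "mes_epith_ratio", "stem_score")


def _panel_row_means(matrix: ExpressionMatrix, panel: GenePanel) -> np.ndarray:
    """Mean over present panel genes for every cell, vectorized."""
    present, _ = resolve_panel(panel, matrix)
    sub = matrix.subset_genes(present)
    vals = sub.values
    if sp.issparse(vals):
        return np.asarray(vals.mean(axis=0)).ravel()
    return vals.mean(axis=0)


def panel_mean(matrix: ExpressionMatrix, panel: GenePanel, cell_id: str) -> float:
    """Arithmetic mean of one cell's expression over present panel genes."""
    try:
        j = matrix.cell_ids.index(cell_id)
    except ValueError:
        raise KeyError(f"cell {cell_id!r} not in matrix") from None
    return float(_panel_row_means(matrix, panel)[j])


def score_cells(matrix: ExpressionMatrix, meta: CellMetadata,
                panels: list[GenePanel], eps: float = RATIO_EPS
                ) -> pd.DataFrame:
    """Score every cell, returning a ScoreTable.

    The returned frame is indexed by cell_id with columns mean_mes,
    mean_epith, mes_epith_ratio, stem_score and flags.  stem_score is
    computed from the STEM panel whose (tissue_class, organ) key matches the
    cell; cells without a matching panel get NaN.  The ratio is
    mean_mes / (mean_epith + eps); cells with mean_epith < 10*eps carry an
    ``unstable_ratio`` flag.
    """
    matrix, meta = align(matrix, meta)
    by_cat = panels_by_category(panels)
    if not by_cat["MES"] or not by_cat["EPITH"]:
        raise ValidationError("score_cells requires one MES and one EPITH panel")
    if len(by_cat["MES"]) > 1 or len(by_cat["EPITH"]) > 1:
        raise ValidationError("at most one MES and one EPITH panel allowed")

    mean_mes = _panel_row_means(matrix, by_cat["MES"][0])
    mean_epith = _panel_row_means(matrix, by_cat["EPITH"][0])
    ratio = mean_mes / (mean_epith + eps)
    unstable = mean_epith < 10 * eps

    stem = np.full(matrix.n_cells, np.nan)
    stem_panels = {p.key: p for p in by_cat["STEM"]}
    if stem_panels:
        keys = list(zip(meta.column("tissue_class"), meta.column("organ")))
        unmatched: set[tuple[str, str]] = set()
        for key, panel in stem_panels.items():
            cols = [j for j, k in enumerate(keys) if k == key]
            if cols:
                vals = _panel_row_means(matrix, panel)
                stem[cols] = vals[cols]
        unmatched = {k for k in keys if k not in stem_panels}
        if unmatched:
            logger.warning(
                "no STEM panel for %d (tissue_class, organ) keys: %s",
                len(unmatched), sorted(unmatched)[:5],
            )

    flags = np.where(unstable, "unstable_ratio", "")
    table = pd.DataFrame(
        {
            "mean_mes": mean_mes,
            "mean_epith": mean_epith,
            "mes_epith_ratio": ratio,
            "stem_score": stem,
            "flags": flags,
        },
        index=pd.Index(matrix.cell_ids, name="cell_id"),
    )
    if not np.all(np.isfinite(table["mean_mes"])) or \
            not np.all(np.isfinite(table["mean_epith"])):
        raise ValidationError("non-finite panel means computed")
    return table


def score_summary(scores: pd.DataFrame, meta: CellMetadata,
                  group_by: str) -> pd.DataFrame:
    """Per-group mean and standard error of each score.

    Groups with a single cell get NaN standard errors (undefined).  The SE
    is the sample standard deviation (ddof=1) divided by sqrt(n).
    """
    groups = meta.column(group_by).reindex(scores.index)
    if groups.isna().any():
        raise ValidationError("scores contain cells absent from metadata")
    rows = []
    for label, idx in sorted(scores.groupby(groups).groups.items()):
        block = scores.loc[idx, list(SCORE_COLUMNS)]
        n = len(block)
        row: dict[str, object] = {group_by: label, "n": n}
        for col in SCORE_COLUMNS:
            vals = block[col].dropna().to_numpy()
            row[f"{col}_mean"] = vals.mean() if vals.size else math.nan
            row[f"{col}_se"] = (
                vals.std(ddof=1) / math.sqrt(len(vals))
                if len(vals) >= 2 else math.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index(group_by)


def write_scores(scores: pd.DataFrame, path: str | Path) -> Path:
    """Write a ScoreTable as TSV with the documented header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    scores.reset_index().to_csv(path, sep="\t", index=False,
                                float_format="%.17g")
    return path


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").set_index("cell_id")
    df["flags"] = df.get("flags", pd.Series("", index=df.index)).fillna("")
    return df
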
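"""Pseudobulk collapsing of cells into per-group mean profiles.

Cells sharing an annotation (cell type, embryonic origin, stage, ...) are
averaged gene-wise into a single profile; the per-cell MES/EPITH scores are
averaged alongside, and the group's MES/EPITH ratio is recomputed from the
collapsed means (ratios of means, not means of ratios).  A second-level
collapse by embryonic origin is cell-weighted so the global mean expression
is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model_io import CellMetadata, ExpressionMatrix, ValidationError, align
from .scoring import RATIO_EPS


@dataclass
class CollapsedProfile:
    """Mean expression and scores over all cells of one group."""

    group_id: str
    n_cells: int
    gene_ids: list[str]
    expression: np.ndarray
    mean_mes: float
    mean_epith: float
    mes_epith_ratio: float
    embryonic_origin: str = "unassigned"
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float).ravel()
        if self.n_cells < 1:
            raise ValidationError(f"group {self.group_id!r}: n_cells < 1")
        if self.expression.size != len(self.gene_ids):
            raise ValidationError(
                f"group {self.group_id!r}: expression length "
                f"{self.expression.size} != {len(self.gene_ids)} genes"
            )


def _dominant(values: pd.Series) -> str:
    """Most frequent value; lexicographically smallest on ties."""
    counts = values.value_counts()
    top = counts[counts == counts.max()].index
    return sorted(top)[0]


def collapse(matrix: ExpressionMatrix, meta: CellMetadata,
             scores: pd.DataFrame, by: str,
             eps: float = RATIO_EPS) -> list[CollapsedProfile]:
    """Collapse cells into one profile per level of metadata column ``by``.

    Returns profiles in deterministic lexicographic group order.  Each
    profile carries the gene-wise mean expression, the group means of the
    per-cell mean_mes / mean_epith, the recomputed group ratio, and the
    group's dominant embryonic origin annotation.
    """
    matrix, meta = align(matrix, meta)
    groups = meta.column(by)
    labels = sorted(groups.unique())
    if not labels:
        raise ValidationError("no groups to collapse")
    dense_cols = matrix.values
    col_pos = {c: j for j, c in enumerate(matrix.cell_ids)}
    profiles = []
    for label in labels:
        members = [c for c in matrix.cell_ids if groups[c] == label]
        cols = [col_pos[c] for c in members]
        block = dense_cols[:, cols]
        expr = (np.asarray(block.mean(axis=1)).ravel()
                if sp.issparse(block) else block.mean(axis=1))
        sub_scores = scores.loc[members]
        m_mes = float(sub_scores["mean_mes"].mean())
        m_epith = float(sub_scores["mean_epith"].mean())
        profiles.append(CollapsedProfile(
            group_id=str(label),
            n_cells=len(cols),
            gene_ids=list(matrix.gene_ids),
            expression=expr,
            mean_mes=m_mes,
            mean_epith=m_epith,
            mes_epith_ratio=m_mes / (m_epith + eps),
            embryonic_origin=_dominant(meta.table.loc[members,
                                                      "embryonic_origin"]),
        ))
    return profiles


def collapse_by_origin(profiles: list[CollapsedProfile],
                       eps: float = RATIO_EPS) -> list[CollapsedProfile]:
    """Second-level collapse of per-type profiles by embryonic origin.

    The aggregate is cell-weighted (weights = n_cells), which conserves the
    global mean expression; "unassigned" origins are kept as their own group.
    """
    if not profiles:
        raise ValidationError("no profiles to collapse")
    gene_ids = profiles[0].gene_ids
    for p in profiles:
        if p.gene_ids != gene_ids:
            raise ValidationError("profiles disagree on gene ids")
    out = []
    origins = sorted({p.embryonic_origin for p in profiles})
    for origin in origins:
        members = [p for p in profiles if p.embryonic_origin == origin]
        w = np.array([p.n_cells for p in members], dtype=float)
        w_norm = w / w.sum()
        expr = np.einsum("g,gj->j", w_norm,
                         np.stack([p.expression for p in members]))
        m_mes = float(np.dot(w_norm, [p.mean_mes for p in members]))
        m_epith = float(np.dot(w_norm, [p.mean_epith for p in members]))
        out.append(CollapsedProfile(
            group_id=origin,
            n_cells=int(w.sum()),
            gene_ids=gene_ids,
            expression=expr,
            mean_mes=m_mes,
            mean_epith=m_epith,
            mes_epith_ratio=m_mes / (m_epith + eps),
            embryonic_origin=origin,
        ))
    return out


def profiles_to_frame(profiles: list[CollapsedProfile]) -> pd.DataFrame:
    """Tabular view: one row per group, gene columns + scores + annotations."""
    gene_ids = profiles[0].gene_ids
    rows = {p.group_id: p.expression for p in profiles}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=gene_ids)
    df.index.name = "group_id"
    df["n_cells"] = [p.n_cells for p in profiles]
    df["mean_mes"] = [p.mean_mes for p in profiles]
    df["mean_epith"] = [p.mean_epith for p in profiles]
    df["mes_epith_ratio"] = [p.mes_epith_ratio for p in profiles]
    df["embryonic_origin"] = [p.embryonic_origin for p in profiles]
    return df


def write_profiles(profiles: list[CollapsedProfile], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    profiles_to_frame(profiles).reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.17g")
    return path
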
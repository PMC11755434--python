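"""Correlation-matrix clustering and PCA + k-means gradient classification.

Two complementary views of how cell populations relate through their
MES/EPITH profiles:

* a Pearson correlation matrix across collapsed (pseudobulk) profiles,
  hierarchically clustered with average linkage (UPGMA) on distance 1 - r;
* a per-cell PCA (five components) of the MES+EPITH panel expression,
  followed by 2-means clustering, summarized per cell type as the mean
  cluster membership — a gradient in [0, 1] from the epithelial-high pole
  (0) to the opposite pole (1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .data_model_io import CellMetadata, ExpressionMatrix, ValidationError, align, logger
from .collapse_annotate import CollapsedProfile
from .panels import GenePanel, panels_by_category, resolve_panel

GENE_SUBSETS = ("whole_transcriptome", "panel_only")


@dataclass
class CorrelationResult:
    """Symmetric Pearson correlation matrix over collapsed profiles."""

    labels: list[str]
    matrix: np.ndarray
    annotations: pd.DataFrame
    constant_profiles: list[str] = field(default_factory=list)
    linkage: np.ndarray | None = None
    linkage_order: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValidationError("correlation matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValidationError("correlation matrix not symmetric")


@dataclass
class GradientResult:
    """Per-cell cluster labels and per-type gradient from PCA + 2-means."""

    per_sample_cluster: pd.Series
    per_type_gradient: pd.Series
    pca_coords: pd.DataFrame
    seed: int
    inertia: float


def correlation_matrix(profiles: list[CollapsedProfile],
                       gene_subset: str = "whole_transcriptome",
                       panels: list[GenePanel] | None = None
                       ) -> CorrelationResult:
    """Pairwise Pearson correlation between profile expression vectors.

    ``panel_only`` restricts to the resolved MES + EPITH genes (``panels``
    required).  Profiles with zero variance cannot be correlated; their
    rows/columns are set to 0 (diagonal kept at 1) and the profile is
    flagged in ``constant_profiles``.
    """
    if len(profiles) < 2:
        raise ValidationError("correlation requires at least 2 profiles")
    if gene_subset not in GENE_SUBSETS:
        raise ValueError(f"gene_subset must be one of {GENE_SUBSETS}")
    gene_ids = profiles[0].gene_ids
    X = np.stack([p.expression for p in profiles])  # groups x genes
    if gene_subset == "panel_only":
        if panels is None:
            raise ValidationError("panel_only requires the panels argument")
        by_cat = panels_by_category(panels)
        wanted = []
        probe = ExpressionMatrix(gene_ids, ["_"],
                                 np.zeros((len(gene_ids), 1)))
        for p in by_cat["MES"] + by_cat["EPITH"]:
            present, _ = resolve_panel(p, probe)
            wanted.extend(present)
        index = probe.gene_index()
        from .data_model_io import canonical_gene_id
        cols = sorted({index[canonical_gene_id(g)] for g in wanted})
        X = X[:, cols]

    labels = [p.group_id for p in profiles]
    sd = X.std(axis=1)
    constant = [labels[i] for i in np.flatnonzero(sd == 0)]
    if constant:
        logger.warning("constant profiles set to correlation 0: %s", constant)
    # corrcoef would emit nan for constant rows; compute guarded
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * X.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc @ Xc.T) / denom
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)

    ann = pd.DataFrame(
        {
            "embryonic_origin": [p.embryonic_origin for p in profiles],
            "mean_mes": [p.mean_mes for p in profiles],
            "mean_epith": [p.mean_epith for p in profiles],
            "mes_epith_ratio": [p.mes_epith_ratio for p in profiles],
        },
        index=pd.Index(labels, name="group_id"),
    )
    return CorrelationResult(labels=labels, matrix=corr, annotations=ann,
                             constant_profiles=constant)


def cluster_labels(result: CorrelationResult) -> list[str]:
    """UPGMA leaf order of the profiles under distance d = 1 - r.

    Profiles are pre-sorted lexicographically by label so tied merges
    resolve deterministically; the linkage matrix is stored on the result.
    """
    order0 = np.argsort(np.asarray(result.labels, dtype=object))
    labels = [result.labels[i] for i in order0]
    corr = result.matrix[np.ix_(order0, order0)]
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = sch.linkage(condensed, method="average")
    leaves = sch.leaves_list(Z)
    result.linkage = Z
    result.linkage_order = [labels[i] for i in leaves]
    return result.linkage_order


def pca_kmeans_gradient(matrix: ExpressionMatrix, meta: CellMetadata,
                        scores: pd.DataFrame,
                        n_components: int = 5, k: int = 2,
                        seed: int = 0, n_restarts: int = 10
                        ) -> GradientResult:
    """PCA of panel expression per cell, 2-means on the PC coordinates.

    ``matrix`` should already be restricted to the MES + EPITH panel genes.
    Cells are centered gene-wise (no scaling: panel genes share units);
    k-means runs with ``n_restarts`` initializations.  Clusters are oriented
    deterministically: cluster 0 is the one with the higher mean mean_epith,
    so the per-type gradient reads as 0 = epithelial pole.  The per-type
    gradient is the mean cluster label over the type's cells.
    """
    matrix, meta = align(matrix, meta)
    if matrix.n_cells < 2:
        raise ValidationError("PCA/k-means requires at least 2 cells")
    if matrix.n_genes < 2:
        raise ValidationError("PCA/k-means requires at least 2 panel genes")
    X = matrix.dense().T  # cells x genes
    cap = min(matrix.n_genes, matrix.n_cells) - 1
    if n_components > cap:
        logger.warning("n_components capped at %d", cap)
        n_components = cap
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)  # centers gene-wise internally

    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(coords)

    epith = scores["mean_epith"].reindex(matrix.cell_ids).to_numpy()
    cluster_epith = [epith[raw == c].mean() if np.any(raw == c) else -np.inf
                     for c in range(k)]
    # relabel so cluster 0 has the highest mean EPITH score
    order = np.argsort(cluster_epith)[::-1]
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw]

    per_sample = pd.Series(labels, index=pd.Index(matrix.cell_ids,
                                                  name="cell_id"),
                           name="cluster")
    types = meta.column("cell_type")
    gradient = per_sample.groupby(types).mean().sort_index()
    gradient.name = "gradient"
    coords_df = pd.DataFrame(
        coords, index=per_sample.index,
        columns=[f"PC{i + 1}" for i in range(n_components)])
    return GradientResult(per_sample_cluster=per_sample,
                          per_type_gradient=gradient,
                          pca_coords=coords_df, seed=seed,
                          inertia=float(km.inertia_))


def kmeans_objective(coords: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squares for a label assignment (oracle helper)."""
    total = 0.0
    for c in np.unique(labels):
        block = coords[labels == c]
        total += ((block - block.mean(axis=0)) ** 2).sum()
    return float(total)
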
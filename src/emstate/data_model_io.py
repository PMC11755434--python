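"""Core data containers and readers/writers for single-cell expression data.

The pipeline operates on already log-normalized expression values: matrices
are consumed "as provided" and never re-normalized, batch-corrected or
QC-filtered here.  The internal orientation is fixed as genes x cells; the
cells x genes layout of the h5ad dialect is transposed on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("emstate")

TISSUE_CLASSES = (
    "epithelial",
    "skeletal_muscle",
    "cardiac_muscle",
    "smooth_muscle",
    "connective",
    "blood",
    "other",
)

EMBRYONIC_ORIGINS = (
    "ectoderm",
    "endoderm",
    "paraxial_mesoderm",
    "lateral_mesoderm",
    "mesenchyme",
    "unassigned",
)

#: metadata columns guaranteed to exist on CellMetadata.table
METADATA_COLUMNS = ("cell_type", "tissue_class", "organ", "embryonic_origin")

_VERSION_SUFFIX = re.compile(r"\.\d+$")


class ValidationError(ValueError):
    """Raised when a container or file violates a structural invariant."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending part."""


def canonical_gene_id(symbol: str) -> str:
    """Canonical form used for gene matching across datasets.

    Version suffixes are stripped (``ENSG000001.4`` -> ``ENSG000001``) and the
    symbol is upper-cased so human (CDH1) and mouse (Cdh1) symbols match.
    """
    return _VERSION_SUFFIX.sub("", symbol.strip()).upper()


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix of log-normalized expression values.

    Parameters
    ----------
    gene_ids, cell_ids
        Ordered unique identifiers for rows and columns.
    values
        Dense ndarray or scipy sparse matrix, shape (n_genes, n_cells).
        Values must be finite and non-negative unless ``centered`` is set.
    centered
        Flag for matrices that have been centered/scaled and may hold
        negative values.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray | sp.spmatrix
    centered: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if not sp.issparse(self.values):
            self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        for label, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise ValidationError(f"duplicated {label} ids: {dupes[:5]}")
        dense_probe = self.values.data if sp.issparse(self.values) else self.values
        if dense_probe.size and not np.all(np.isfinite(dense_probe)):
            raise ValidationError("matrix contains non-finite values")
        if not self.centered and dense_probe.size and dense_probe.min() < 0:
            raise ValidationError(
                "negative values in a matrix not flagged as centered"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        """Dense ndarray view of the values (copy if sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def gene_index(self) -> dict[str, int]:
        """Map canonical gene id -> row index (first occurrence wins)."""
        index: dict[str, int] = {}
        for i, g in enumerate(self.gene_ids):
            index.setdefault(canonical_gene_id(g), i)
        return index

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to the given genes (canonical matching), preserving order."""
        index = self.gene_index()
        rows = [index[canonical_gene_id(g)] for g in genes
                if canonical_gene_id(g) in index]
        if not rows:
            raise ValidationError("no requested genes present in matrix")
        vals = self.values[rows, :]
        return ExpressionMatrix(
            [self.gene_ids[r] for r in rows], list(self.cell_ids), vals,
            centered=self.centered,
        )

    def subset_cells(self, cells: Iterable[str]) -> "ExpressionMatrix":
        pos = {c: j for j, c in enumerate(self.cell_ids)}
        cols = [pos[c] for c in cells if c in pos]
        vals = self.values[:, cols]
        return ExpressionMatrix(
            list(self.gene_ids), [self.cell_ids[j] for j in cols], vals,
            centered=self.centered,
        )


@dataclass
class CellMetadata:
    """Per-cell annotations keyed by ``cell_id``.

    The underlying table always carries the columns in METADATA_COLUMNS;
    absent annotations are filled with "unassigned".  Optional columns
    (``stage``, ``truth_state``, ...) are kept as-is.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        df = self.table.copy()
        if "cell_id" in df.columns:
            df = df.set_index("cell_id")
        df.index = df.index.astype(str)
        df.index.name = "cell_id"
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated cell ids in metadata: {dupes[:5]}")
        for col in METADATA_COLUMNS:
            if col not in df.columns:
                df[col] = "unassigned"
            df[col] = df[col].fillna("unassigned").astype(str)
        bad = set(df["tissue_class"]) - set(TISSUE_CLASSES) - {"unassigned"}
        if bad:
            raise ValidationError(
                f"tissue_class values outside allowed set: {sorted(bad)}"
            )
        self.table = df

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table.index)

    def column(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(f"metadata column {name!r} not present")
        return self.table[name]

    def subset(self, cells: Iterable[str]) -> "CellMetadata":
        return CellMetadata(self.table.loc[list(cells)].copy())


def align(matrix: ExpressionMatrix, meta: CellMetadata
          ) -> tuple[ExpressionMatrix, CellMetadata]:
    """Align a matrix with metadata on shared cell ids.

    Cells present in the matrix but absent from metadata are dropped with a
    warning; metadata rows without a matrix column are ignored.
    """
    known = set(meta.cell_ids)
    keep = [c for c in matrix.cell_ids if c in known]
    if len(keep) < matrix.n_cells:
        logger.warning(
            "dropping %d matrix cells absent from metadata",
            matrix.n_cells - len(keep),
        )
    if not keep and matrix.n_cells:
        raise ValidationError("no overlap between matrix cells and metadata")
    return matrix.subset_cells(keep), meta.subset(keep)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

FORMATS = ("mtx_dir", "tsv", "h5ad")


def read_matrix(path: str | Path, format: str
                ) -> tuple[ExpressionMatrix, CellMetadata]:
    """Read an expression matrix plus metadata from disk.

    ``mtx_dir`` expects matrix.mtx + genes.tsv + barcodes.tsv (+ optional
    metadata.tsv); ``tsv`` a dense gene x cell table with a header row of
    cell ids (+ optional sidecar <stem>.meta.tsv); ``h5ad`` an AnnData file
    whose obs table supplies the metadata columns (read-only).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx_dir":
        return _read_mtx_dir(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "h5ad":
        return _read_h5ad(path)
    raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def _meta_from_frame(df: pd.DataFrame) -> CellMetadata:
    return CellMetadata(df)


def _read_mtx_dir(path: Path) -> tuple[ExpressionMatrix, CellMetadata]:
    mtx = path / "matrix.mtx"
    genes_f = path / "genes.tsv"
    cells_f = path / "barcodes.tsv"
    for f in (mtx, genes_f, cells_f):
        if not f.exists():
            raise ParseError(f"mtx_dir is missing companion file {f.name}")
    try:
        values = scipy.io.mmread(mtx)
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise ParseError(f"cannot parse {mtx}: {exc}") from exc
    genes = genes_f.read_text().splitlines()
    genes = [g.split("\t")[0] for g in genes if g.strip()]
    cells = [c.strip() for c in cells_f.read_text().splitlines() if c.strip()]
    meta_f = path / "metadata.tsv"
    if meta_f.exists():
        meta_df = pd.read_csv(meta_f, sep="\t", dtype=str)
        if "cell_id" not in meta_df.columns:
            raise ParseError(f"{meta_f} lacks a cell_id column")
    else:
        meta_df = pd.DataFrame({"cell_id": cells})
    matrix = ExpressionMatrix(genes, cells, sp.csr_matrix(values))
    return align(matrix, _meta_from_frame(meta_df))


def _read_tsv(path: Path) -> tuple[ExpressionMatrix, CellMetadata]:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated gene ids in {path.name}: {dupes[:5]}")
    matrix = ExpressionMatrix(
        [str(g) for g in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(dtype=float),
    )
    sidecar = path.with_suffix(".meta.tsv")
    if sidecar.exists():
        meta_df = pd.read_csv(sidecar, sep="\t", dtype=str)
    else:
        meta_df = pd.DataFrame({"cell_id": matrix.cell_ids})
    return align(matrix, _meta_from_frame(meta_df))


def _read_h5ad(path: Path) -> tuple[ExpressionMatrix, CellMetadata]:
    import anndata

    adata = anndata.read_h5ad(path)
    values = adata.X.T if adata.X is not None else np.zeros((adata.n_vars, 0))
    if sp.issparse(values):
        values = sp.csr_matrix(values)
    else:
        values = np.asarray(values, dtype=float)
    matrix = ExpressionMatrix(
        [str(g) for g in adata.var_names],
        [str(c) for c in adata.obs_names],
        values,
    )
    meta_df = adata.obs.reset_index(names="cell_id")
    return align(matrix, _meta_from_frame(meta_df))


def write_matrix(matrix: ExpressionMatrix, meta: CellMetadata,
                 path: str | Path, format: str) -> Path:
    """Write matrix + metadata so that :func:`read_matrix` round-trips."""
    path = Path(path)
    matrix, meta = align(matrix, meta)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(matrix.values),
                         precision=17)
        (path / "genes.tsv").write_text(
            "".join(f"{g}\n" for g in matrix.gene_ids))
        (path / "barcodes.tsv").write_text(
            "".join(f"{c}\n" for c in matrix.cell_ids))
        meta.table.reset_index().to_csv(path / "metadata.tsv", sep="\t",
                                        index=False)
        return path
    if format == "tsv":
        path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(matrix.dense(), index=matrix.gene_ids,
                          columns=matrix.cell_ids)
        df.to_csv(path, sep="\t", float_format="%.17g")
        meta.table.reset_index().to_csv(path.with_suffix(".meta.tsv"),
                                        sep="\t", index=False)
        return path
    raise ValueError(f"unsupported write format {format!r}")


def attach_embryonic_origin(meta: CellMetadata,
                            mapping: Mapping[str, str]) -> CellMetadata:
    """Assign embryonic-origin annotations per cell type.

    Cell types absent from ``mapping`` become "unassigned" (warned once).
    Mapping values must be drawn from the allowed origin categories.
    """
    bad = sorted(set(mapping.values()) - set(EMBRYONIC_ORIGINS))
    if bad:
        raise ValidationError(
            f"embryonic origin values outside allowed set: {bad}"
        )
    df = meta.table.copy()
    origins = df["cell_type"].map(mapping)
    unmapped = sorted(df.loc[origins.isna(), "cell_type"].unique())
    if unmapped:
        logger.warning("cell types without origin mapping -> unassigned: %s",
                       unmapped)
    df["embryonic_origin"] = origins.fillna("unassigned")
    return CellMetadata(df)
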
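"""Expression-matrix container, QC filters, log-normalization, and file IO.

The central object is :class:`ExpressionMatrix`, a thin wrapper around an
:class:`anndata.AnnData` (cells x genes) that enforces the metadata contract
used throughout the pipeline: every cell carries a ``cell_line`` and a
``cluster`` label plus treatment annotations.  Matrices move through two
layers: raw ``counts`` and ``lognorm`` (library-size scaled, log1p).

On-disk formats are the field's plain-text standards: MatrixMarket (.mtx,
genes x cells) with ``genes.tsv``/``barcodes.tsv`` sidecars and a cell
metadata TSV; gene sets travel as GMT.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

META_COLUMNS = ("cell_line", "cluster", "treated", "drug", "drug_class")

COUNTS = "counts"
LOGNORM = "lognorm"


class QCError(ValueError):
    """Raised when a QC filter would leave an empty matrix."""


class ExpressionMatrix:
    """Gene x cell expression values plus per-cell metadata.

    Parameters
    ----------
    adata
        AnnData with cells in ``obs`` and genes in ``var``.  ``obs`` must
        contain ``cell_line`` and ``cluster`` columns; ``treated``, ``drug``
        and ``drug_class`` are filled with defaults if absent.
    layer_tag
        ``"counts"`` for raw non-negative integers, ``"lognorm"`` for
        log-normalized values.
    """

    def __init__(self, adata: ad.AnnData, layer_tag: str = COUNTS):
        if layer_tag not in (COUNTS, LOGNORM):
            raise ValueError(f"unknown layer_tag {layer_tag!r}")
        obs = adata.obs
        for col, default in (("treated", True), ("drug", ""), ("drug_class", "")):
            if col not in obs.columns:
                obs[col] = default
        for col in ("cell_line", "cluster"):
            if col not in obs.columns:
                raise ValueError(f"cell metadata must contain a {col!r} column")
            if obs[col].isna().any() or (obs[col].astype(str) == "").any():
                raise ValueError(f"every cell needs a non-empty {col!r} label")
        if adata.obs_names.duplicated().any():
            raise ValueError("cell ids are not unique")
        if adata.var_names.duplicated().any():
            raise ValueError("gene ids are not unique")
        X = adata.X
        data = X.data if sp.issparse(X) else np.asarray(X)
        if data.size and float(np.min(data)) < 0:
            raise ValueError("expression values must be non-negative")
        if layer_tag == LOGNORM and data.size and not np.all(np.isfinite(data)):
            raise ValueError("lognorm values must be finite")
        adata.uns.setdefault("layer_tag", layer_tag)
        adata.uns["layer_tag"] = layer_tag
        self.adata = adata
        self.layer_tag = layer_tag

    # -- accessors ---------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.adata.var_names)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.adata.obs_names)

    @property
    def cell_meta(self) -> pd.DataFrame:
        return self.adata.obs

    @property
    def n_genes(self) -> int:
        return self.adata.n_vars

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    def dense(self) -> np.ndarray:
        """Cells x genes dense array."""
        X = self.adata.X
        return X.toarray() if sp.issparse(X) else np.asarray(X)

    def subset_cells(self, mask_or_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.adata[mask_or_ids].copy(), self.layer_tag)

    def subset_genes(self, mask_or_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.adata[:, mask_or_ids].copy(), self.layer_tag)

    def cell_lines(self) -> list[str]:
        return sorted(self.adata.obs["cell_line"].astype(str).unique())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_cells} cells, "
            f"layer={self.layer_tag})"
        )


def _detected_per_cell(m: ExpressionMatrix) -> np.ndarray:
    X = m.adata.X
    if sp.issparse(X):
        return np.asarray((X > 0).sum(axis=1)).ravel()
    return (np.asarray(X) > 0).sum(axis=1)


def _detected_per_gene(m: ExpressionMatrix, cell_mask: np.ndarray | None = None) -> np.ndarray:
    X = m.adata.X
    if cell_mask is not None:
        X = X[cell_mask]
    if sp.issparse(X):
        return np.asarray((X > 0).sum(axis=0)).ravel()
    return (np.asarray(X) > 0).sum(axis=0)


def filter_cells(
    m: ExpressionMatrix, min_features: int, max_features: int | float
) -> ExpressionMatrix:
    """Retain cells whose number of detected genes lies in [min, max].

    "Detected" means a strictly positive count.  Bounds are inclusive, so the
    protocol "remove cells with fewer than 200 or more than 2500 features"
    corresponds to ``min_features=200, max_features=2500``.  The filter is
    evaluated per cell independently, so a multi-cell-line matrix behaves
    exactly as if each line were filtered on its own.
    """
    if m.layer_tag != COUNTS:
        raise ValueError("filter_cells expects the counts layer")
    if not (0 <= min_features <= max_features):
        raise ValueError("need 0 <= min_features <= max_features")
    detected = _detected_per_cell(m)
    keep = (detected >= min_features) & (detected <= max_features)
    if not keep.any():
        raise QCError("no cells pass QC with bounds "
                      f"({min_features}, {max_features})")
    if keep.all():
        return m
    return m.subset_cells(keep)


def filter_genes(
    m: ExpressionMatrix, min_cells: int, per_line: bool = True
) -> ExpressionMatrix:
    """Retain genes detected in at least ``min_cells`` cells.

    With ``per_line=True`` (default) detection is counted within each cell
    line and a gene is kept if it passes the threshold in at least one line,
    mirroring a protocol that processes each line separately; with
    ``per_line=False`` cells are pooled.
    """
    if m.layer_tag != COUNTS:
        raise ValueError("filter_genes expects the counts layer")
    if min_cells <= 0:
        return m
    lines = m.adata.obs["cell_line"].astype(str).to_numpy()
    if per_line and len(np.unique(lines)) > 1:
        keep = np.zeros(m.n_genes, dtype=bool)
        for line in np.unique(lines):
            keep |= _detected_per_gene(m, lines == line) >= min_cells
    else:
        keep = _detected_per_gene(m) >= min_cells
    if not keep.any():
        raise QCError(f"no genes detected in >= {min_cells} cells")
    if keep.all():
        return m
    return m.subset_genes(keep)


def lognormalize(
    m: ExpressionMatrix, scale: float = 1e4, base: float | None = None
) -> ExpressionMatrix:
    """Library-size normalize and log-transform: log(1 + count/total * scale).

    Natural log by default; pass ``base`` for another logarithm.  The base and
    scale factor are recorded in the output metadata.
    """
    if m.layer_tag != COUNTS:
        raise ValueError("lognormalize expects the counts layer")
    X = m.adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [m.cell_ids[i] for i in zero[:5]]
        raise ValueError(f"cells with zero total count: {names}"
                         + (" ..." if zero.size > 5 else ""))
    if sp.issparse(X):
        out = X.astype(np.float64).tocsr(copy=True)
        inv = scale / totals
        out = sp.diags(inv) @ out
        out.data = np.log1p(out.data)
        if base is not None:
            out.data /= np.log(base)
    else:
        out = np.log1p(np.asarray(X, dtype=np.float64) * (scale / totals)[:, None])
        if base is not None:
            out /= np.log(base)
    adata = ad.AnnData(out, obs=m.adata.obs.copy(), var=m.adata.var.copy())
    adata.uns["lognorm_scale"] = float(scale)
    adata.uns["lognorm_base"] = float(base) if base is not None else float(np.e)
    return ExpressionMatrix(adata, LOGNORM)


def prep(
    m: ExpressionMatrix,
    min_features: int = 200,
    max_features: int = 2500,
    min_cells: int = 100,
    scale: float = 1e4,
    genes_first: bool = False,
) -> ExpressionMatrix:
    """Full QC + normalization: cell filter, gene filter, lognormalize.

    Default order is cells-then-genes; ``genes_first`` flips it.
    """
    steps = (
        (lambda x: filter_genes(x, min_cells), lambda x: filter_cells(x, min_features, max_features))
        if genes_first
        else (lambda x: filter_cells(x, min_features, max_features), lambda x: filter_genes(x, min_cells))
    )
    for step in steps:
        m = step(m)
    return lognormalize(m, scale=scale)


# -- MatrixMarket + TSV IO -------------------------------------------------

def write_matrix_dir(m: ExpressionMatrix, out_dir: str | Path) -> Path:
    """Write matrix.mtx (genes x cells), genes.tsv, barcodes.tsv, meta.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = m.adata.X
    mat = sp.csr_matrix(X).T  # genes x cells on disk, CellRanger-style
    scipy.io.mmwrite(str(out / "matrix.mtx"), mat)
    pd.Series(m.gene_ids).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(m.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    meta = m.cell_meta[list(META_COLUMNS)].copy()
    meta.insert(0, "cell_id", m.cell_ids)
    meta.to_csv(out / "meta.tsv", sep="\t", index=False)
    (out / "layer.txt").write_text(m.layer_tag + "\n")
    return out


def read_matrix_dir(in_dir: str | Path) -> ExpressionMatrix:
    """Read a directory written by :func:`write_matrix_dir`."""
    p = Path(in_dir)
    mat = sp.csr_matrix(scipy.io.mmread(str(p / "matrix.mtx"))).T  # cells x genes
    genes = pd.read_csv(p / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(p / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    meta = pd.read_csv(p / "meta.tsv", sep="\t", dtype={"cell_id": str}, keep_default_na=False)
    meta = meta.set_index("cell_id").reindex(cells)
    meta["treated"] = meta["treated"].astype(str).str.lower().isin(("true", "1"))
    adata = ad.AnnData(mat, obs=meta, var=pd.DataFrame(index=genes))
    adata.obs_names = cells
    layer = COUNTS
    layer_file = p / "layer.txt"
    if layer_file.exists():
        layer = layer_file.read_text().strip()
    return ExpressionMatrix(adata, layer)


# -- GMT gene sets ---------------------------------------------------------

def read_gmt(path: str | Path) -> "list":
    """Read a GMT file into a list of GeneSignature (name, description, genes...)."""
    from .signatures import GeneSignature

    sigs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, genes = fields[0], fields[1], fields[2:]
        sigs.append(GeneSignature(name=name, genes=frozenset(g for g in genes if g)))
    return sigs


def write_gmt(signatures: Iterable, path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for sig in signatures:
        lines.append("\t".join([sig.name, sig.direction] + sorted(sig.genes)))
    path.write_text("\n".join(lines) + "\n")
    return path
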
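"""Expression data container and IO.

Cells are rows, genes are columns everywhere. The container wraps an
:class:`anndata.AnnData` with raw counts in ``layers["counts"]``, log-normalized
expression in ``X``, and per-cell annotations (cell_type, subcluster, condition,
sample_id) plus the cellular detection rate (CDR) in ``obs``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

REQUIRED_ANNOTATIONS = ("cell_id", "cell_type", "condition")
OPTIONAL_ANNOTATIONS = ("subcluster", "sample_id")
DEFAULT_SCALE = 1e4  # counts-per-10k before log1p


@dataclass
class ExpressionDataset:
    """Counts + log-normalized cell x gene matrix with cell annotations."""

    adata: ad.AnnData

    # -- construction ---------------------------------------------------
    @classmethod
    def from_counts(cls, counts, genes, obs: pd.DataFrame, scale: float = DEFAULT_SCALE) -> "ExpressionDataset":
        counts = sp.csr_matrix(counts) if not sp.issparse(counts) else counts.tocsr()
        counts = counts.astype(np.float64)
        obs = obs.copy()
        if "cell_id" in obs.columns:
            obs = obs.set_index("cell_id")
        obs.index = obs.index.astype(str)
        if counts.shape[0] != len(obs):
            raise ValueError(
                f"matrix has {counts.shape[0]} cells but annotations describe {len(obs)}"
            )
        if counts.shape[1] != len(genes):
            raise ValueError(
                f"matrix has {counts.shape[1]} genes but gene list has {len(genes)}"
            )
        adata = ad.AnnData(
            X=log_normalize(counts, scale=scale),
            obs=obs,
            var=pd.DataFrame(index=pd.Index([str(g) for g in genes], name="gene")),
        )
        adata.layers["counts"] = counts
        adata.obs["cdr"] = compute_cdr(counts)
        adata.uns["lognorm_scale"] = scale
        return cls(adata)

    # -- accessors -------------------------------------------------------
    @property
    def counts(self):
        return self.adata.layers["counts"]

    @property
    def lognorm(self):
        return self.adata.X

    @property
    def obs(self) -> pd.DataFrame:
        return self.adata.obs

    @property
    def genes(self) -> pd.Index:
        return self.adata.var_names

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @property
    def n_genes(self) -> int:
        return self.adata.n_vars

    def gene_index(self, gene: str) -> int:
        try:
            return int(self.adata.var_names.get_loc(gene))
        except KeyError:
            raise KeyError(f"gene {gene!r} not in dataset") from None

    def gene_counts(self, gene: str) -> np.ndarray:
        col = self.counts[:, self.gene_index(gene)]
        return np.asarray(col.todense()).ravel() if sp.issparse(col) else np.asarray(col).ravel()

    def gene_lognorm(self, gene: str) -> np.ndarray:
        col = self.lognorm[:, self.gene_index(gene)]
        return np.asarray(col.todense()).ravel() if sp.issparse(col) else np.asarray(col).ravel()

    def detection_fraction(self) -> pd.Series:
        """Per-gene fraction of all cells with count > 0."""
        frac = np.asarray((self.counts > 0).mean(axis=0)).ravel()
        return pd.Series(frac, index=self.genes)

    def subset(self, mask) -> "ExpressionDataset":
        return ExpressionDataset(self.adata[np.asarray(mask)].copy())

    def cells_of_type(self, cell_type: str) -> "ExpressionDataset":
        return self.subset((self.obs["cell_type"] == cell_type).to_numpy())

    def conditions(self) -> list:
        return sorted(self.obs["condition"].unique())

    # -- IO ----------------------------------------------------------------
    def write(self, outdir) -> None:
        """Write counts (Matrix Market), gene/cell lists and annotations as text."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(self.counts.T))  # genes x cells, 10x style
        pd.Series(self.genes).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
        pd.Series(self.obs.index).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
        ann = self.obs.reset_index(names="cell_id")
        ann.to_csv(outdir / "annotations.tsv", sep="\t", index=False)


def log_normalize(counts, scale: float = DEFAULT_SCALE):
    """Library-size normalize to ``scale`` counts per cell, then log1p.

    Zeros map to zeros and doubling all counts of a cell leaves its values
    unchanged.  Raises on cells with zero library size.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if sp.issparse(counts):
        counts = counts.tocsr().astype(np.float64)
        lib = np.asarray(counts.sum(axis=1)).ravel()
        _check_libsize(lib)
        out = counts.copy()
        out.data = out.data * np.repeat(scale / lib, np.diff(out.indptr))
        out.data = np.log1p(out.data)
        return out
    counts = np.asarray(counts, dtype=np.float64)
    lib = counts.sum(axis=1)
    _check_libsize(lib)
    return np.log1p(counts / lib[:, None] * scale)


def _check_libsize(lib: np.ndarray) -> None:
    bad = np.flatnonzero(lib <= 0)
    if bad.size:
        raise ValueError(f"cells with zero library size: {bad[:10].tolist()}")


def compute_cdr(counts) -> np.ndarray:
    """Cellular detection rate: fraction of genes with count > 0, per cell."""
    if sp.issparse(counts):
        det = np.asarray((counts > 0).sum(axis=1)).ravel()
    else:
        det = (np.asarray(counts) > 0).sum(axis=1)
    return det / counts.shape[1]


def read_expression(matrix_path, genes_path=None, cells_path=None,
                    annotations_path=None, scale: float = DEFAULT_SCALE) -> ExpressionDataset:
    """Read counts from Matrix Market (+ features/barcodes lists) or dense CSV,
    join per-cell annotations, compute CDR and log-normalized expression.

    Matrix Market orientation is auto-detected from the gene/cell list lengths.
    Cells lacking an annotation row are dropped with a logged count. A dense CSV
    must have cell ids as its index and gene names as columns.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".csv":
        dense = pd.read_csv(matrix_path, index_col=0)
        counts = sp.csr_matrix(dense.to_numpy(dtype=np.float64))
        genes = list(dense.columns)
        cells = [str(c) for c in dense.index]
    else:
        mat = scipy.io.mmread(str(matrix_path)).tocsr()
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str).tolist()
        if mat.shape == (len(genes), len(cells)):
            mat = mat.T.tocsr()
        elif mat.shape != (len(cells), len(genes)):
            raise ValueError(
                f"matrix shape {mat.shape} matches neither (cells={len(cells)}, "
                f"genes={len(genes)}) nor its transpose"
            )
        counts = mat

    if annotations_path is None:
        obs = pd.DataFrame({"cell_id": cells, "cell_type": "unknown", "condition": "unknown"})
    else:
        obs = pd.read_csv(annotations_path, sep="\t", dtype=str)
        missing = [c for c in REQUIRED_ANNOTATIONS if c not in obs.columns]
        if missing:
            raise ValueError(f"annotation table missing required columns: {missing}")
    obs = obs.set_index("cell_id")
    keep = [i for i, c in enumerate(cells) if c in obs.index]
    n_dropped = len(cells) - len(keep)
    if n_dropped:
        logger.warning("dropping %d cells lacking annotations", n_dropped)
    counts = counts[keep]
    obs = obs.loc[[cells[i] for i in keep]]
    return ExpressionDataset.from_counts(counts, genes, obs.reset_index(), scale=scale)


def append_genes(ds: ExpressionDataset, names, count_cols: np.ndarray,
                 lognorm_cols: np.ndarray) -> ExpressionDataset:
    """Return a dataset with extra pseudo-gene columns appended (counts and
    lognorm supplied directly; CDR and existing columns are untouched)."""
    counts = sp.hstack([ds.counts, sp.csr_matrix(np.atleast_2d(count_cols))], format="csr")
    lognorm = sp.hstack([sp.csr_matrix(ds.lognorm), sp.csr_matrix(np.atleast_2d(lognorm_cols))], format="csr")
    var = pd.DataFrame(index=pd.Index(list(ds.genes) + list(names), name="gene"))
    adata = ad.AnnData(X=lognorm, obs=ds.obs.copy(), var=var)
    adata.layers["counts"] = counts
    adata.uns.update(ds.adata.uns)
    return ExpressionDataset(adata)


def add_averaged_genes(ds: ExpressionDataset, averaged: dict) -> ExpressionDataset:
    """Materialize ortholog-averaged pseudo-genes.

    ``averaged`` maps pseudo-gene name -> list of source genes; the pseudo-gene's
    log-normalized expression is the arithmetic mean of the sources' log-normalized
    values (counts column: mean of counts, for bookkeeping only).
    """
    names, ccols, lcols = [], [], []
    for name, sources in averaged.items():
        present = [g for g in sources if g in ds.genes]
        if not present:
            logger.warning("averaged gene %s: no source genes present; skipped", name)
            continue
        idx = [ds.gene_index(g) for g in present]
        c = np.asarray(ds.counts[:, idx].todense()) if sp.issparse(ds.counts) else ds.counts[:, idx]
        l = np.asarray(ds.lognorm[:, idx].todense()) if sp.issparse(ds.lognorm) else ds.lognorm[:, idx]
        names.append(name)
        ccols.append(c.mean(axis=1))
        lcols.append(l.mean(axis=1))
    if not names:
        return ds
    return append_genes(ds, names, np.column_stack(ccols), np.column_stack(lcols))
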
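"""Count-matrix I/O, quality filtering and normalization.

The pipeline applied to a merged CTC/PBMC count matrix is fixed:

    merge -> filter_cells -> filter_genes -> median_normalize -> log1p_transform

Cells must express a minimum fraction of genes (default 10 %, boundary
inclusive: a cell at exactly the threshold is retained); genes must reach a
minimum count in a minimum number of cells (default count >= 5 in >= 10
cells).  Library depths are standardized by median normalization — each cell
is scaled so that its total equals the median library size — and expression
is log-transformed with a pseudo-count of 1.

Matrices are held as :class:`anndata.AnnData` with cells as observations and
genes as variables.  Raw counts are integers; provenance flags
(``normalized``, ``logged``) are kept in ``adata.uns`` and guard against
double transformation.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class PreprocessError(ValueError):
    """Raised for invalid matrices or out-of-order pipeline steps."""


# ---------------------------------------------------------------------------
# helpers


def _dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense())
    return np.asarray(X)


def _check_unique(names: Sequence[str], kind: str) -> None:
    s = pd.Index(names)
    if s.has_duplicates:
        dup = s[s.duplicated()].unique().tolist()
        raise PreprocessError(f"duplicate {kind} identifier(s): {dup[:5]}")


def make_count_matrix(
    counts, genes: Sequence[str], cells: Sequence[str]
) -> ad.AnnData:
    """Assemble a raw count AnnData (cells × genes) from a gene-by-cell array."""
    _check_unique(genes, "gene")
    _check_unique(cells, "cell")
    X = counts.T if sp.issparse(counts) else np.asarray(counts).T
    if sp.issparse(X):
        neg = X.min() < 0
    else:
        neg = (X < 0).any()
    if neg:
        raise PreprocessError("counts must be non-negative")
    adata = ad.AnnData(
        X=sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X),
        obs=pd.DataFrame(index=pd.Index(cells, name="cell")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.uns["normalized"] = False
    adata.uns["logged"] = False
    return adata


# ---------------------------------------------------------------------------
# merging


def merge_on_common_genes(
    matrices: Sequence[ad.AnnData], dataset_ids: Iterable[str] | None = None
) -> ad.AnnData:
    """Merge count matrices on the intersection of their gene sets.

    The cell set is the union of all inputs; counts are preserved.  Cell
    identifiers colliding across inputs are disambiguated by prefixing with
    the dataset id.
    """
    matrices = list(matrices)
    if len(matrices) < 2:
        raise PreprocessError("merge requires at least two matrices")
    ids = list(dataset_ids) if dataset_ids is not None else [
        f"d{i}" for i in range(len(matrices))
    ]
    if len(ids) != len(matrices):
        raise PreprocessError("dataset_ids length must match matrices")

    common = matrices[0].var_names
    for m in matrices[1:]:
        common = common.intersection(m.var_names)
    if len(common) == 0:
        raise PreprocessError("no genes common to all matrices; cannot merge")
    common = pd.Index(sorted(common))

    all_cells = pd.Index(np.concatenate([m.obs_names for m in matrices]))
    prefix = all_cells.has_duplicates

    blocks, cells, datasets = [], [], []
    for mid, m in zip(ids, matrices):
        sub = m[:, common]
        blocks.append(_dense(sub.X))
        names = [f"{mid}:{c}" for c in m.obs_names] if prefix else list(m.obs_names)
        cells.extend(names)
        datasets.extend([mid] * m.n_obs)
    merged = make_count_matrix(np.vstack(blocks).T, list(common), cells)
    merged.obs["dataset"] = datasets
    # carry over per-cell annotations shared by all inputs
    shared = set.intersection(*(set(m.obs.columns) for m in matrices)) if matrices else set()
    for col in sorted(shared):
        merged.obs[col] = np.concatenate([np.asarray(m.obs[col]) for m in matrices])
    return merged


# ---------------------------------------------------------------------------
# filtering


def filter_cells(adata: ad.AnnData, min_expressed_fraction: float = 0.10) -> ad.AnnData:
    """Drop poor-quality cells expressing fewer than the given fraction of genes.

    A cell at exactly the threshold is retained ("fewer than" read literally).
    """
    if not 0.0 <= min_expressed_fraction <= 1.0:
        raise PreprocessError("min_expressed_fraction must be in [0, 1]")
    X = adata.X
    nnz = np.asarray((X > 0).sum(axis=1)).ravel()
    keep = nnz / adata.n_vars >= min_expressed_fraction
    return adata[keep].copy()


def filter_genes(adata: ad.AnnData, min_count: int = 5, min_cells: int = 10) -> ad.AnnData:
    """Keep genes with count >= min_count in at least min_cells cells."""
    if min_count < 0:
        raise PreprocessError("min_count must be >= 0")
    if min_cells < 1:
        raise PreprocessError("min_cells must be >= 1")
    X = adata.X
    n_high = np.asarray((X >= min_count).sum(axis=0)).ravel()
    keep = n_high >= min_cells
    return adata[:, keep].copy()


# ---------------------------------------------------------------------------
# normalization


def median_normalize(adata: ad.AnnData) -> ad.AnnData:
    """Scale each cell by (median library size) / (its library size).

    After normalization every cell's total equals the median of the input
    library sizes (standard midpoint median for an even cell count).
    """
    if adata.uns.get("normalized", False):
        return adata.copy()
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if (totals <= 0).any():
        bad = list(adata.obs_names[totals <= 0][:5])
        raise PreprocessError(
            f"cells with zero total count (e.g. {bad}); run filter_cells first"
        )
    med = float(np.median(totals))
    out = adata.copy()
    scale = med / totals
    if sp.issparse(out.X):
        out.X = sp.diags(scale) @ out.X.tocsr()
    else:
        out.X = np.asarray(out.X, dtype=float) * scale[:, None]
    out.uns["normalized"] = True
    return out


def log1p_transform(adata: ad.AnnData, base: float | None = None) -> ad.AnnData:
    """log(x + 1) transform (natural log by default)."""
    if adata.uns.get("logged", False):
        raise PreprocessError("matrix is already log-transformed")
    out = adata.copy()
    X = _dense(out.X)
    if (X < 0).any():
        raise PreprocessError("negative values; log1p requires non-negative input")
    L = np.log1p(X)
    if base is not None:
        L /= np.log(base)
    out.X = L
    out.uns["logged"] = True
    out.uns["log_base"] = "e" if base is None else base
    return out


def preprocess(
    adata: ad.AnnData,
    min_expressed_fraction: float = 0.10,
    min_count: int = 5,
    min_cells: int = 10,
    log_base: float | None = None,
) -> ad.AnnData:
    """Run the fixed pipeline: filter cells, filter genes, normalize, log1p."""
    out = filter_cells(adata, min_expressed_fraction)
    out = filter_genes(out, min_count, min_cells)
    out = median_normalize(out)
    return log1p_transform(out, base=log_base)


# ---------------------------------------------------------------------------
# I/O


def write_matrix(adata: ad.AnnData, path: str, fmt: str = "mtx") -> None:
    """Write a matrix as MTX + genes.tsv/cells.tsv sidecars or a dense TSV.

    ``fmt="mtx"``: *path* is a directory receiving ``matrix.mtx``,
    ``genes.tsv`` and ``cells.tsv``.  ``fmt="tsv"``: *path* is a file with
    genes as rows and cells as columns.
    """
    if fmt == "mtx":
        os.makedirs(path, exist_ok=True)
        X = adata.X.T if sp.issparse(adata.X) else sp.csc_matrix(np.asarray(adata.X).T)
        scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), X)
        pd.Series(adata.var_names).to_csv(
            os.path.join(path, "genes.tsv"), sep="\t", index=False, header=False
        )
        pd.Series(adata.obs_names).to_csv(
            os.path.join(path, "cells.tsv"), sep="\t", index=False, header=False
        )
    elif fmt == "tsv":
        df = pd.DataFrame(_dense(adata.X).T, index=adata.var_names, columns=adata.obs_names)
        df.to_csv(path, sep="\t", index_label="gene")
    else:
        raise PreprocessError(f"unknown format {fmt!r} (use 'mtx' or 'tsv')")


def read_matrix(path: str, fmt: str = "mtx", integer: bool = True) -> ad.AnnData:
    """Read a matrix written by :func:`write_matrix` (gene-by-cell on disk)."""
    if fmt == "mtx":
        try:
            X = scipy.io.mmread(os.path.join(path, "matrix.mtx"))
        except ValueError as e:
            raise PreprocessError(f"malformed MTX file: {e}") from e
        genes = pd.read_csv(
            os.path.join(path, "genes.tsv"), sep="\t", header=None
        )[0].astype(str).tolist()
        cells = pd.read_csv(
            os.path.join(path, "cells.tsv"), sep="\t", header=None
        )[0].astype(str).tolist()
        X = sp.csr_matrix(X)
        if X.shape != (len(genes), len(cells)):
            raise PreprocessError(
                f"dimension mismatch: matrix {X.shape} vs {len(genes)} genes, "
                f"{len(cells)} cells"
            )
        vals = X.data
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise PreprocessError(f"duplicated gene row(s): {dup[:5]}")
        genes = df.index.astype(str).tolist()
        cells = df.columns.astype(str).tolist()
        X = df.to_numpy(dtype=float)
        vals = X.ravel()
    else:
        raise PreprocessError(f"unknown format {fmt!r} (use 'mtx' or 'tsv')")
    if integer and not np.allclose(vals, np.round(vals)):
        raise PreprocessError("non-integer values where integer counts required")
    return make_count_matrix(X, genes, cells)
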
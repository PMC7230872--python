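"""E:M phenotype scoring and continuum ordering of single-cell transcriptomes.

Each cell's marker-gene expression vector is Z-transformed within the cell
(population standard deviation), and a phenotype score is the mean Z over
that phenotype's marker set:

    Z_phenotype = sum_{i in markers} Z_i / |markers|

The per-cell E:M score compares the epithelial and mesenchymal phenotype
scores.  Two modes are available:

* ``ratio`` — the literal quotient ``z_e / z_m``, with a guard that flags
  near-zero denominators as non-finite;
* ``difference`` — ``z_e - z_m``, the default for *ordering* cells.

Because the two phenotype scores are strongly anti-correlated across real
and simulated CTCs, the quotient is sign-degenerate along the continuum
(both strongly epithelial and strongly mesenchymal cells yield negative
ratios, and the denominator crosses zero mid-continuum), so it cannot
induce a monotone ordering.  The difference preserves the intended sign
convention — a cell enriched with epithelial markers receives a large
positive score and sits at the epithelial pole (first) of the ordering —
and is used as the default ordering key; the literal ratio remains
available on every score table.

Also provided: moving-average marker trends along the ordered continuum,
agglomerative two-group stratification, phenotype anti-correlation, and the
per-study PD-L1 (CD274) versus HLA class I correlation table.
"""

from __future__ import annotations

from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import AgglomerativeClustering

from .preprocess import _dense
from .synthetic import MarkerPanel

__all__ = [
    "zscore_within_cell",
    "phenotype_score",
    "em_score",
    "score_cells",
    "order_continuum",
    "moving_average_trend",
    "phenotype_anticorrelation",
    "cluster_em",
    "checkpoint_correlation",
]

RATIO_GUARD = 1e-8


class ScoringError(ValueError):
    pass


def zscore_within_cell(x: np.ndarray, cell_id: str = "?") -> np.ndarray:
    """Standardize a cell's marker-expression vector to mean 0, SD 1.

    Uses the population (divide-by-n) standard deviation.  Scale-invariant:
    multiplying the vector by a positive constant leaves the output
    unchanged up to the shared mean shift.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ScoringError(f"cell {cell_id}: need >= 2 marker genes")
    sd = x.std()  # population SD
    if sd == 0 or not np.isfinite(sd):
        raise ScoringError(f"cell {cell_id}: zero variance across marker genes")
    return (x - x.mean()) / sd


def phenotype_score(z: pd.Series | np.ndarray, markers: Sequence[str]) -> float:
    """Mean Z over a phenotype's marker set.

    ``z`` is a Series indexed by gene (or an array when ``markers`` indexes
    positions).
    """
    markers = list(markers)
    if len(markers) == 0:
        raise ScoringError("empty marker set")
    if isinstance(z, pd.Series):
        missing = [m for m in markers if m not in z.index]
        if missing:
            raise ScoringError(f"markers absent from z vector: {missing[:5]}")
        vals = z.loc[markers].to_numpy(dtype=float)
    else:
        vals = np.asarray(z, dtype=float)[np.asarray(markers)]
    return float(vals.mean())


def em_score(z_e: float, z_m: float, mode: str = "ratio") -> float:
    """E:M score from the two phenotype scores.

    In ratio mode, denominators within ``RATIO_GUARD`` of zero yield NaN
    (flagged, excluded from ordering by callers).
    """
    if mode == "ratio":
        if abs(z_m) < RATIO_GUARD:
            return float("nan")
        return z_e / z_m
    if mode == "difference":
        return z_e - z_m
    raise ScoringError(f"unknown mode {mode!r}")


def _marker_z(adata: ad.AnnData, genes: Sequence[str], axis: str) -> pd.DataFrame:
    X = _dense(adata[:, list(genes)].X).astype(float)
    if axis == "cell":
        mean = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        bad = (sd == 0).ravel()
        if bad.any():
            raise ScoringError(
                f"zero marker variance in cell(s): {list(adata.obs_names[bad][:5])}"
            )
    elif axis == "gene":
        mean = X.mean(axis=0, keepdims=True)
        sd = X.std(axis=0, keepdims=True)
        if (sd == 0).any():
            bad = [g for g, s in zip(genes, sd.ravel()) if s == 0]
            raise ScoringError(f"zero variance in gene(s): {bad[:5]}")
    else:
        raise ScoringError("axis must be 'cell' or 'gene'")
    return pd.DataFrame((X - mean) / sd, index=adata.obs_names, columns=list(genes))


def score_cells(
    adata: ad.AnnData,
    panel: MarkerPanel,
    axis: str = "cell",
    order_mode: str = "difference",
) -> pd.DataFrame:
    """Phenotype scores and continuum rank for every cell.

    Expects a normalized, log-transformed matrix.  The Z-transform runs over
    the union of the panel's epithelial, mesenchymal and CSC markers present
    in the matrix (``axis="cell"``: within each cell, the verbatim default;
    ``axis="gene"``: per gene across cells).  Returns a DataFrame with
    columns ``z_epithelial``, ``z_mesenchymal``, ``em_ratio``, ``em_diff``
    and ``rank`` (0 = epithelial pole, ordered by ``order_mode``).
    """
    present = [g for g in (*panel.epithelial, *panel.mesenchymal, *panel.csc)
               if g in adata.var_names]
    epi = [g for g in panel.epithelial if g in adata.var_names]
    mes = [g for g in panel.mesenchymal if g in adata.var_names]
    if not epi or not mes:
        raise ScoringError("panel's epithelial and mesenchymal sets must be "
                           "represented in the matrix")
    Z = _marker_z(adata, present, axis)
    z_e = Z[epi].mean(axis=1)
    z_m = Z[mes].mean(axis=1)
    ratio = np.where(np.abs(z_m) < RATIO_GUARD, np.nan, z_e / z_m)
    scores = pd.DataFrame(
        {
            "z_epithelial": z_e,
            "z_mesenchymal": z_m,
            "em_ratio": ratio,
            "em_diff": z_e - z_m,
        }
    )
    scores.index.name = "cell_id"
    ordered = order_continuum(scores, mode=order_mode)
    scores["rank"] = pd.Series(np.arange(len(ordered)), index=ordered).reindex(
        scores.index
    )
    return scores


def order_continuum(scores: pd.DataFrame, mode: str = "difference") -> list:
    """Order cells along the E→M continuum (epithelial pole first).

    Sorts by the requested E:M score, descending; ties (and only ties) break
    lexicographically by cell identifier.  Cells with a non-finite score
    (ratio-mode guard) are excluded, with the count recorded via logging.
    """
    col = {"ratio": "em_ratio", "difference": "em_diff"}.get(mode)
    if col is None:
        raise ScoringError(f"unknown mode {mode!r}")
    s = scores[col]
    finite = s[np.isfinite(s)]
    n_excl = len(s) - len(finite)
    if n_excl:
        import logging

        logging.getLogger(__name__).info(
            "order_continuum: excluded %d cell(s) with non-finite %s", n_excl, col
        )
    df = finite.to_frame("score")
    df["cell"] = df.index.astype(str)
    df = df.sort_values(["score", "cell"], ascending=[False, True])
    return list(df.index)


def moving_average_trend(
    adata: ad.AnnData,
    ordered_cells: Sequence[str],
    genes: Sequence[str],
    window: int | None = None,
) -> pd.DataFrame:
    """Centered moving average of expression along the ordered continuum.

    Windows shrink at the edges so the output has one value per cell.  The
    default window is ``max(5, ceil(0.1 * n))``.
    """
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise ScoringError(f"genes absent from matrix: {missing}")
    n = len(ordered_cells)
    if window is None:
        window = max(5, int(np.ceil(0.1 * n)))
    if not 1 <= window <= n:
        raise ScoringError(f"window must be in [1, {n}]")
    sub = adata[list(ordered_cells), list(genes)]
    df = pd.DataFrame(_dense(sub.X), index=list(ordered_cells), columns=list(genes))
    return df.rolling(window, center=True, min_periods=1).mean()


def phenotype_anticorrelation(
    scores: pd.DataFrame, method: str = "spearman"
) -> float:
    """Correlation between the epithelial and mesenchymal phenotype scores."""
    z_e, z_m = scores["z_epithelial"], scores["z_mesenchymal"]
    ok = np.isfinite(z_e) & np.isfinite(z_m)
    if ok.sum() < 3:
        raise ScoringError("need >= 3 cells with finite phenotype scores")
    if method == "spearman":
        rho = scipy.stats.spearmanr(z_e[ok], z_m[ok]).statistic
    elif method == "pearson":
        rho = scipy.stats.pearsonr(z_e[ok], z_m[ok]).statistic
    else:
        raise ScoringError(f"unknown method {method!r}")
    return float(rho)


def cluster_em(
    adata: ad.AnnData,
    genes: Sequence[str] | None = None,
    k: int = 2,
    linkage: str = "ward",
) -> pd.Series:
    """Agglomerative hierarchical stratification of cells into k groups.

    Ward linkage on Euclidean distances over (normalized) marker expression;
    with k=2 this approximates the binarized epithelial/mesenchymal split.
    """
    if adata.n_obs < k:
        raise ScoringError(f"need >= {k} cells for k={k} clusters")
    X = _dense(adata[:, list(genes)].X if genes is not None else adata.X)
    if k == 1:
        labels = np.zeros(adata.n_obs, dtype=int)
    else:
        labels = AgglomerativeClustering(n_clusters=k, linkage=linkage).fit_predict(X)
    return pd.Series(labels, index=adata.obs_names, name="em_cluster")


def checkpoint_correlation(
    adata: ad.AnnData,
    study_col: str = "batch",
    gene_a: str = "CD274",
    genes_b: Sequence[str] = ("HLA-A", "HLA-B", "HLA-C"),
    method: str = "spearman",
) -> pd.DataFrame:
    """Per-study correlation between PD-L1 and mean HLA class I expression.

    Studies where either side has zero variance (or fewer than 3 cells, or a
    missing gene) are reported as NA with the reason.  Pass a single-gene
    ``genes_b`` (e.g. ``["HLA-B"]``) for a one-axis variant.
    """
    if gene_a not in adata.var_names:
        raise ScoringError(f"{gene_a} absent from matrix")
    avail_b = [g for g in genes_b if g in adata.var_names]
    if not avail_b:
        raise ScoringError(f"none of {list(genes_b)} present in matrix")
    rows = []
    for study, idx in adata.obs.groupby(study_col, observed=True).groups.items():
        sub = adata[idx]
        a = _dense(sub[:, [gene_a]].X).ravel()
        b = _dense(sub[:, avail_b].X).mean(axis=1)
        row = {"study": study, "n": len(idx), "genes_b": ",".join(avail_b)}
        if len(idx) < 3:
            row.update(rho=np.nan, note="fewer than 3 cells")
        elif a.std() == 0 or b.std() == 0:
            row.update(rho=np.nan, note="zero variance")
        else:
            if method == "spearman":
                rho = scipy.stats.spearmanr(a, b).statistic
            else:
                rho = scipy.stats.pearsonr(a, b).statistic
            row.update(rho=float(rho), note="")
        rows.append(row)
    return pd.DataFrame(rows).set_index("study")


def plot_trends(trends: pd.DataFrame, ax=None, title: str | None = None):
    """Plot moving-average marker trends along the continuum."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for gene in trends.columns:
        ax.plot(np.arange(len(trends)), trends[gene], label=gene)
    ax.set_xlabel("continuum position (E pole → M pole)")
    ax.set_ylabel("smoothed log(expression + 1)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
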
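"""Synthetic CTC/PBMC cohort generator with known ground truth.

Emulates the statistical structure of a multi-study circulating-tumor-cell
(CTC) versus peripheral-blood-mononuclear-cell (PBMC) compendium:

* two cell classes drawn from several batches (studies);
* CTCs placed on a latent epithelial→mesenchymal (E→M) continuum
  ``t ∈ [0, 1]`` along which epithelial-marker expression decays and
  mesenchymal-marker expression rises;
* cancer-stem-cell markers split into a CD44-like arm that emerges late on
  the continuum and a CD24-like arm that is lost late;
* leukocyte markers (PTPRC, ...) high only in PBMCs;
* an immune-checkpoint pattern (PD-L1/CD274 rising, HLA class I falling
  along the continuum in CTCs) and a set of CTC-upregulated surface-protein
  genes (ITGB5, TACSTD2, SLC39A6);
* library-size variation, negative-binomial overdispersion with gene-level
  dispersion, Bernoulli dropout, and multiplicative log-normal batch
  effects.

Counts are sampled on the relative-abundance scale: per-gene log2 mean
profiles are converted to cell-wise proportions, scaled by a uniform random
library size and drawn from a negative binomial, then thinned by dropout.
Identical configurations (including the seed) give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .preprocess import make_count_matrix

__all__ = [
    "MarkerPanel",
    "SynthConfig",
    "generate_marker_panel",
    "simulate_cohort",
]


class SynthConfigError(ValueError):
    """Invalid generator configuration."""


# canonical marker names; panels larger than these lists are padded with
# synthetic identifiers (EPI_17, ...)
EPITHELIAL_MARKERS = (
    "EPCAM", "KRT8", "KRT18", "KRT19", "CDH1", "CLDN3", "CLDN4", "CLDN7",
    "DSP", "OCLN", "MUC1", "ESRP1", "ESRP2", "KRT7", "KRT5", "CDH3",
)
MESENCHYMAL_MARKERS = (
    "VIM", "ZEB1", "ZEB2", "SNAI1", "SNAI2", "TWIST1", "TWIST2", "FN1",
    "CDH2", "FOXC2", "MMP2", "MMP9", "SPARC", "COL1A1", "COL1A2", "COL3A1",
    "COL5A1", "ACTA2", "TAGLN", "S100A4", "POSTN", "THBS1", "VCAN", "TNC",
    "SERPINE1", "TGFB1", "TGFBI", "LGALS1", "EMP3", "AXL", "MSN", "LAMC1",
    "PDGFRB", "NID1", "BGN", "LOX", "FBN1", "CALD1", "GREM1",
)
CSC_UP_MARKERS = (  # CD44-like: emerge late on the continuum
    "CD44", "ALDH1A1", "PROM1", "KIT", "ABCG2", "SOX2", "NANOG", "POU5F1",
    "KLF4", "MYC", "BMI1", "NOTCH1", "CD47",
)
CSC_DOWN_MARKERS = (  # CD24-like: lost late on the continuum
    "CD24", "GATA3", "ELF3", "RAB25", "FOXA1", "KRT15", "SDC1", "DSC2",
    "JUP", "PKP3", "GRHL3", "TFAP2A", "EHF",
)
LEUKOCYTE_MARKERS = (
    "PTPRC", "CD3E", "CD3D", "CD19", "MS4A1", "NKG7", "LYZ", "CD14",
    "FCGR3A", "IL7R",
)
CHECKPOINT_GENE = "CD274"  # PD-L1
HLA_GENES = ("HLA-A", "HLA-B", "HLA-C")
SURFACE_GENES = ("ITGB5", "TACSTD2", "SLC39A6")

CANCER_TYPES = ("breast", "prostate", "lung", "melanoma", "pancreas")
CANCER_TYPE_PROBS = (0.70, 0.10, 0.08, 0.06, 0.06)


@dataclass(frozen=True)
class MarkerPanel:
    """Curated marker gene lists, pairwise disjoint.

    ``genes`` is the full ordered gene universe (markers scattered among
    unlabeled background genes); it may be empty when a panel is built from
    lists alone.
    """

    epithelial: tuple = ()
    mesenchymal: tuple = ()
    csc_up: tuple = ()
    csc_down: tuple = ()
    leukocyte: tuple = ()
    genes: tuple = ()

    @property
    def csc(self) -> tuple:
        return self.csc_up + self.csc_down

    @property
    def background(self) -> tuple:
        marked = set(self.epithelial) | set(self.mesenchymal) | set(self.csc) | set(
            self.leukocyte
        )
        return tuple(g for g in self.genes if g not in marked)

    def __post_init__(self):
        sets = [set(self.epithelial), set(self.mesenchymal), set(self.csc_up),
                set(self.csc_down), set(self.leukocyte)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise SynthConfigError("marker classes must be pairwise disjoint")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in ("epithelial", "mesenchymal", "csc_up", "csc_down", "leukocyte"):
            rows += [(g, cls) for g in getattr(self, cls)]
        return pd.DataFrame(rows, columns=["gene", "class"])

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "MarkerPanel":
        df = pd.read_csv(path, sep="\t")
        def pick(c):
            return tuple(df.loc[df["class"] == c, "gene"].astype(str))
        csc = pick("csc")
        csc_up, csc_down = pick("csc_up"), pick("csc_down")
        if csc and not (csc_up or csc_down):  # undirected csc: split evenly
            h = (len(csc) + 1) // 2
            csc_up, csc_down = csc[:h], csc[h:]
        return cls(
            epithelial=pick("epithelial"),
            mesenchymal=pick("mesenchymal"),
            csc_up=csc_up,
            csc_down=csc_down,
            leukocyte=pick("leukocyte"),
        )


def _named(canon: Sequence[str], n: int, prefix: str) -> tuple:
    names = list(canon[:n])
    names += [f"{prefix}_{i:02d}" for i in range(len(names), n)]
    return tuple(names)


def generate_marker_panel(
    panel_sizes: Sequence[int], n_genes: int, seed: int = 0
) -> MarkerPanel:
    """Build a marker panel of (n_epithelial, n_mesenchymal, n_csc, n_leukocyte)
    genes inside a universe of ``n_genes`` genes.

    Marker positions are shuffled deterministically through the universe;
    remaining genes are unlabeled background.  The CSC class is split into a
    CD44-like (late-up) and a CD24-like (late-down) arm.
    """
    if len(panel_sizes) != 4:
        raise SynthConfigError("panel_sizes must be (n_e, n_m, n_csc, n_leu)")
    n_e, n_m, n_c, n_l = (int(x) for x in panel_sizes)
    if min(n_e, n_m, n_c, n_l) < 0:
        raise SynthConfigError("panel sizes must be non-negative")
    if n_e + n_m + n_c + n_l > n_genes:
        raise SynthConfigError(
            f"panel sizes sum to {n_e + n_m + n_c + n_l} > n_genes={n_genes}"
        )
    n_cu = (n_c + 1) // 2
    epi = _named(EPITHELIAL_MARKERS, n_e, "EPI")
    mes = _named(MESENCHYMAL_MARKERS, n_m, "MES")
    cup = _named(CSC_UP_MARKERS, n_cu, "CSCUP")
    cdn = _named(CSC_DOWN_MARKERS, n_c - n_cu, "CSCDN")
    leu = _named(LEUKOCYTE_MARKERS, n_l, "LEU")

    marked = list(epi + mes + cup + cdn + leu)
    special = [g for g in (CHECKPOINT_GENE, *HLA_GENES, *SURFACE_GENES)
               if g not in marked]
    n_bg = n_genes - len(marked)
    bg = special[:n_bg] + [f"G{i:05d}" for i in range(n_bg - min(len(special), n_bg))]
    genes = np.array(marked + bg, dtype=object)
    rng = np.random.default_rng(seed)
    rng.shuffle(genes)
    return MarkerPanel(
        epithelial=epi, mesenchymal=mes, csc_up=cup, csc_down=cdn,
        leukocyte=leu, genes=tuple(genes),
    )


@dataclass
class SynthConfig:
    """Cohort-level generator settings.

    Defaults emulate a modest three-study compendium: 300 CTCs against a
    three-fold PBMC background, an eight-fold (3 log2 units) marker gradient
    across the continuum, 30 % dropout and mild multiplicative batch effects.
    """

    n_ctc: int = 300
    n_pbmc: int = 900
    n_batches: int = 3
    n_genes: int = 2000
    panel_sizes: tuple = (16, 39, 26, 10)
    continuum_shape: str = "uniform"  # or "bimodal"
    effect_size: float = 3.0  # log2 span of marker gradients along t
    dropout_rate: float = 0.30
    batch_strength: float = 0.25  # sd of log-normal gene×batch factors
    library_size_range: tuple = (20_000, 60_000)
    low_quality_fraction: float = 0.0  # cells planted below the 10 % QC bar
    plant_checkpoint_pattern: bool = True
    plant_surface_markers: bool = True
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_ctc, self.n_pbmc, self.n_genes) < 1 or self.n_batches < 1:
            raise SynthConfigError("n_ctc, n_pbmc, n_genes, n_batches must be >= 1")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise SynthConfigError("dropout_rate must be in [0, 1]")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise SynthConfigError("library_size_range must satisfy 0 < min <= max")
        if self.continuum_shape not in ("uniform", "bimodal"):
            raise SynthConfigError("continuum_shape must be 'uniform' or 'bimodal'")
        if not 0.0 <= self.low_quality_fraction <= 1.0:
            raise SynthConfigError("low_quality_fraction must be in [0, 1]")
        if self.effect_size < 0 or self.batch_strength < 0:
            raise SynthConfigError("effect_size and batch_strength must be >= 0")
        if sum(self.panel_sizes) > self.n_genes:
            raise SynthConfigError("panel sizes exceed n_genes")

    def to_dict(self) -> dict:
        return asdict(self)


# log2 expression levels used by the mean model
_BG_MEAN, _BG_SD = 3.5, 1.2   # unlabeled background genes
_MARKER_LOW = 2.0             # marker level at its "off" end of the gradient
_OFF_CLASS = 1.0              # tumor markers in PBMCs / leukocyte markers in CTCs
_HLA_PBMC = 5.0               # HLA class I is high in immune cells
_SURFACE_LOG2FC = 2.5         # planted CTC-vs-PBMC surface-marker effect


def _latent_t(rng: np.random.Generator, n: int, shape: str) -> np.ndarray:
    if shape == "uniform":
        return rng.uniform(0.0, 1.0, n)
    # bimodal: cells pile up near the epithelial and mesenchymal poles
    pole = rng.random(n) < 0.5
    t = np.where(pole, rng.beta(2.0, 8.0, n), rng.beta(8.0, 2.0, n))
    return t


def _csc_ramp(t: np.ndarray) -> np.ndarray:
    """Late-emergence ramp: 0 until t≈0.6, then rising to 1 at the M pole."""
    return np.clip((t - 0.6) / 0.35, 0.0, 1.0)


def simulate_cohort(
    config: SynthConfig, panel: MarkerPanel | None = None
) -> ad.AnnData:
    """Generate a CTC/PBMC cohort with ground truth in ``.obs``.

    Returns raw counts (cells × genes) with per-cell annotation columns
    ``class_label``, ``batch``, ``cancer_type`` and the latent continuum
    position ``latent_t`` (NaN for PBMCs).
    """
    config.validate()
    if panel is None:
        panel = generate_marker_panel(config.panel_sizes, config.n_genes, config.seed)
    genes = list(panel.genes)
    if len(genes) != config.n_genes:
        raise SynthConfigError(
            f"panel universe has {len(genes)} genes, config expects {config.n_genes}"
        )
    gi = {g: k for k, g in enumerate(genes)}
    rng = np.random.default_rng(config.seed)

    n_cells = config.n_ctc + config.n_pbmc
    is_ctc = np.zeros(n_cells, bool)
    is_ctc[: config.n_ctc] = True
    t = np.full(n_cells, np.nan)
    t[is_ctc] = _latent_t(rng, config.n_ctc, config.continuum_shape)
    batch = rng.integers(0, config.n_batches, n_cells)
    cancer = np.where(
        is_ctc,
        rng.choice(CANCER_TYPES, n_cells, p=CANCER_TYPE_PROBS),
        "none",
    )

    # log2 mean profile per cell × gene
    base = rng.normal(_BG_MEAN, _BG_SD, config.n_genes)
    mu = np.tile(base, (n_cells, 1))
    eff = config.effect_size
    tc = np.nan_to_num(t)  # 0 for PBMCs; masked below anyway

    def set_cols(gene_names, ctc_level, pbmc_level):
        idx = [gi[g] for g in gene_names if g in gi]
        if not idx:
            return
        mu[np.ix_(is_ctc, idx)] = np.asarray(ctc_level)[is_ctc, None]
        mu[np.ix_(~is_ctc, idx)] = np.asarray(pbmc_level)[~is_ctc, None]

    ones = np.ones(n_cells)
    set_cols(panel.epithelial, _MARKER_LOW + eff * (1 - tc), _OFF_CLASS * ones)
    set_cols(panel.mesenchymal, _MARKER_LOW + eff * tc, _OFF_CLASS * ones)
    ramp = _csc_ramp(tc)
    set_cols(panel.csc_up, _MARKER_LOW + eff * ramp, _OFF_CLASS * ones)
    set_cols(panel.csc_down, _MARKER_LOW + eff * (1 - ramp), _OFF_CLASS * ones)
    set_cols(panel.leukocyte, _OFF_CLASS * ones, (_MARKER_LOW + eff) * ones)
    if config.plant_checkpoint_pattern:
        set_cols([CHECKPOINT_GENE], 1.5 + 0.8 * eff * tc, _OFF_CLASS * ones)
        set_cols(HLA_GENES, 1.5 + 0.8 * eff * (1 - tc), _HLA_PBMC * ones)
    if config.plant_surface_markers:
        set_cols(SURFACE_GENES, (_MARKER_LOW + _SURFACE_LOG2FC) * ones,
                 _MARKER_LOW * ones)

    # batch effects: gene-wise multiplicative log-normal factors per batch
    batch_fac = np.exp(
        rng.normal(0.0, config.batch_strength, (config.n_batches, config.n_genes))
    ) if config.batch_strength > 0 else np.ones((config.n_batches, config.n_genes))

    w = np.exp2(mu) * batch_fac[batch]
    p = w / w.sum(axis=1, keepdims=True)
    lib = rng.integers(
        config.library_size_range[0], config.library_size_range[1] + 1, n_cells
    )
    mean = p * lib[:, None]

    # negative binomial with gene-level dispersion theta_g
    theta = np.exp(rng.normal(np.log(10.0), 0.5, config.n_genes))
    prob = theta / (theta + mean)
    counts = rng.negative_binomial(theta[None, :], prob)

    if config.dropout_rate > 0:
        counts = counts * (rng.random(counts.shape) >= config.dropout_rate)

    planted = np.zeros(n_cells, bool)
    if config.low_quality_fraction > 0:
        n_lq = int(round(config.low_quality_fraction * n_cells))
        lq = rng.choice(n_cells, n_lq, replace=False)
        planted[lq] = True
        for i in lq:
            keep = rng.random(config.n_genes) < 0.05
            counts[i] = counts[i] * keep

    cells = [
        (f"CTC{i:04d}" if is_ctc[i] else f"PBMC{i - config.n_ctc:04d}")
        for i in range(n_cells)
    ]
    adata = make_count_matrix(counts.T, genes, cells)
    adata.obs["class_label"] = pd.Categorical(
        np.where(is_ctc, "CTC", "PBMC"), categories=["CTC", "PBMC"]
    )
    adata.obs["batch"] = pd.Categorical([f"batch{b}" for b in batch])
    adata.obs["cancer_type"] = pd.Categorical(cancer)
    adata.obs["latent_t"] = t
    adata.obs["planted_low_quality"] = planted
    adata.uns["synth_config"] = config.to_dict()
    return adata


def truth_frame(adata: ad.AnnData) -> pd.DataFrame:
    """Ground-truth table (cell_id, class_label, batch, latent_t)."""
    df = adata.obs[["class_label", "batch", "latent_t"]].copy()
    df.index.name = "cell_id"
    return df.reset_index()
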
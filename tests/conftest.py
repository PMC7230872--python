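import numpy as np
import pytest

from ctcemt import preprocess as P
from ctcemt import synthetic as S


@pytest.fixture(scope="session")
def default_cohort():
    """The default three-batch synthetic cohort (seed 42) plus its panel."""
    cfg = S.SynthConfig(seed=42)
    panel = S.generate_marker_panel(cfg.panel_sizes, cfg.n_genes, cfg.seed)
    return S.simulate_cohort(cfg, panel), panel, cfg


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: no dropout, no batch effects (for monotonicity)."""
    cfg = S.SynthConfig(
        n_ctc=200, n_pbmc=200, dropout_rate=0.0, batch_strength=0.0, seed=7
    )
    panel = S.generate_marker_panel(cfg.panel_sizes, cfg.n_genes, cfg.seed)
    return S.simulate_cohort(cfg, panel), panel, cfg


@pytest.fixture()
def toy_filter_matrix():
    """20-gene x 30-cell matrix with planted quality-filter boundary cases.

    Hand-derived outcome under the default filters (cells needing >= 10 %
    expressed genes, then genes needing count >= 5 in >= 10 cells):

    * cells: 27 well-expressed cells, one cell at exactly 2/20 = 10 %
      (retained — boundary inclusive), one at 1/20 (removed), one all-zero
      (removed) -> 28 survivors;
    * genes: g0 has count 5 in exactly 10 surviving cells (retained),
      g1 in 9 (removed), g2 has count 4 everywhere (removed), g3..g19 are
      broadly expressed (retained) -> 18 survivors.
    """
    counts = np.zeros((20, 30), dtype=int)  # gene x cell
    counts[3:20, 0:27] = 6      # good cells express g3..g19
    counts[0, 0:10] = 5         # g0: count 5 in exactly 10 cells
    counts[1, 0:9] = 5          # g1: count 5 in only 9 cells
    counts[2, 0:28] = 4         # g2: below min_count everywhere
    counts[3:20, 27] = 0
    counts[3, 27] = 6           # boundary cell: exactly 2 nonzero genes
    counts[4, 27] = 6
    counts[3, 28] = 7           # poor cell: 1/20 = 5 % expressed
    # cell 29 stays all-zero
    genes = [f"g{i}" for i in range(20)]
    cells = [f"c{i}" for i in range(30)]
    adata = P.make_count_matrix(counts, genes, cells)
    expected = {"n_cells_kept": 28, "n_genes_kept": 18,
                "kept_genes": ["g0"] + [f"g{i}" for i in range(3, 20)]}
    return adata, expected
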
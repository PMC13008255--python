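import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from singist.datamodel import PseudobulkBlocks, SingleCellData
from singist.simulate import SimulationConfig, simulate_exact_shift


def make_blocks(seed: int, n: int = 10, cell_types=("TC", "KC", "DC"), p: int = 8,
                shift: float = 0.0, n_signal: int = 3):
    """Random pseudobulk blocks with an optional class location shift on the
    first ``n_signal`` genes of every block; first half of samples is class 1."""
    rng = np.random.default_rng(seed)
    ids = pd.Index([f"s{i:02d}" for i in range(n)], name="sample_id")
    y = np.array([1] * (n // 2) + [0] * (n - n // 2), dtype=float)
    blocks = {}
    for ct in cell_types:
        X = rng.normal(5.0, 1.0, size=(n, p))
        X[y == 1, :n_signal] += shift
        blocks[ct] = pd.DataFrame(X, index=ids,
                                  columns=[f"{ct}G{j}" for j in range(p)])
    return PseudobulkBlocks(blocks), y


def make_sc_data(seed: int = 0, n_genes: int = 6, samples=("s1", "s2"),
                 cell_types=("A", "B"), cells_per: int = 4, labels=(1, 0)):
    """Tiny annotated single-cell counts object for io/pseudobulk tests."""
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i}" for i in range(n_genes)])
    rows = []
    cols = []
    for sid in samples:
        for ct in cell_types:
            for k in range(cells_per):
                rows.append({"cell_id": f"{sid}_{ct}_{k}", "sample_id": sid,
                             "cell_type": ct})
                cols.append(rng.poisson(3.0, size=n_genes))
    counts = sp.csr_matrix(np.array(cols).T)
    cells = pd.DataFrame(rows).set_index("cell_id")
    y = pd.Series(list(labels), index=pd.Index(samples, name="sample_id"),
                  name="class_label")
    return SingleCellData(counts=counts, genes=genes, cells=cells, samples=y)


@pytest.fixture
def exact_ds():
    return simulate_exact_shift(SimulationConfig(seed=11))


@pytest.fixture
def exact_ds_flipped():
    return simulate_exact_shift(SimulationConfig(seed=11, concordance="sign-flipped"))
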
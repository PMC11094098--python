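import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from gams_stratify.synthdata import PopulationSpec, SynthConfig, generate_dataset


def small_config(seed: int = 0, **overrides) -> SynthConfig:
    """A fast three-population configuration for unit tests."""
    kwargs = dict(
        populations=[
            PopulationSpec("GAMs", n_marker_genes=10),
            PopulationSpec("tumor", n_marker_genes=10),
            PopulationSpec("lymphocytes", n_marker_genes=10),
        ],
        n_cells_per_population=60,
        n_noise_genes=300,
        n_program_pos=15,
        n_program_neg=15,
        seed=seed,
    )
    kwargs.update(overrides)
    return SynthConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config(seed=0))


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the study's default conditions (600 cells, ~2k genes)."""
    return generate_dataset(SynthConfig(seed=0))


def toy_adata(counts, genes=None, cells=None) -> AnnData:
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cells = cells or [f"c{i}" for i in range(n_cells)]
    return AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=pd.DataFrame(index=cells),
        var=pd.DataFrame(index=genes),
    )
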
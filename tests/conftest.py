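import numpy as np
import pandas as pd
import pytest

from adipospec.data_model import CountMatrix, ExpressionMatrix
from adipospec.synthetic_data import SimConfig

SIX_TISSUES = (
    "visceral_adipose",
    "subcutaneous_adipose",
    "intramuscular_adipose",
    "muscle",
    "liver",
    "brain",
)


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    """3 genes x 4 samples over 2 tissues (fat has 2 replicates)."""
    values = pd.DataFrame(
        {
            "fat_r1": [2.0, 0.5, 10.0],
            "fat_r2": [4.0, 0.9, 12.0],
            "liver_r1": [1.0, 0.2, 0.0],
            "brain_r1": [0.0, 0.1, 3.0],
        },
        index=["g1", "g2", "g3"],
    )
    tissue = {"fat_r1": "fat", "fat_r2": "fat", "liver_r1": "liver", "brain_r1": "brain"}
    return ExpressionMatrix(values, tissue)


@pytest.fixture
def six_tissue_null_config() -> SimConfig:
    """6 tissues x 2 replicates, no planted structure: a 6 vs 6 null design."""
    return SimConfig(
        n_genes=1000,
        tissues=SIX_TISSUES,
        adipose_tissues=SIX_TISSUES[:3],
        replicates_range=(2, 2),
        fraction_specific=0.0,
        n_shared_adipose=0,
        de_fold_change=1.0,
        n_de_background=0,
        seed=42,
    )


@pytest.fixture
def six_tissue_de_config() -> SimConfig:
    """6 vs 6 design with 100 planted 4-fold genes at dispersion 0.1."""
    return SimConfig(
        n_genes=1000,
        tissues=SIX_TISSUES,
        adipose_tissues=SIX_TISSUES[:3],
        replicates_range=(2, 2),
        fraction_specific=0.0,
        n_shared_adipose=0,
        de_fold_change=4.0,
        n_de_background=100,
        nb_dispersion=0.1,
        seed=7,
    )


def make_count_matrix(counts: np.ndarray, tissues: list[str]) -> CountMatrix:
    genes = [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    return CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples),
        dict(zip(samples, tissues)),
    )
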
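import numpy as np
import pandas as pd
import pytest

from omicblup import (
    impute_mean_dosage,
    mi_kernel,
    nir_kernel,
    normalize_columns,
    savgol_first_derivative,
    snp_qc,
    spatial_kernel,
    vanraden_g,
)
from omicblup.simulate import SimConfig, generate_dataset


def small_config(**overrides) -> SimConfig:
    """Small but fully structured breeding trial for fast tests."""
    base = dict(
        n_lines=120,
        n_snps=400,
        n_cycles=2,
        locations=("LocA", "LocB"),
        trials_per_env=2,
        plots_grid=(8, 10),
        n_mi_features=200,
        n_nir_wavelengths=60,
        seed=1,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def dataset():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def kernels(dataset):
    """G, S, Q_MI, Q_NIR for the shared dataset."""
    geno = impute_mean_dosage(snp_qc(dataset.genotypes))
    g = vanraden_g(geno)
    s = spatial_kernel(dataset.phenotypes[["plot_id", "trial", "row", "col"]])
    q_mi = mi_kernel(normalize_columns(dataset.mi))
    nir = savgol_first_derivative(normalize_columns(dataset.nir), 11, 2)
    q_nir = nir_kernel(normalize_columns(nir))
    return {"G": g, "S": s, "Q_MI": q_mi, "Q_NIR": q_nir}


@pytest.fixture(scope="session")
def scalars(kernels):
    return {
        "d_G": kernels["G"].mean_diag,
        "d_S": kernels["S"].mean_diag,
        "mean_S": kernels["S"].mean_all,
        "d_Q": kernels["Q_MI"].mean_diag,
    }


def random_genotypes(rng, n_lines=50, n_snps=200, missing=0.05):
    p = rng.uniform(0.05, 0.5, n_snps)
    d = rng.binomial(2, p, size=(n_lines, n_snps)).astype(float)
    if missing:
        d[rng.random(d.shape) < missing] = np.nan
    from omicblup import GenotypeMatrix

    return GenotypeMatrix(
        [f"L{i}" for i in range(n_lines)],
        [f"S{j}" for j in range(n_snps)],
        d,
    )


def grid_layout(rows, cols, trial="T1", prefix="P"):
    recs = [
        dict(plot_id=f"{prefix}{r}_{c}", trial=trial, row=r, col=c)
        for r in range(rows)
        for c in range(cols)
    ]
    return pd.DataFrame(recs)
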
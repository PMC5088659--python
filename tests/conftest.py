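"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from regionrank import synthdata as sd


@pytest.fixture(scope="session")
def small_cohort() -> sd.CohortData:
    """A compact multi-region cohort without covariate confounds."""
    return sd.simulate_cohort(
        sd.CohortConfig(
            seed=101,
            n_regions=3,
            n_probesets=300,
            n_modules=4,
            module_size=40,
            covariate_effect=0.0,
        )
    )


@pytest.fixture(scope="session")
def default_cohort() -> sd.CohortData:
    """The generator's default study conditions (covariates included)."""
    return sd.simulate_cohort(sd.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def two_block_matrix() -> tuple[pd.DataFrame, list[int]]:
    """Two planted 50-gene blocks (within-r 0.8, between-r 0) over 60 samples."""
    rng = np.random.default_rng(42)

    def block(n_genes: int, r: float) -> np.ndarray:
        lat = rng.standard_normal(60)
        noise_sd = np.sqrt(1.0 / r - 1.0)
        return lat[None, :] + noise_sd * rng.standard_normal((n_genes, 60))

    x = np.vstack([block(50, 0.8), block(50, 0.8)])
    m = pd.DataFrame(x, index=[f"g{i:03d}" for i in range(100)])
    return m, [0] * 50 + [1] * 50


@pytest.fixture(scope="session")
def small_sc() -> sd.SingleCellData:
    """Small single-cell dataset with planted 8-fold markers."""
    return sd.simulate_single_cell_counts(
        sd.SingleCellConfig(
            seed=5, n_genes=60, n_cells_per_type=30, marker_fraction=0.15
        )
    )
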
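import numpy as np
import pandas as pd
import pytest

import modkit as mk
from modkit.compendium import CenteredMatrix


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic compendium (seed 0) shared across the heavy tests."""
    cfg = mk.SimConfig(seed=0)
    truth = mk.generate_truth(cfg)
    x, meta = mk.generate_expression(truth, cfg)
    xc = mk.center_to_reference(x, meta)
    return cfg, truth, x, meta, xc


@pytest.fixture(scope="session")
def fitted(default_sim):
    """Robust ICA fit of the default compendium at the planted dimensionality."""
    cfg, truth, x, meta, xc = default_sim
    res = mk.RobustICA(xc, k=cfg.n_modules, n_runs=50).fit(seed=42)
    return res


def planted_matrix(
    seed,
    n_genes=300,
    n_samples=80,
    n_modules=5,
    members=15,
    noise_sd=0.05,
    activity_sd=5.0,
    activity_density=0.5,
    gene_noise_sd=None,
):
    """Small planted-factor centered matrix used by decomposition tests.

    ``gene_noise_sd`` optionally overrides the per-gene noise scale vector
    (heteroscedastic noise with idiosyncratically variable genes).
    """
    rng = np.random.default_rng(seed)
    M = np.zeros((n_genes, n_modules))
    for j in range(n_modules):
        M[j * members:(j + 1) * members, j] = np.abs(rng.normal(1.0, 0.2, members))
        M[:, j] /= np.linalg.norm(M[:, j])
    A = rng.normal(0.0, activity_sd, (n_modules, n_samples))
    A *= rng.random((n_modules, n_samples)) < activity_density
    noise = rng.normal(0.0, 1.0, (n_genes, n_samples))
    if gene_noise_sd is not None:
        noise *= np.asarray(gene_noise_sd)[:, None]
    else:
        noise *= noise_sd
    values = M @ A + noise
    xc = CenteredMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i + 1:04d}" for i in range(n_genes)],
            columns=[f"s{i + 1:03d}" for i in range(n_samples)],
        ),
        reference_samples=[],
    )
    return xc, M, A
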
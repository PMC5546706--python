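"""Shared fixtures: small deterministic cohorts and one full-scale fit.

All data are generated programmatically; nothing is read from disk except
files the tests themselves write to tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest

import psdanet as pn


@pytest.fixture(scope="session")
def clean_dataset() -> pn.SyntheticDataset:
    """Small noise-free shmoo cohort with known pulses."""
    return pn.generate(pn.GeneratorConfig(n_genes=12, noise_cv=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_dataset() -> pn.SyntheticDataset:
    """Small 5%-noise shmoo cohort."""
    return pn.generate(pn.GeneratorConfig(n_genes=30, noise_cv=0.05, seed=5))


@pytest.fixture(scope="session")
def default_dataset() -> pn.SyntheticDataset:
    """The full-scale study condition: 195 genes, 5-min grid, CV 5%."""
    return pn.generate(pn.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_psda_fit(default_dataset) -> pn.PsdaResults:
    """PSDA fit of the full-scale cohort against its global profile.

    Session-scoped: the fit takes ~10 s and several tests reuse it.
    """
    ds = default_dataset
    model = pn.PsdaModel(ds.expression, ds.growth, ds.degradation, ds.global_profile)
    return model.fit(seed=7)


@pytest.fixture(scope="session")
def default_meta_genes(default_dataset, default_psda_fit):
    """Meta-gene activities from clustering the full-scale fit (k = 6)."""
    ds = default_dataset
    res = default_psda_fit
    reg = res.regulation_matrix()
    event = [g for g, f in res.fits.items() if f.classification != "none"]
    traces = {g: reg.loc[g].to_numpy() for g in event}
    assignment = pn.kmeans_cluster(traces, ds.growth.grid, k=6, n_restarts=50, seed=0)
    activities = pn.meta_gene_activity(assignment, traces, ds.growth.grid)
    return assignment, activities, traces


@pytest.fixture()
def flat_grid() -> pn.TimeGrid:
    return pn.TimeGrid(np.arange(0.0, 101.0, 5.0))
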
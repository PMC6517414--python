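"""Shared fixtures: simulated cohorts and meta-collections reused across tests.

Everything is generated programmatically from fixed seeds; the heavier
session-scoped objects (first-passage cohorts, the default meta-collection
and its signature) are built once and shared by the unit and acceptance
suites.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from critaging.normalize import MetaCollection, yugene
from critaging.pipeline import RunConfig, mortality_cohorts
from critaging.signature import ResampleConfig, resample_signature
from critaging.synthetic_data import (
    FactorModelParams,
    MetaCollectionSpec,
    generate_meta_collection,
)

warnings.filterwarnings("ignore", category=UserWarning)

ACCEPT_SEED = 20220914  # fixed study seed for the shared simulations


@pytest.fixture(scope="session")
def fp_cohorts():
    """Eight first-passage cohorts (n = 2e4 each) with alpha spanning 10x."""
    cfg = RunConfig(seed=ACCEPT_SEED, n_cohorts=8, cohort_size=20000)
    return mortality_cohorts(cfg)


@pytest.fixture(scope="session")
def fp_alphas():
    cfg = RunConfig(seed=ACCEPT_SEED, n_cohorts=8, cohort_size=20000)
    return np.exp(np.linspace(*np.log(np.asarray(cfg.alpha_range)), cfg.n_cohorts))


@pytest.fixture(scope="session")
def default_factor():
    return FactorModelParams.random(G=500, seed=ACCEPT_SEED + 1)


@pytest.fixture(scope="session")
def default_collection(default_factor):
    """The default 20-dataset meta-collection, YuGene-normalized."""
    spec = MetaCollectionSpec(n_datasets=20, seed=ACCEPT_SEED + 2)
    return generate_meta_collection(spec, default_factor).map(yugene)


@pytest.fixture(scope="session")
def default_signature(default_collection):
    cfg = ResampleConfig(B=200, seed=ACCEPT_SEED + 3)
    return resample_signature(default_collection, cfg)


def make_single_gene_collection(seed: int, G: int = 50, gene: int = 7):
    """A batch-free collection where one gene carries the aging signal and
    every other gene is pure residual noise (lasso support-recovery fixture)."""
    from critaging._rng import rng_from

    rng = rng_from(seed, 99)
    xbar = np.clip(rng.normal(6.0, 1.5, G), 1.0, None)
    b = np.zeros(G)
    b[gene] = 1.0
    factor = FactorModelParams(xbar=xbar, b=b, resid_sd=0.03)
    spec = MetaCollectionSpec(
        n_datasets=10, samples_per_dataset=(10, 10),
        offset_sd=0.0, scale_range=(1.0, 1.0), seed=seed,
    )
    return generate_meta_collection(spec, factor), factor
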
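"""Shared fixtures: synthetic datasets and cached posterior fits.

The expensive MCMC fits are session-scoped so that several test modules can
interrogate the same posterior (recovery, reliability, fit assessment)
without refitting.
"""

from __future__ import annotations

import numpy as np
import pytest

import bcfa
from bcfa.model import LoadingPattern, ModelSpec, PriorConfig


@pytest.fixture(scope="session")
def bsem_std():
    """Standardized n=2000 continuous responses from the BSEM preset."""
    data = bcfa.generate_continuous(bcfa.bsem_generating_model(), 2000, seed=0)
    return bcfa.standardize(data)


@pytest.fixture(scope="session")
def bsem_fit(bsem_std):
    """Cross-loading spec (v=0.005) fitted to the BSEM-solution synthetic data."""
    spec = bcfa.with_crossloading_priors(bcfa.pih_cfa_spec(), 0.005)
    return bcfa.run_mcmc(
        spec, bsem_std, chains=4, min_iterations=6000, max_iterations=12000,
        seed=50,
    )


@pytest.fixture(scope="session")
def cfa_std():
    """Standardized n=2000 responses from the zero-cross CFA preset."""
    data = bcfa.generate_continuous(bcfa.cfa_generating_model(), 2000, seed=1)
    return bcfa.standardize(data)


@pytest.fixture(scope="session")
def cfa_fit(cfa_std):
    """Plain CFA spec fitted to well-specified CFA synthetic data."""
    return bcfa.run_mcmc(
        bcfa.pih_cfa_spec(), cfa_std, chains=4, min_iterations=3000,
        max_iterations=10000, seed=51,
    )


@pytest.fixture(scope="session")
def onefactor_fit(bsem_std):
    """Deliberately misspecified one-factor fit to four-factor data."""
    pattern = LoadingPattern(major=np.ones((12, 1), dtype=bool))
    spec = ModelSpec(pattern=pattern, priors=PriorConfig(), label="1-factor")
    return bcfa.run_mcmc(
        spec, bsem_std, chains=2, min_iterations=1500, max_iterations=4000,
        seed=52,
    )


@pytest.fixture(scope="session")
def small_two_factor_model():
    """Compact 6-item / 2-factor generating model for cheap sampler tests."""
    lam = np.array(
        [
            [0.8, 0.0],
            [0.7, 0.0],
            [0.6, 0.0],
            [0.0, 0.8],
            [0.0, 0.7],
            [0.0, 0.6],
        ]
    )
    phi = np.array([[1.0, 0.5], [0.5, 1.0]])
    items = tuple(f"q{i}" for i in range(1, 7))
    return bcfa.GeneratingModel.from_standardized(
        lam, phi, item_labels=items, factor_labels=("F1", "F2")
    )


@pytest.fixture(scope="session")
def small_spec(small_two_factor_model):
    major = np.abs(small_two_factor_model.Lambda) > 0
    return bcfa.build_cfa_spec(
        LoadingPattern(major=major),
        item_labels=small_two_factor_model.item_labels,
        factor_labels=small_two_factor_model.factor_labels,
    )
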
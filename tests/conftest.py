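"""Shared fixtures.

The two session-scoped replicate runs back the statistical acceptance
tests (type-1 direction, power ordering, null calibration); they are the
expensive part of the suite and are computed once.  Base seeds were
fixed when the fixtures were written and are not adjusted afterwards.
"""

from __future__ import annotations

import numpy as np
import pytest

from sparseassoc.evaluate import SINGLE_VARIANT_METHODS, run_replicates
from sparseassoc.simulate import default_panel_spec

NULL_BASE_SEED = 101
ALT_BASE_SEED = 202
PANEL_SEED = 2027


def make_toy_cohort(n=300, m=8, seed=7, maf_range=(0.005, 0.05)):
    """Null logistic cohort with AGE/SEX covariates and a rare-variant region."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(25, 70, n)
    sex = rng.integers(0, 2, n).astype(float)
    X = np.column_stack([np.ones(n), age, sex])
    eta = -1.5 + 0.02 * age - 0.3 * sex - 0.9
    pi = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < pi).astype(float)
    mafs = np.exp(rng.uniform(np.log(maf_range[0]), np.log(maf_range[1]), m))
    G = rng.binomial(2, mafs[None, :], size=(n, m)).astype(float)
    # guarantee polymorphism
    for j in range(m):
        if G[:, j].max() == 0:
            G[rng.integers(0, n), j] = 1.0
    return y, X, G


@pytest.fixture(scope="session")
def toy_cohort():
    return make_toy_cohort()


@pytest.fixture(scope="session")
def null_run():
    """R=2000 null replicates of the default panel, five single-variant tests."""
    spec = default_panel_spec(seed=PANEL_SEED)
    return run_replicates(
        spec,
        list(SINGLE_VARIANT_METHODS),
        R=2000,
        scenario="null",
        base_seed=NULL_BASE_SEED,
        B=1000,
    )


@pytest.fixture(scope="session")
def alt_run():
    """R=1000 alternative replicates, collapsing tests on rare / rare+lf."""
    spec = default_panel_spec(seed=PANEL_SEED)
    return run_replicates(
        spec,
        ["burden", "skat", "skato"],
        R=1000,
        scenario="alternative",
        base_seed=ALT_BASE_SEED,
        classes=("rare", "rare_lf"),
        B=1000,
    )
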
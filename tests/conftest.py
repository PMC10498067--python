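"""Shared fixtures: synthetic datasets reused across test modules."""

import numpy as np
import pytest

from ordif.grm import GradedResponseModel
from ordif.io import ResponseMatrix
from ordif.simulate import SyntheticSpec, default_fixture_spec, default_item_bank, generate


@pytest.fixture(scope="session")
def recovery_data():
    """J=10, n=2000, no DIF — the parameter-recovery dataset."""
    a, b = default_item_bank(10)
    spec = SyntheticSpec(n_per_group=(1000, 1000), discrimination=a, thresholds=b)
    df, truth = generate(spec, seed=42)
    return spec, df, truth


@pytest.fixture(scope="session")
def recovery_fit(recovery_data):
    """Graded model fitted once on the recovery dataset."""
    _, df, _ = recovery_data
    return GradedResponseModel().fit(df.drop(columns="group"))


@pytest.fixture(scope="session")
def fixture_run():
    """Default desk-scale DIF scenario (J=20, 4 DIF items) at one seed."""
    spec = default_fixture_spec()
    df, truth = generate(spec, seed=7)
    rm = ResponseMatrix(df.drop(columns="group").astype(float), df["group"])
    return spec, rm, truth


@pytest.fixture(scope="session")
def one_factor_data():
    """n=5000 draws from an exact one-factor model (8 indicators)."""
    rng = np.random.default_rng(11)
    n, J = 5000, 8
    lam = rng.uniform(0.5, 0.9, J)
    psi = 1 - lam**2
    X = np.outer(rng.normal(size=n), lam) + rng.normal(size=(n, J)) * np.sqrt(psi)
    return X, lam, psi
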
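import numpy as np
import pytest

from pxmdc import (
    AbundanceMatrix,
    MaskedMatrix,
    MissingnessSpec,
    ThresholdParams,
    default_fixture,
    simulate_mm,
    tier_by_percent,
)


@pytest.fixture(scope="session")
def fixture_matrix() -> AbundanceMatrix:
    """Standard 100 x 30 synthetic abundance matrix (3 decades of spread)."""
    return default_fixture(seed=1)


@pytest.fixture(scope="session")
def masked_fixture(fixture_matrix) -> MaskedMatrix:
    """Fixture matrix with 10% labeled MM missingness at alpha = 0.5."""
    params = ThresholdParams(30, 40, 30, 0.5)
    tiers = tier_by_percent(fixture_matrix, params)
    return simulate_mm(
        fixture_matrix, tiers, MissingnessSpec(rate=0.1, params=params, seed=42)
    )


def make_masked(values, mask, labels=None, met_prefix="m", samp_prefix="s"):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return MaskedMatrix(
        metabolite_ids=[f"{met_prefix}{i:02d}" for i in range(m)],
        sample_ids=[f"{samp_prefix}{j:02d}" for j in range(n)],
        values=values,
        mask=np.asarray(mask, dtype=bool),
        labels=labels,
    )


def make_complete(values):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return AbundanceMatrix(
        metabolite_ids=[f"m{i:02d}" for i in range(m)],
        sample_ids=[f"s{j:02d}" for j in range(n)],
        values=values,
    )
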
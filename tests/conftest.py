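import numpy as np
import pytest

from wagglemix import MixtureParams, WaggleDataset, sample_mixture


@pytest.fixture(scope="session")
def canonical_params() -> MixtureParams:
    """A well-behaved mixture parameter set used across tests."""
    return MixtureParams.from_values(p=0.4, a_s=0.2, b_s=2.0, a_r=0.15, b_r=3.0, m=0.5)


@pytest.fixture(scope="session")
def random_valid_params():
    """50 random valid parameter sets for normalization/property sweeps."""
    rng = np.random.default_rng(20260927)
    out = []
    while len(out) < 50:
        m = rng.uniform(0.0, 1.0)
        a_s = rng.uniform(0.05, 0.9) / max(m, 0.5) * 0.5
        a_r = rng.uniform(0.05, 0.9) / max(m, 0.5) * 0.5
        if a_s * m >= 0.95 or a_r * m >= 0.95:
            continue
        out.append(
            MixtureParams.from_values(
                p=rng.uniform(0.0, 1.0),
                a_s=a_s,
                b_s=10.0 ** rng.uniform(-1, 1.3),
                a_r=a_r,
                b_r=10.0 ** rng.uniform(-1, 1.3),
                m=m,
            )
        )
    return out


@pytest.fixture()
def small_dataset(canonical_params) -> WaggleDataset:
    x = sample_mixture(200, canonical_params, seed=42)
    return WaggleDataset(hive_id="fixture-hive", durations=x)
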
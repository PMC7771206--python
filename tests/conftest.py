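import numpy as np
import pandas as pd
import pytest

from epilink.synthetic import SyntheticBundle, simulate_bundle


@pytest.fixture(scope="session")
def bundle() -> SyntheticBundle:
    """A moderately sized coherent synthetic study, shared across tests."""
    return simulate_bundle(seed=1)


@pytest.fixture(scope="session")
def small_bundle() -> SyntheticBundle:
    """A tiny bundle for fast brute-force comparisons."""
    return simulate_bundle(seed=2, n_samples=20, n_peaks=60, n_genes=20,
                           n_promoter_links=2, n_distal_links=2, n_cn_links=1,
                           n_extra_effects=3, n_prognostic=2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def toy_cohort(proportions, prefix="S") -> pd.DataFrame:
    props = np.asarray(proportions, dtype=float)
    return pd.DataFrame({
        "sample_id": [f"{prefix}{i:03d}" for i in range(1, len(props) + 1)],
        "proportion": props,
        "group": np.where(props >= 0.5, "high", "low"),
    })
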
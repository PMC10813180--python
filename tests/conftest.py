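import numpy as np
import pytest

from sersdx.spectra import Spectrum, SpectraSet
from sersdx.synthetic import SyntheticConfig, generate_cohort
from sersdx.preprocess import preprocess_set


@pytest.fixture
def rng():
    return np.random.default_rng(20240133)


@pytest.fixture
def toy_spectrum():
    wn = np.arange(600.0, 700.0, 2.0)
    y = 1.0 + np.exp(-0.5 * ((wn - 650.0) / 5.0) ** 2)
    return Spectrum(wn, y, sample_id="toy", label="FM")


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort: 20 FM + 14 non-FM + 3 NC, 4 replicates."""
    cfg = SyntheticConfig(seed=42, n_fm=20, n_nonfm=14, n_nc=3)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_processed(small_cohort):
    return preprocess_set(small_cohort.select_labels("FM", "NONFM"))


def random_spectra_set(rng, n=6, p=40, label_split=3):
    """Unstructured random SpectraSet for algebra-level tests."""
    grid = 600.0 + 2.0 * np.arange(p)
    X = rng.normal(1.0, 0.1, size=(n, p)) + 2.0
    labels = np.array(
        ["FM"] * label_split + ["NONFM"] * (n - label_split), dtype=object
    )
    ids = np.array([f"s{i}" for i in range(n)], dtype=object)
    return SpectraSet(grid=grid, X=X, labels=labels, ids=ids)
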
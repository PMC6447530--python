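import numpy as np
import pytest

from metanno.config import RunConfig
from metanno.fixtures import FixtureSpec, make_fixture
from metanno.spectra import Spectrum


@pytest.fixture(scope="session")
def standard_fixture():
    """The 50-metabolite small-world dataset: inheritance 0.7, library 20%."""
    return make_fixture(FixtureSpec(seed=1, n_metabolites=50, library_fraction=0.2))


@pytest.fixture(scope="session")
def standard_result(standard_fixture):
    from metanno.pipeline import run_on_fixture

    return run_on_fixture(standard_fixture, RunConfig(seed=1))


@pytest.fixture(scope="session")
def chain_fixture():
    """Five metabolites in a reaction chain; only the first is in the library."""
    return make_fixture(
        FixtureSpec(
            seed=7,
            n_metabolites=5,
            topology="chain",
            library_metabolites=("M0000",),
            n_samples_per_group=3,
            n_noise_peaks=2,
        )
    )


def random_spectrum(rng, n=8, mz_low=60.0, mz_high=500.0, min_gap=0.5):
    """Random spectrum whose fragments are far apart relative to tolerance."""
    mz = np.sort(rng.choice(np.arange(mz_low, mz_high, min_gap), size=n, replace=False))
    mz = mz + rng.uniform(-0.001, 0.001, size=n)
    inten = rng.uniform(0.05, 1.0, size=n)
    return Spectrum(precursor_mz=mz_high + 50, fragments=np.column_stack([mz, inten]))
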
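import numpy as np
import pytest

from ms2search import synthetic
from ms2search.embed import default_models
from ms2search.library_store import build_library
from ms2search.search_core import generate_training_pairs, train_ranker
from ms2search.spectra_io import Spectrum


def make_spectrum(mz, intensities, spectrum_id="s", precursor_mz=500.0,
                  ionmode="positive", **metadata):
    return Spectrum(
        spectrum_id=spectrum_id,
        mz=np.asarray(mz, dtype=float),
        intensities=np.asarray(intensities, dtype=float),
        precursor_mz=precursor_mz,
        ionmode=ionmode,
        metadata=metadata,
    )


def random_spectrum(rng, n_peaks=None, spectrum_id="s", max_mz=1000.0):
    n = n_peaks or rng.integers(3, 40)
    mz = np.sort(rng.uniform(50.0, max_mz, size=n))
    intensities = rng.uniform(0.01, 1.0, size=n)
    intensities[rng.integers(n)] = 1.0
    return make_spectrum(mz, intensities, spectrum_id=spectrum_id,
                         precursor_mz=float(rng.uniform(100, 900)))


@pytest.fixture(scope="session")
def small_cfg():
    return synthetic.SyntheticConfig(
        n_clusters=4, structures_per_cluster=4, spectra_per_structure=3, seed=7
    )


@pytest.fixture(scope="session")
def small_library(small_cfg):
    return synthetic.generate_library(small_cfg)


@pytest.fixture(scope="session")
def small_store(small_library):
    spectra, structures = small_library
    return build_library(
        spectra,
        *default_models(),
        fingerprint_overrides=synthetic.fingerprint_overrides(structures),
    )


@pytest.fixture(scope="session")
def small_ranker(small_store):
    pairs = generate_training_pairs(small_store, top_n=30, seed=11)
    return train_ranker(pairs, n_estimators=100, seed=11,
                        library_parameter_hash=small_store.parameter_hash)
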
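import warnings

import numpy as np
import pytest

from masstaxa.peaks import (PeakParams, bin_to_convergence,
                            build_feature_matrix, detect_peaks)
from masstaxa.preprocess import preprocess_pipeline
from masstaxa.synthgen import preset_params, simulate_library


def matrix_from_library(params, profiles, replicate_policy="mean"):
    """Full pipeline: simulate -> preprocess -> detect -> bin -> matrix."""
    spectra, _ = simulate_library(params, profiles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        processed = [preprocess_pipeline(s) for s in spectra]
        peaklists = [detect_peaks(s, PeakParams()) for s in processed]
        binned, fm, _ = bin_to_convergence(peaklists)
        return build_feature_matrix(binned, fm, replicate_policy)


@pytest.fixture(scope="session")
def small_library_matrix():
    """4 species x 6 specimens x 1 replicate — cheap enough for LOO tests."""
    params, profiles = preset_params("default", seed=7)
    params.n_phyla = 1
    params.n_classes_per_phylum = 2
    params.n_genera_per_class = 2
    params.n_species_per_genus = 1
    params.n_specimens_per_species = 6
    params.n_replicates = 1
    from masstaxa.synthgen import make_taxonomy_profiles
    profiles = make_taxonomy_profiles(params)
    return matrix_from_library(params, profiles)


@pytest.fixture(scope="session")
def hierarchy_matrix():
    """16 species in 2 phyla x 2 classes x 2 genera x 2 species."""
    params, profiles = preset_params("hierarchy", seed=3)
    return matrix_from_library(params, profiles)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
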
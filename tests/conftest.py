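import numpy as np
import pytest

from dropspect import synth
from dropspect.derep import FractionScheme


@pytest.fixture(scope="session")
def study_scale_features():
    """64 feature lists (60 grouped + 4 sparse) with planted 8-group structure."""
    return synth.gen_feature_tables(
        n_groups=8,
        samples_per_group=[20, 10, 8, 7, 5, 4, 3, 3],
        n_sparse_samples=4,
        seed=101,
    )


@pytest.fixture(scope="session")
def clone_fingerprints():
    """3 clones x 3 noisy copies of fingerprint band patterns."""
    return synth.gen_fingerprints(n_clones=3, copies_per_clone=3, flip_prob=0.05, seed=202)


@pytest.fixture(scope="session")
def spectral_family():
    """7-member compound family plus 5 unrelated background spectra."""
    family, truth = synth.gen_compound_family(
        scaffold_peaks=10, n_derivatives=7, seed=303, family_id="serr"
    )
    background = synth.gen_random_spectra(n=5, seed=304)
    return family, background, truth


@pytest.fixture(scope="session")
def spiked_plate():
    """159-fraction assay plate with one active window at fractions 84-87."""
    return synth.gen_fraction_plate(
        scheme=FractionScheme(), spiked_windows=[((84, 87), 95.0)], noise_sd=0.02, seed=405
    )
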
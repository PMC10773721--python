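import numpy as np
import pytest
from hypothesis import settings

import injurycast as ic
from injurycast import models, windowing

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """10 athletes x 120 days with the default planted risk signal."""
    return ic.generate_cohort(n_athletes=10, n_days=120, seed=42)


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    """Normalized, padded windows of the small cohort, as arrays."""
    wins = ic.build_windows(small_cohort)
    norm, _ = windowing.normalize_windows(wins)
    padded = windowing.pad_windows(norm)
    return windowing.windows_to_arrays(padded)


@pytest.fixture(scope="session")
def cohort64():
    """64-athlete cohort at reference scale for resampling-count checks."""
    recs = ic.generate_cohort(n_athletes=64, n_days=400, seed=7)
    wins = ic.build_windows(recs)
    norm, _ = windowing.normalize_windows(wins)
    padded = windowing.pad_windows(norm)
    return windowing.windows_to_arrays(padded)


@pytest.fixture(scope="session")
def tiny_trained_models(small_windows):
    """A quickly trained DCAE + classifier pair on GASF stacks (for shape and
    attribution tests, not for performance claims)."""
    from injurycast import encoders

    X, y, aids, _ = small_windows
    stacks = encoders.encode_dataset(X[:160], "gasf")
    spec = models.AutoencoderSpec(conv_channels=(8, 16), epochs=4)
    dcae = models.dcae_fit(stacks, spec, seed=1)
    latents = dcae.encode(stacks)
    clf_spec = models.ClassifierSpec(hidden_units=(16, 16), epochs=6)
    clf = models.dnn_fit(latents, y[:160], clf_spec, seed=1)
    return dcae, clf, stacks
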
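import warnings

import numpy as np
import pytest

from ripplelock.simulate import (SimulationConfig, ArtifactInjectionConfig,
                                 generate_recording)
from ripplelock import artifacts as art
from ripplelock.io import nrem_mask

warnings.filterwarnings("ignore", message="Mean of empty slice")


@pytest.fixture(scope="session")
def short_night():
    """10-minute default-parameter night with injected artifacts."""
    cfg = SimulationConfig(
        duration_s=600.0, seed=11,
        artifact_injection=ArtifactInjectionConfig(
            n_amplitude=2, n_steps=2, n_hf_bursts=2))
    rec, truth, hyp = generate_recording(cfg)
    return cfg, rec, truth, hyp


@pytest.fixture(scope="session")
def short_night_masks(short_night):
    _, rec, _, hyp = short_night
    mask = art.combine_masks(
        art.detect_all(rec.channel("NC"), rec.fs, hyp),
        art.detect_all(rec.channel("HIPP"), rec.fs, hyp))
    nrem = nrem_mask(hyp, rec.fs, rec.n_samples)
    return mask, nrem


@pytest.fixture()
def rng(request):
    import zlib

    # stable per-test stream, independent of execution order
    seed = zlib.crc32(request.node.name.encode()) % (2**31)
    return np.random.default_rng(seed)
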
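import numpy as np
import pytest

from somavar.simulate import CghEvent, CghTruth, simulate_cgh


@pytest.fixture(scope="session")
def small_cgh():
    """Three samples, two chromosomes, one private event each for S1/S2
    plus one event shared by every sample (background heterogeneity)."""
    truth = CghTruth(
        planted_events=[
            CghEvent("S1", "Gm11", 100_000, 140_000, "del", -1.0),
            CghEvent("S2", "Gm13", 300_000, 320_000, "dup", 1.0),
        ],
        shared_events=[CghEvent(None, "Gm11", 500_000, 530_000, "del", -1.0)],
        chromosome_lengths={"Gm11": 1_000_000, "Gm13": 1_000_000},
        noise_sd=0.15, probe_spacing_bp=2000, seed=5,
        sample_ids=["S1", "S2", "S3"])
    tracks, manifest = simulate_cgh(truth)
    return truth, tracks, manifest


def probe_index(position_bp: int, spacing: int = 2000) -> int:
    """0-based probe index of a 1-based position on the synthetic layout."""
    return position_bp // spacing - 1


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
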
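import numpy as np
import pytest

from synergycoach.synth import GroundTruth, make_default_ground_truth


@pytest.fixture(scope="session")
def gt_default() -> GroundTruth:
    """Default study conditions: 16 muscles, 3 synergies, default jitter/noise."""
    return make_default_ground_truth(16, 3, seed=1)


@pytest.fixture(scope="session")
def gt_clean() -> GroundTruth:
    """Noise-free, jitter-free ground truth (exact W0 @ C0 envelopes)."""
    return make_default_ground_truth(
        16, 3, seed=1, snr_db=np.inf, weight_jitter_sd=0.0,
        subject_shift_sd=0.0, rep_shift_sd=0.0, shape_jitter_sd=0.0,
        shape_mod_amp=0.0)


def random_low_rank(p: int, n: int, s: int, seed: int) -> tuple:
    """Exact rank-s nonnegative product E = W0 @ C0 with its factors."""
    rng = np.random.default_rng(seed)
    W0 = rng.uniform(0.1, 1.0, size=(p, s))
    C0 = rng.uniform(0.0, 1.0, size=(s, n))
    return W0 @ C0, W0, C0
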
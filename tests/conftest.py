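import numpy as np
import pytest

import leggrowth as lg


@pytest.fixture(scope="session")
def calibrated_spec():
    """Band-wise generator moment-matched to the embedded reference table."""
    return lg.calibrate_from_summary()


@pytest.fixture(scope="session")
def calibrated_cohort(calibrated_spec):
    """One cohort at the published group sizes (208-ish rows), fixed seed."""
    return lg.simulate_cohort(calibrated_spec, seed=11)


@pytest.fixture(scope="session")
def sync_cohort():
    """Mode-B cohort under the isometric null (shared exponent)."""
    spec = lg.synchronous_spec()
    return lg.simulate_cohort(
        spec, {"boy": (4, 25, 30, 43, 19), "girl": (4, 17, 24, 24, 18)}, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
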
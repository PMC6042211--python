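import numpy as np
import pytest

from locohcv import Trajectory, simulate, two_patch_config


def make_random_track(seed: int, n: int, extent: float = 1000.0, dt: float = 600.0) -> Trajectory:
    """Uniform scatter with strictly increasing jittered timestamps."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, extent, n)
    y = rng.uniform(0.0, extent, n)
    t = dt * np.arange(n) + rng.uniform(0.0, 0.4 * dt, n)
    return Trajectory.from_arrays(x, y, t, individual_id=f"rand{seed}")


@pytest.fixture
def small_track() -> Trajectory:
    return make_random_track(seed=42, n=40)


@pytest.fixture
def two_patch_track() -> Trajectory:
    """120 fixes, two patches 20x the patch sd apart, 3 visits each."""
    return simulate(
        two_patch_config(
            n_per_dwell=20, n_visits=3, separation=1000.0,
            within_patch_sd=50.0, dt=600.0, travel_speed=2.0, seed=7,
        )
    )
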
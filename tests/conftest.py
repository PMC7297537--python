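import numpy as np
import pytest

from compassrun.geometry import LocalFrame, PlanarTrack
from compassrun.segmentation import Excursion
from compassrun.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def frame():
    return LocalFrame(49.8, 15.5)


def make_excursion(xy, times=None, owner=(0.0, 0.0), turning=None):
    """Build an Excursion directly from planar coordinates (test helper)."""
    xy = np.asarray(xy, float)
    if times is None:
        times = np.arange(len(xy)) * 5.0
    track = PlanarTrack(np.asarray(times, float), xy[:, 0], xy[:, 1])
    exc = Excursion(track, 0, len(xy) - 1, (float(owner[0]), float(owner[1])),
                    trial_id="test", dog_id="dog")
    if turning is not None:
        exc.turning_point_index = turning
    return exc


@pytest.fixture(scope="session")
def small_dataset():
    """30 mixed-strategy trials at default study conditions."""
    cfg = SimConfig(n_trials=30, seed=17)
    records, truth = simulate_dataset(cfg)
    return cfg, records, truth
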
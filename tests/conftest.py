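import numpy as np
import pytest

from microhet import synth
from microhet.imaging import ColonyTrack


@pytest.fixture(scope="session")
def wt_rates_2000():
    """Seeded wild-type mixture: 90% fast bulk (0.407 h^-1), 10% slow."""
    spec = synth.MixtureSpec(components=synth.WT_MIXTURE, n_colonies=2000,
                             rng_seed=7)
    return synth.generate_rate_mixture(spec)


@pytest.fixture(scope="session")
def small_timelapse():
    """A 6-colony rendered stack with ground truth (fast to process)."""
    specs = synth.grid_colony_specs(6, (900, 900), rates=0.407, rng_seed=11)
    return synth.generate_timelapse(specs, frame_interval=1.5, n_frames=9,
                                    image_shape=(900, 900), noise_sd=1.0,
                                    rng_seed=11)


def make_track(times, areas, colony_id=0):
    return ColonyTrack(colony_id=colony_id, frames=list(range(len(times))),
                       times=list(times), areas=list(areas),
                       centroids=[(0.0, 0.0)] * len(times))


@pytest.fixture
def track_factory():
    return make_track
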
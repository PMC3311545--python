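import numpy as np
import pytest

from ezgkit.quantify import TimeCourseCounts
from ezgkit.simulate import SimulationConfig


@pytest.fixture
def toy_counts() -> TimeCourseCounts:
    return TimeCourseCounts(
        transcript_ids=["t1", "t2", "t3"],
        lengths_bp=[1000, 517, 2000],
        counts=np.array(
            [
                [10, 20, 30, 40],
                [0, 7, 3, 1],
                [5, 0, 0, 0],
            ]
        ),
        library_sizes=np.array([1_000_000, 3_200_000, 2_000_000, 1_500_000]),
    )


@pytest.fixture
def sim_config() -> SimulationConfig:
    return SimulationConfig(n_transcripts=400, seed=11)
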
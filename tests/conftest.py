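import os

os.environ.setdefault("MPLBACKEND", "Agg")

import numpy as np
import pytest

from voigtnmr import PeakSpec, SimConfig, SpectraSet, make_axis


@pytest.fixture(scope="session")
def paper_axis() -> np.ndarray:
    """The printed acquisition grid: -1..10 ppm at 2.5e-4 ppm resolution."""
    return make_axis(-1.0, 10.0, 2.5e-4)


@pytest.fixture(scope="session")
def paper_axis_set(paper_axis) -> SpectraSet:
    return SpectraSet(paper_axis, np.ones((1, paper_axis.size)), ["s0"])


@pytest.fixture()
def small_cfg() -> SimConfig:
    """A fast 1.0-2.0 ppm scenario with three well-separated peaks."""
    return SimConfig(
        axis=(1.0, 2.0, 2.5e-4),
        peaks=[
            PeakSpec(1.20, 0.15, 0.002, 0.6, 3e-4),
            PeakSpec(1.48, 0.22, 0.0018, 0.8, 3e-4),
            PeakSpec(1.75, 0.10, 0.0025, 0.4, 3e-4),
        ],
        noise_sd=0.05,
        n_samples=5,
        seed=11,
    )
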
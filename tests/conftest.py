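import numpy as np
import pytest

from msbiotype.config import PipelineConfig
from msbiotype.io import Peak, PeakList, load_table1
from msbiotype.pipeline import run_study
from msbiotype.simulate import SimulationConfig, simulate_study


def make_peaklist(mzs, intensities=None, normalized=False, **kw) -> PeakList:
    """Terse PeakList builder for tests."""
    if intensities is None:
        intensities = [1.0] * len(mzs)
    peaks = [Peak(float(m), float(i)) for m, i in zip(mzs, intensities)]
    return PeakList(peaks, normalized=normalized, **kw)


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def default_study():
    """One simulated blinded study at the default design, seed 1."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_study_result(default_study):
    """The default study pushed through the full pipeline."""
    return run_study(default_study, PipelineConfig())
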
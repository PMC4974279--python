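import numpy as np
import pytest

from approachscan import AnalysisConfig, GratingSpec, Protocol, build_trajectory


@pytest.fixture(scope="session")
def short_protocol() -> Protocol:
    """Small fast protocol for unit tests where the exact geometry is irrelevant:
    1.0 -> 0.1 m at 10 mm/s (90 s approach), short dwells."""
    return Protocol(1000.0, 100.0, 10.0, dwell_start_s=10.0, dwell_end_s=5.0, name="short")


@pytest.fixture(scope="session")
def short_trajectory(short_protocol):
    return build_trajectory(short_protocol)


@pytest.fixture(scope="session")
def fast_cfg() -> AnalysisConfig:
    """Coarser step and fewer resamples for cheap unit tests."""
    return AnalysisConfig(step_s=0.1, bootstrap_n=300)


@pytest.fixture(scope="session")
def gratings_distant():
    return [GratingSpec(38.0, "1F"), GratingSpec(19.0, "2F")]
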
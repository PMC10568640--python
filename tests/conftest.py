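import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from myodiff.fcs_io import ChannelInfo, Sample
from myodiff.pipeline import AnalysisConfig
from myodiff.simulator import SimConfig, simulate_experiment

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_sample(events, channel_names=("FSC-HLin", "SSC-HLin", "GRN-B-HLin", "RED-R-HLin"),
                sample_id="s1", well_id=None, **kw):
    """Build a Sample from a plain event matrix."""
    events = np.atleast_2d(np.asarray(events, dtype=np.float64))
    channels = [ChannelInfo(name=n, index=i + 1) for i, n in enumerate(channel_names)]
    return Sample(sample_id=sample_id, events=events, channels=channels, well_id=well_id, **kw)


@pytest.fixture(scope="session")
def default_experiment():
    """One fully simulated experiment at the default study conditions."""
    return simulate_experiment(SimConfig(seed=11))


@pytest.fixture
def analysis_config():
    return AnalysisConfig()
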
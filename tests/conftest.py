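import numpy as np
import pytest

from flowdedup.distance import DistanceConfig
from flowdedup.flow_model import default_parametric_model
from flowdedup.flowgram_io import Flowgram
from flowdedup.simulate import SimConfig, simulate_run


@pytest.fixture(scope="session")
def model():
    return default_parametric_model()


@pytest.fixture(scope="session")
def dist_cfg(model):
    return DistanceConfig(model=model)


@pytest.fixture(scope="session")
def small_run():
    """100 reads, 20% duplicates, default noise, fixed seed."""
    cfg = SimConfig(n_templates=80, duplicate_rate=0.2, seed=42)
    return simulate_run(cfg)


def tiny_sim_config(**kwargs) -> SimConfig:
    """Small, fast simulation settings shared across tests."""
    defaults = dict(
        n_templates=3,
        duplicate_rate=0.5,
        read_length_flows=(40.0, 10.0),
        min_length_flows=20,
        n_flows=80,
        genome_length=2000,
        seed=0,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


def make_flowgram(values, read_id="fg", key="TCAG", clip_left=0, clip_right=0,
                  **kwargs) -> Flowgram:
    """Flowgram over a TACG cycle long enough for the given values."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    order = ("TACG" * (n // 4 + 1))[:n]
    return Flowgram(
        read_id=read_id, flow_values=values, flow_order=order,
        key_sequence=key, clip_left=clip_left, clip_right=clip_right, **kwargs,
    )
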
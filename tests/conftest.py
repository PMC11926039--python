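import numpy as np
import pytest

from cpraqa.scoring import Thresholds
from cpraqa.simulate import QualityParams, SimulationConfig, ViewConfig
from cpraqa.skeleton import PoseSequence, get_topology


@pytest.fixture(scope="session")
def graph17():
    return get_topology("reduced-17")


@pytest.fixture(scope="session")
def graph33():
    return get_topology("mediapipe-33")


@pytest.fixture
def thresholds():
    return Thresholds()


def clean_config(seed=0, **kw):
    """Single noise-free, occlusion-free view; reduced topology."""
    kw.setdefault("views", (ViewConfig("1", 0.0, 0.0),))
    kw.setdefault("topology", "reduced-17")
    return SimulationConfig(seed=seed, **kw)


@pytest.fixture
def clean_cfg():
    return clean_config()


def short_params(**kw):
    """Two cycles of twelve compressions: fast but still scoreable."""
    kw.setdefault("n_cycles", 2)
    kw.setdefault("compressions_per_cycle", 12)
    kw.setdefault("pause_s", 4.0)
    return QualityParams(**kw)


def make_seq(data, fps=30.0, view_id="1", mask=None):
    return PoseSequence(view_id, fps, np.asarray(data, dtype=float), mask)


def still_pose(graph, T, fps=30.0):
    """A motionless plausible kneeling pose for the given topology."""
    rng = np.random.default_rng(0)
    base = rng.uniform(-0.5, 0.8, size=(graph.N, 3))
    data = np.zeros((T, graph.N, 4))
    data[:, :, :3] = base
    data[:, :, 3] = 0.9
    return make_seq(data, fps=fps)
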
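import warnings

import numpy as np
import pytest

from kinegraph.benchmarks import generate_pair_model, render_synthetic_video
from kinegraph.discovery import DiscoveryConfig, run

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def pair_model_a():
    """Autonomous AR source driving a target: vanishing reverse transfer
    entropy, temporal v-structure at the target."""
    return generate_pair_model("a", T=10_000, seed=3)


@pytest.fixture(scope="session")
def pair_model_b():
    """Same plus a lagged feedback edge: the v-structure coexists with a
    positive reverse transfer entropy."""
    return generate_pair_model("b", T=10_000, seed=3)


@pytest.fixture(scope="session")
def discovered_a(pair_model_a):
    net, ds = pair_model_a
    summary, unfolded, decisions = run(ds, DiscoveryConfig(tau=2, delta_tau=1))
    return net, summary, unfolded, decisions


@pytest.fixture(scope="session")
def discovered_b(pair_model_b):
    net, ds = pair_model_b
    summary, unfolded, decisions = run(ds, DiscoveryConfig(tau=2, delta_tau=1))
    return net, summary, unfolded, decisions


@pytest.fixture(scope="session")
def small_video():
    """12-frame synthetic crop with one central cancer cell and 6 immune."""
    return render_synthetic_video(n_immune=6, n_frames=12, seed=4)
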
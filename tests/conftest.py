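import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import msephys as m

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def epochs_300():
    """Alternating 30 s REST/RUN blocks over 300 s."""
    return m.make_epochs(300.0)


@pytest.fixture(scope="session")
def teevra_session(epochs_300):
    """One strongly rhythmic 7 Hz bursting unit plus its LFP ground truth."""
    lfp, truth = m.generate_lfp(m.LfpSpec(seed=11), epochs_300)
    spec = m.UnitSpec(archetype="teevra", rate_rest=30.0, rate_run=30.0, seed=12)
    train = m.generate_unit(spec, epochs_300, truth["trough_times"],
                            unit_id="teevra-0")
    return train, epochs_300, lfp, truth


def poisson_train(rate_hz: float, duration_s: float, seed: int,
                  unit_id: str = "poisson") -> m.SpikeTrain:
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration_s)
    t = np.sort(rng.uniform(0.0, duration_s, n))
    t = t[np.concatenate([[True], np.diff(t) > 0])]
    return m.SpikeTrain(unit_id, t, 0.0, duration_s)
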
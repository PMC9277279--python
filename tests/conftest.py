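import numpy as np
import pytest

from quakecall.detector import default_templates
from quakecall.synth import ScenarioConfig, gen_scenario

STANDARD_FIXTURE_SEED = 7  # Poisson draw gives exactly 50 D calls


@pytest.fixture(scope="session")
def templates():
    return default_templates(2000.0)


@pytest.fixture(scope="session")
def standard_scenario():
    """The standard detector-validation fixture: 2 h, 50 injected D calls at
    high SNR over song chorus and background noise, fully seeded."""
    cfg = ScenarioConfig(duration_s=2 * 3600.0, dcall_rate_before=25.0,
                         dcall_rate_after=25.0, seed=STANDARD_FIXTURE_SEED)
    recording, truth, catalog, stations = gen_scenario(cfg)
    dcalls = truth[truth["kind"] == "dcall"]
    assert len(dcalls) == 50
    return {"config": cfg, "recording": recording, "truth": truth,
            "catalog": catalog, "stations": stations, "dcalls": dcalls}


@pytest.fixture(scope="session")
def noise_audio():
    """30 min of seeded Gaussian background noise (no injected signals)."""
    from quakecall.signal import AudioSegment
    rng = np.random.default_rng(1234)
    return AudioSegment(rng.normal(0.0, 0.02, 1800 * 2000), 2000.0)
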
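import logging

import pytest

import synerkit as sk
from synerkit.synthetic_data import (
    REFERENCE_DOSE_EFFECT,
    REFERENCE_SINGLE_AGENT_FITS,
)

# the flagged-point warnings are expected in several tests; keep output clean
logging.getLogger("synerkit").setLevel(logging.ERROR)

AGENTS = tuple(sorted(REFERENCE_DOSE_EFFECT))


@pytest.fixture(scope="session")
def reference_fits():
    """Median-effect fits of the four published single-agent dose-effect tables."""
    return {
        agent: sk.fit_median_effect(sk.reference_dose_effect_points(agent))
        for agent in AGENTS
    }


@pytest.fixture(scope="session")
def published_fits():
    """Curves built directly from the published (Dm, m) parameters."""
    return {
        agent: sk.MedianEffectFit.from_parameters(
            agent, p["Dm"], p["m"], p["unit"]
        )
        for agent, p in REFERENCE_SINGLE_AGENT_FITS.items()
    }
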
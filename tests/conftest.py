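import numpy as np
import pytest

from retinfo import quantal, synth
from retinfo.quantal import DeconvolutionKernel, SpatialComponent
from retinfo.regimes import StimulusProtocol, configure_cohort


@pytest.fixture(scope="session")
def kernel():
    return DeconvolutionKernel()


@pytest.fixture(scope="session")
def cohort():
    return configure_cohort()


@pytest.fixture(scope="session")
def component():
    return SpatialComponent(center=6.0, width=1.2, amplitude=1.0)


@pytest.fixture(scope="session")
def render_synapse(kernel, component):
    """Simulate and render one synapse; returns (train, recording)."""

    def _make(regime, contrast, duration, seed, **render_kw):
        protocol = StimulusProtocol.constant(contrast, duration)
        train = synth.simulate_release(regime, protocol, seed)
        rec = synth.render_linescan(
            train, [component], kernel, regime, seed=seed + 10_000, **render_kw
        )
        return train, rec

    return _make


@pytest.fixture(scope="session")
def decomposed_pm(cohort, kernel, render_synapse):
    """A batch of decomposed afternoon-regime recordings at 100% contrast,
    shared across tests to keep the suite fast."""
    out = []
    for s in range(6):
        train, rec = render_synapse(cohort["pm"].synapse, 100.0, 20.0, 300 + s)
        series, diag = quantal.decompose_recording(rec, kernel)
        out.append((train, rec, series, diag))
    return out
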
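"""Shared fixtures: one full synthetic recovery run reused across test modules."""

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import photoflux as pf
from photoflux.synthetic import GroundTruth, transient_kernel_peak_delay_s

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@dataclass
class RecoveryRun:
    """End-to-end pipeline output for the default 600 s baseline session."""

    config: pf.SimulationConfig
    truth: GroundTruth
    session: pf.PhotometrySession
    dff: pf.DffTrace
    z: pf.ZTrace
    transients: object
    kernel_peak_delay_s: float

    @property
    def n(self) -> int:
        return min(len(self.dff), self.truth.true_dff.size)


@pytest.fixture(scope="session")
def recovery600() -> RecoveryRun:
    """Default 600 s session (0.5 Hz transients, motion, bleach), fully processed."""
    config = pf.SimulationConfig()  # duration 600 s, seed 0
    raw, truth = pf.generate_session(config)
    session = pf.demodulate_session(raw)
    dff, z = pf.process_session(session)
    transients = pf.detect_transients(z)
    return RecoveryRun(
        config=config,
        truth=truth,
        session=session,
        dff=dff,
        z=z,
        transients=transients,
        kernel_peak_delay_s=transient_kernel_peak_delay_s(config),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
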
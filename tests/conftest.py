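import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import clamap as cm

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def protocol() -> cm.LightProtocol:
    return cm.LightProtocol()


@pytest.fixture(scope="session")
def reference():
    return cm.load_reference_table()


@pytest.fixture(scope="session")
def effects_table(protocol):
    """Effect table calibrated to the packaged reference strengths."""
    return cm.calibrate_effects_from_fixture(protocol=protocol)


@pytest.fixture(scope="session")
def study_dataset(effects_table, protocol):
    """Full study-design dataset: 35 circuits x 2 subtypes x 15 cells."""
    return cm.generate_dataset(effects_table, design=15, protocol=protocol, seed=0)


@pytest.fixture(scope="session")
def study_metrics(study_dataset, protocol):
    return cm.cell_metrics_table(study_dataset, protocol)


@pytest.fixture(scope="session")
def study_matrix(study_metrics):
    return cm.assemble_matrix(study_metrics)


def make_trace(
    samples: np.ndarray,
    sampling_rate: float = 10_000.0,
    pulse_onsets: tuple[float, ...] = (100.0, 250.0, 400.0),
    intensity: float = 3.0,
) -> cm.VoltageTrace:
    return cm.VoltageTrace(np.asarray(samples, dtype=float), sampling_rate, pulse_onsets, intensity)


def trace_with_spikes(
    spike_times_ms: list[float],
    baseline: float = -70.0,
    duration_ms: float = 650.0,
    sampling_rate: float = 10_000.0,
    peak: float = 30.0,
    width_ms: float = 1.0,
    pulse_onsets: tuple[float, ...] = (100.0, 250.0, 400.0),
) -> cm.VoltageTrace:
    """Flat trace with stereotyped triangular spikes at the given times."""
    n = int(round(duration_ms * sampling_rate / 1000.0))
    v = np.full(n, baseline)
    n_w = int(round(width_ms * sampling_rate / 1000.0))
    for t in spike_times_ms:
        i0 = int(round(t * sampling_rate / 1000.0))
        apex = i0 + n_w // 2
        v[i0 : apex + 1] = np.linspace(baseline, peak, apex - i0 + 1)
        v[apex : i0 + n_w + 1] = np.linspace(peak, baseline, n_w - n_w // 2 + 1)
    return make_trace(v, sampling_rate, pulse_onsets)
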
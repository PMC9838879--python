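"""Light-stimulation protocol and neuron parameter containers.

The mapping protocol delivers three 5 ms blue-light pulses at 150 ms
intervals while a claustrum projection neuron is held in current clamp and
digitized at 10 kHz. Each cell is swept once per light intensity, including
a 0 mW (no-light) sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigurationError

DEFAULT_INTENSITIES: tuple[float, ...] = (0.0, 0.6, 1.2, 1.8, 2.4, 3.0)


@dataclass(frozen=True)
class LightProtocol:
    """Pulse-train stimulation protocol for one sweep.

    Times are in ms, rates in Hz, light intensities in mW. The sweep layout
    is a pre-stimulus baseline, ``n_pulses`` pulse windows spaced by
    ``inter_pulse_interval``, and a tail long enough to contain the decay of
    the last response.
    """

    n_pulses: int = 3
    pulse_duration: float = 5.0
    inter_pulse_interval: float = 150.0
    intensities: tuple[float, ...] = DEFAULT_INTENSITIES
    sampling_rate: float = 10_000.0
    sweep_duration: float = 650.0
    pre_stimulus_baseline: float = 100.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be > 0")
        if self.n_pulses < 1:
            raise ConfigurationError("n_pulses must be >= 1")
        if any(i < 0 for i in self.intensities):
            raise ConfigurationError("intensities must be non-negative")
        if 0.0 not in self.intensities:
            raise ConfigurationError("intensities must include the 0 mW (no-light) sweep")
        if self.pulse_duration >= self.inter_pulse_interval:
            raise ConfigurationError("pulse windows overlap: pulse_duration >= inter_pulse_interval")
        last_end = self.pulse_onsets[-1] + self.pulse_duration
        if last_end > self.sweep_duration:
            raise ConfigurationError("pulse train does not fit inside the sweep")

    @property
    def pulse_onsets(self) -> tuple[float, ...]:
        """Pulse onset times (ms), spaced by the inter-pulse interval."""
        return tuple(
            self.pre_stimulus_baseline + p * self.inter_pulse_interval for p in range(self.n_pulses)
        )

    @property
    def n_samples(self) -> int:
        return int(round(self.sweep_duration * self.sampling_rate / 1000.0))

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms

    def sample_index(self, t_ms: float) -> int:
        return int(round(t_ms * self.sampling_rate / 1000.0))


@dataclass(frozen=True)
class NeuronParams:
    """Phenomenological parameters of a claustrum projection neuron.

    Type I neurons fire a single action potential to a brief depolarizing
    step; type II neurons burst (>1 spike). Membrane capacitance ranges
    (type I ~75-130 pF, type II ~130-200 pF) corroborate the classification.
    Hyperpolarizing responses are bounded below by the -75 mV inhibitory
    (GABA-A) reversal potential.
    """

    subtype: str = "I"
    resting_vm: float = -70.0  # mV
    ap_threshold: float = -40.0  # mV
    spike_peak: float = 30.0  # mV
    spike_width: float = 1.0  # ms
    burst_spike_count: int = 1
    burst_interval: float = 3.0  # ms between spikes within a burst
    membrane_capacitance: float = 100.0  # pF
    gaba_reversal: float = -75.0  # mV
    noise_sd: float = 0.5  # mV
    epsp_rise_tau: float = 2.0  # ms
    epsp_decay_tau: float = 50.0  # ms

    def __post_init__(self) -> None:
        if self.subtype not in ("I", "II"):
            raise ConfigurationError(f"unknown subtype {self.subtype!r}")
        if self.subtype == "I" and self.burst_spike_count != 1:
            raise ConfigurationError("type I neurons fire single spikes (burst_spike_count must be 1)")
        if self.subtype == "II" and self.burst_spike_count < 2:
            raise ConfigurationError("type II neurons burst (burst_spike_count must be >= 2)")
        if self.epsp_rise_tau <= 0 or self.epsp_decay_tau <= self.epsp_rise_tau:
            raise ConfigurationError("require 0 < epsp_rise_tau < epsp_decay_tau")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.gaba_reversal >= self.resting_vm:
            raise ConfigurationError("gaba_reversal must lie below resting_vm")


CAPACITANCE_RANGE: dict[str, tuple[float, float]] = {"I": (75.0, 130.0), "II": (130.0, 200.0)}


def default_neuron(subtype: str, **overrides) -> NeuronParams:
    """Default parameter set for a subtype (type II bursts with 3 spikes)."""
    lo, hi = CAPACITANCE_RANGE[subtype]
    base = NeuronParams(
        subtype=subtype,
        burst_spike_count=1 if subtype == "I" else 3,
        membrane_capacitance=0.5 * (lo + hi),
    )
    return replace(base, **overrides) if overrides else base
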
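"""Synthetic optogenetic current-clamp trace and dataset generation.

The response model is deliberately phenomenological. Each light pulse
injects a difference-of-exponentials depolarization kernel (peak-normalized)
scaled by ``weight x intensity``; the kernel's slow decay stands in for the
compound mono- and polysynaptic envelope seen in these recordings. Firing is
decided deterministically on the noiseless drive: a cell spikes on a pulse
when ``spike_gain x weight x intensity`` (times the per-pulse kernel peak)
reaches the distance from rest to the action-potential threshold. Type II
neurons emit a stereotyped burst per suprathreshold event, type I a single
spike. Gaussian noise is added to the membrane potential; hyperpolarizing
excursions are floored at the inhibitory reversal potential; spikes are
superimposed as brief triangular excursions to the spike peak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .effects import EffectTable, SynapticEffect
from .exceptions import DataIntegrityError, ProtocolMismatchError
from .protocol import CAPACITANCE_RANGE, LightProtocol, NeuronParams, default_neuron
from .regions import CircuitSpec, validate_circuit


@dataclass(frozen=True)
class VoltageTrace:
    """One current-clamp sweep: membrane potential (mV) plus its protocol."""

    samples: np.ndarray
    sampling_rate: float
    pulse_onsets: tuple[float, ...]
    intensity: float

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    def time_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt_ms


@dataclass
class CellRecord:
    """One recorded neuron: circuit labels, per-intensity sweeps, QC metadata."""

    cell_id: str
    circuit: CircuitSpec
    subtype: str
    traces: dict[float, VoltageTrace]
    step_response: VoltageTrace
    qc: dict[str, float]
    membrane_capacitance: float
    weight: float = 0.0  # realized per-cell synaptic weight (mV/mW)


def epsp_kernel(t_ms: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Peak-normalized difference-of-exponentials kernel, zero for t < 0."""
    t = np.asarray(t_ms, dtype=float)
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    out = np.where(t >= 0.0, np.exp(-np.clip(t, 0, None) / decay_tau) - np.exp(-np.clip(t, 0, None) / rise_tau), 0.0)
    return out / peak


def kernel_integral(rise_tau: float, decay_tau: float) -> float:
    """Closed-form integral (ms) of the peak-normalized kernel over [0, inf)."""
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    return (decay_tau - rise_tau) / peak


@lru_cache(maxsize=32)
def _unit_envelope_cached(protocol: LightProtocol, rise_tau: float, decay_tau: float) -> np.ndarray:
    t = protocol.time_ms()
    env = np.zeros(protocol.n_samples)
    for onset in protocol.pulse_onsets:
        env += epsp_kernel(t - onset, rise_tau, decay_tau)
    env.setflags(write=False)
    return env


def unit_envelope(protocol: LightProtocol, neuron: NeuronParams) -> np.ndarray:
    """Noiseless response to unit weight at unit intensity (mV)."""
    return _unit_envelope_cached(protocol, neuron.epsp_rise_tau, neuron.epsp_decay_tau)


def unit_pulse_peaks(protocol: LightProtocol, neuron: NeuronParams) -> np.ndarray:
    """Per-pulse maximum of the unit envelope within each pulse window.

    Later pulses ride on the decaying tails of earlier ones, so their peaks
    slightly exceed 1; the spike-gain calibration uses these exact values.
    """
    env = unit_envelope(protocol, neuron)
    peaks = []
    for onset in protocol.pulse_onsets:
        i0 = protocol.sample_index(onset)
        i1 = protocol.sample_index(onset + protocol.inter_pulse_interval)
        peaks.append(env[i0:min(i1, env.size)].max())
    return np.asarray(peaks)


def _insert_spike(v: np.ndarray, i0: int, n_w: int, peak: float) -> None:
    """Superimpose a triangular spike starting at sample i0 over n_w samples."""
    i_end = min(i0 + n_w, v.size - 1)
    apex = min(i0 + max(n_w // 2, 1), i_end)
    if apex > i0:
        v[i0 : apex + 1] = np.linspace(v[i0], peak, apex - i0 + 1)
    else:
        v[apex] = peak
    if i_end > apex:
        v[apex : i_end + 1] = np.linspace(peak, v[i_end], i_end - apex + 1)


def _spike_times(
    effect: SynapticEffect, neuron: NeuronParams, intensity: float, protocol: LightProtocol
) -> list[float]:
    """Deterministic spike times from the noiseless gain-scaled drive.

    A pulse fires when the drive reaches the threshold distance from rest;
    if the drive additionally reaches ``burst_drive_ratio`` times that level
    the cell emits its full burst (type II), otherwise a single spike.
    """
    if effect.spike_gain <= 0.0 or effect.weight <= 0.0 or intensity <= 0.0:
        return []
    theta = neuron.ap_threshold - neuron.resting_vm
    drive = effect.spike_gain * effect.weight * intensity * unit_envelope(protocol, neuron)
    times: list[float] = []
    for onset in protocol.pulse_onsets:
        i0 = protocol.sample_index(onset)
        i1 = min(protocol.sample_index(onset + protocol.inter_pulse_interval), drive.size)
        seg = drive[i0:i1]
        above = np.nonzero(seg >= theta)[0]
        if above.size == 0:
            continue
        t_cross = (i0 + above[0]) * protocol.dt_ms
        bursts = neuron.burst_spike_count > 1 and seg.max() >= effect.burst_drive_ratio * theta
        n_spikes = neuron.burst_spike_count if bursts else 1
        for k in range(n_spikes):
            times.append(t_cross + k * neuron.burst_interval)
    return times


def generate_trace(
    effect: SynapticEffect,
    neuron: NeuronParams,
    intensity: float,
    protocol: LightProtocol,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> VoltageTrace:
    """Simulate one sweep at one light intensity.

    With zero weight and zero noise the trace is flat at the resting
    potential; in the subthreshold regime the response is exactly
    ``weight x intensity x`` the pulse-train kernel envelope.
    """
    if intensity not in protocol.intensities:
        raise ProtocolMismatchError(
            f"intensity {intensity} mW is not part of the protocol {protocol.intensities}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    v = neuron.resting_vm + effect.weight * intensity * unit_envelope(protocol, neuron)
    if neuron.noise_sd > 0:
        v = v + rng.normal(0.0, neuron.noise_sd, size=v.size)
    else:
        v = v.copy()
    np.maximum(v, neuron.gaba_reversal, out=v)  # inhibitory reversal floor
    n_w = max(int(round(neuron.spike_width * protocol.sampling_rate / 1000.0)), 2)
    for t_s in _spike_times(effect, neuron, intensity, protocol):
        _insert_spike(v, protocol.sample_index(t_s), n_w, neuron.spike_peak)
    return VoltageTrace(v, protocol.sampling_rate, protocol.pulse_onsets, intensity)


STEP_SWEEP_MS = 200.0
STEP_ONSET_MS = 50.0
STEP_DURATION_MS = 2.0


def generate_step_response(
    neuron: NeuronParams,
    sampling_rate: float = 10_000.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> VoltageTrace:
    """Sweep for the subtype-classification protocol.

    A brief depolarizing step elicits one spike from type I neurons and a
    burst from type II neurons; every projection neuron spikes to the step.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(STEP_SWEEP_MS * sampling_rate / 1000.0))
    v = np.full(n, neuron.resting_vm)
    if neuron.noise_sd > 0:
        v += rng.normal(0.0, neuron.noise_sd, size=n)
    n_w = max(int(round(neuron.spike_width * sampling_rate / 1000.0)), 2)
    for k in range(neuron.burst_spike_count):
        t_s = STEP_ONSET_MS + STEP_DURATION_MS + k * neuron.burst_interval
        _insert_spike(v, int(round(t_s * sampling_rate / 1000.0)), n_w, neuron.spike_peak)
    return VoltageTrace(v, sampling_rate, (STEP_ONSET_MS,), 0.0)


def _lognormal_weights(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Positive weights with given mean and coefficient of variation."""
    if cv == 0.0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _sanitize(region: str) -> str:
    return region.replace("/", "")


def generate_dataset(
    effects: EffectTable,
    design: int = 15,
    protocol: LightProtocol | None = None,
    seed: int | None = None,
    subtypes: tuple[str, ...] = ("I", "II"),
    neuron_overrides: dict | None = None,
    contamination_rate: float = 0.0,
) -> list[CellRecord]:
    """Simulate ``design`` cells per subtype for every circuit in the table.

    The default design replicates the study layout: 35 circuits x 2 subtypes
    x 15 cells = 1,050 records. Identical seeds produce identical datasets.
    QC metadata are clean by default; with ``contamination_rate`` > 0 a
    fraction of cells carries a disqualifying drift or resistance change.
    """
    if design < 1:
        raise DataIntegrityError("design must be >= 1 cell per subtype per circuit")
    protocol = protocol or LightProtocol()
    neuron_overrides = neuron_overrides or {}
    root_ss = np.random.SeedSequence(seed)
    records: list[CellRecord] = []
    combos = [(c, s) for c in effects.circuits for s in subtypes]
    cell_streams = root_ss.spawn(len(combos) * design)
    idx = 0
    for circuit, subtype in combos:
        effect = effects[(circuit, subtype)]
        neuron = default_neuron(subtype, **neuron_overrides)
        for j in range(design):
            rng = np.random.default_rng(cell_streams[idx])
            cap = rng.uniform(*CAPACITANCE_RANGE[subtype])
            if effect.weight == 0.0:
                w_cell = 0.0
            else:
                w_cell = float(np.sign(effect.weight)) * float(
                    _lognormal_weights(rng, abs(effect.weight), effect.weight_cv, 1)[0]
                )
            cell_effect = replace(effect, weight=w_cell)
            cell_neuron = replace(neuron, membrane_capacitance=cap)
            traces = {
                inten: generate_trace(cell_effect, cell_neuron, inten, protocol, rng=rng)
                for inten in protocol.intensities
            }
            step = generate_step_response(cell_neuron, protocol.sampling_rate, rng=rng)
            if contamination_rate > 0 and rng.random() < contamination_rate:
                if rng.random() < 0.5:
                    qc = {
                        "vm_drift": rng.uniform(10.5, 20.0),
                        "access_resistance_change": rng.uniform(0.0, 0.05),
                        "membrane_resistance_change": rng.uniform(0.0, 0.05),
                    }
                else:
                    qc = {
                        "vm_drift": rng.uniform(0.0, 5.0),
                        "access_resistance_change": rng.uniform(0.16, 0.5),
                        "membrane_resistance_change": rng.uniform(0.0, 0.05),
                    }
            else:
                qc = {
                    "vm_drift": rng.uniform(0.0, 5.0),
                    "access_resistance_change": rng.uniform(0.0, 0.05),
                    "membrane_resistance_change": rng.uniform(0.0, 0.05),
                }
            cell_id = (
                f"c{idx:04d}_{_sanitize(circuit.input_region)}_"
                f"{_sanitize(circuit.output_region)}_{subtype}"
            )
            records.append(
                CellRecord(cell_id, circuit, subtype, traces, step, qc, cap, w_cell)
            )
            idx += 1
    return records


# ---------------------------------------------------------------------------
# dataset container: HDF5 (one group per cell) plus a flat CSV manifest
# ---------------------------------------------------------------------------

def save_dataset(records: list[CellRecord], path: str | Path, protocol: LightProtocol | None = None) -> None:
    protocol = protocol or LightProtocol()
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["protocol"] = json.dumps(
            {
                "n_pulses": protocol.n_pulses,
                "pulse_duration": protocol.pulse_duration,
                "inter_pulse_interval": protocol.inter_pulse_interval,
                "intensities": list(protocol.intensities),
                "sampling_rate": protocol.sampling_rate,
                "sweep_duration": protocol.sweep_duration,
                "pre_stimulus_baseline": protocol.pre_stimulus_baseline,
            }
        )
        for rec in records:
            g = f.create_group(rec.cell_id)
            g.attrs["input"] = rec.circuit.input_region
            g.attrs["output"] = rec.circuit.output_region
            g.attrs["subtype"] = rec.subtype
            g.attrs["membrane_capacitance"] = rec.membrane_capacitance
            g.attrs["weight"] = rec.weight
            for k, v in rec.qc.items():
                g.attrs[f"qc_{k}"] = v
            for i, inten in enumerate(protocol.intensities):
                g.create_dataset(f"sweep_{i:02d}", data=rec.traces[inten].samples.astype(np.float32))
            g.create_dataset("step_response", data=rec.step_response.samples.astype(np.float32))


def load_dataset(path: str | Path) -> tuple[list[CellRecord], LightProtocol]:
    path = Path(path)
    records: list[CellRecord] = []
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["protocol"])
        protocol = LightProtocol(
            n_pulses=int(meta["n_pulses"]),
            pulse_duration=meta["pulse_duration"],
            inter_pulse_interval=meta["inter_pulse_interval"],
            intensities=tuple(meta["intensities"]),
            sampling_rate=meta["sampling_rate"],
            sweep_duration=meta["sweep_duration"],
            pre_stimulus_baseline=meta["pre_stimulus_baseline"],
        )
        for cell_id in sorted(f.keys()):
            g = f[cell_id]
            circuit = CircuitSpec(str(g.attrs["input"]), str(g.attrs["output"]))
            validate_circuit(circuit)
            traces = {
                inten: VoltageTrace(
                    np.asarray(g[f"sweep_{i:02d}"], dtype=float),
                    protocol.sampling_rate,
                    protocol.pulse_onsets,
                    inten,
                )
                for i, inten in enumerate(protocol.intensities)
            }
            step = VoltageTrace(
                np.asarray(g["step_response"], dtype=float), protocol.sampling_rate, (STEP_ONSET_MS,), 0.0
            )
            qc = {k[3:]: float(g.attrs[k]) for k in g.attrs if k.startswith("qc_")}
            records.append(
                CellRecord(
                    cell_id,
                    circuit,
                    str(g.attrs["subtype"]),
                    traces,
                    step,
                    qc,
                    float(g.attrs["membrane_capacitance"]),
                    float(g.attrs["weight"]),
                )
            )
    return records, protocol


def dataset_manifest(records: list[CellRecord]) -> pd.DataFrame:
    """Flat per-cell manifest (cell_id, circuit labels, QC fields)."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "input": [r.circuit.input_region for r in records],
            "output": [r.circuit.output_region for r in records],
            "subtype": [r.subtype for r in records],
            "membrane_capacitance": [r.membrane_capacitance for r in records],
            "vm_drift": [r.qc["vm_drift"] for r in records],
            "access_resistance_change": [r.qc["access_resistance_change"] for r in records],
            "membrane_resistance_change": [r.qc["membrane_resistance_change"] for r in records],
        }
    )
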
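"""Calibration of the effect table to the packaged reference strengths.

The packaged fixture (``data/circuit_strength_reference.csv``) holds the
published per-circuit, per-subtype mean AUC and APs-per-pulse values. The
noiseless sweep envelope is linear in the synaptic weight, so the weight for
each combination is the target mean AUC divided by the measured unit-weight
AUC constant. The spike gain is then solved so that the population
expectation of APs per pulse (over the lognormal between-cell weight
distribution) equals the APs target. Because spikes are included in the
integral, a short fixed-point refinement against the noiseless forward map
then absorbs the action-potential waveform area into the weight, so the
noiseless simulate-then-measure round trip reproduces the AUC targets to
well under the 5% calibration tolerance.
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import lognorm

from .effects import EffectTable, SynapticEffect
from .exceptions import CalibrationError
from .metrics import default_windows, trace_auc
from .protocol import LightProtocol, NeuronParams, default_neuron
from .regions import SUBTYPES, CircuitSpec, enumerate_circuits
from .simulate import generate_trace, unit_pulse_peaks

REFERENCE_CSV = "circuit_strength_reference.csv"


def load_reference_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged (or an external) circuit-strength reference table.

    Columns: metric {auc, aps}, subtype {I, II}, input, output, mean, sem, n.
    """
    if path is not None:
        df = pd.read_csv(path)
    else:
        with resources.files("clamap.data").joinpath(REFERENCE_CSV).open() as fh:
            df = pd.read_csv(fh)
    required = {"metric", "subtype", "input", "output", "mean", "sem", "n"}
    if not required.issubset(df.columns):
        raise CalibrationError(f"reference table missing columns {sorted(required - set(df.columns))}")
    return df


def unit_auc_constant(protocol: LightProtocol, neuron: NeuronParams) -> float:
    """Intensity-averaged AUC (mV*ms) of the noiseless unit-weight response.

    Measured with the same trapezoidal integration and windows the analysis
    uses, so calibration and measurement agree by construction.
    """
    quiet = replace(neuron, noise_sd=0.0)
    baseline, response = default_windows(protocol)
    eff = SynapticEffect(weight=1.0, weight_cv=0.0, spike_gain=0.0)
    aucs = [
        trace_auc(generate_trace(eff, quiet, i, protocol, seed=0), baseline, response)
        for i in protocol.intensities
    ]
    return float(np.mean(aucs))


def _crossing_prob_sum(
    gain: float,
    weight_mean: float,
    weight_cv: float,
    threshold: float,
    protocol: LightProtocol,
    pulse_peaks: np.ndarray,
) -> float:
    """Sum over (intensity > 0, pulse) of P(gain * w * I * peak_p >= threshold)
    for lognormal cell weights with the given mean and CV."""
    if gain <= 0 or weight_mean <= 0:
        return 0.0
    intensities = np.array([i for i in protocol.intensities if i > 0])
    level = gain * weight_mean * intensities[:, None] * pulse_peaks[None, :]
    if weight_cv == 0.0:
        return float((level >= threshold).sum())
    sigma = np.sqrt(np.log1p(weight_cv**2))
    scale = weight_mean / np.sqrt(1 + weight_cv**2)  # exp(mu)
    cut = threshold / (gain * intensities[:, None] * pulse_peaks[None, :])
    return float(lognorm.sf(cut, s=sigma, scale=scale).sum())


def expected_aps_per_pulse(
    gain: float,
    weight_mean: float,
    weight_cv: float,
    burst_spike_count: int,
    theta: float,
    protocol: LightProtocol,
    pulse_peaks: np.ndarray,
    burst_drive_ratio: float = 1.0,
) -> float:
    """Population expectation of the intensity-averaged APs-per-pulse metric.

    A pulse event (drive over the threshold distance ``theta``) yields one
    spike; a type II cell whose drive also clears ``burst_drive_ratio x
    theta`` emits its full burst instead.
    """
    denom = len(protocol.intensities) * protocol.n_pulses
    events = _crossing_prob_sum(gain, weight_mean, weight_cv, theta, protocol, pulse_peaks)
    if burst_spike_count > 1 and np.isfinite(burst_drive_ratio):
        bursts = _crossing_prob_sum(
            gain, weight_mean, weight_cv, burst_drive_ratio * theta, protocol, pulse_peaks
        )
    else:
        bursts = 0.0
    return (events + (burst_spike_count - 1) * bursts) / denom


def expected_event_rate(
    gain: float,
    weight_mean: float,
    weight_cv: float,
    theta: float,
    protocol: LightProtocol,
    pulse_peaks: np.ndarray,
) -> float:
    """Expected single-spike-equivalent rate (activation reliability): the
    APs-per-pulse metric a non-bursting cell with the same drive would show."""
    denom = len(protocol.intensities) * protocol.n_pulses
    return _crossing_prob_sum(gain, weight_mean, weight_cv, theta, protocol, pulse_peaks) / denom


def _noiseless_mean_auc(
    effect: SynapticEffect, neuron: NeuronParams, protocol: LightProtocol
) -> float:
    """Intensity-averaged AUC of the deterministic (noise-free, CV-free)
    response, spikes included — the forward map the refinement inverts."""
    quiet = replace(neuron, noise_sd=0.0)
    baseline, response = default_windows(protocol)
    aucs = [
        trace_auc(generate_trace(effect, quiet, i, protocol, seed=0), baseline, response)
        for i in protocol.intensities
    ]
    return float(np.mean(aucs))


def _refine_weight(
    weight: float,
    gain: float,
    burst_ratio: float,
    target_auc: float,
    neuron: NeuronParams,
    weight_cv: float,
    protocol: LightProtocol,
    max_iter: int = 4,
    rtol: float = 1e-3,
) -> tuple[float, float]:
    """Fixed-point refinement of the weight against the noiseless forward map.

    The gain is co-scaled so ``gain * weight`` (the firing drive) is
    preserved while the EPSP weight absorbs the spike-waveform area. The
    best iterate is kept in case a spike-count flip makes the map
    discontinuous at the target.
    """
    best = (np.inf, weight, gain)
    for _ in range(max_iter):
        eff = SynapticEffect(weight, weight_cv, gain, burst_ratio)
        measured = _noiseless_mean_auc(eff, neuron, protocol)
        rel = abs(measured - target_auc) / abs(target_auc)
        if rel < best[0]:
            best = (rel, weight, gain)
        if rel < rtol or measured == 0.0 or measured * target_auc <= 0:
            break
        new_weight = weight * target_auc / measured
        gain = gain * weight / new_weight if new_weight != 0 else 0.0
        weight = new_weight
    return best[1], best[2]


def calibrate_effects_from_fixture(
    fixture: pd.DataFrame | None = None,
    protocol: LightProtocol | None = None,
    weight_cv: float = 0.3,
    neuron_overrides: dict | None = None,
    reliability_burst_split: float = 2.0,
    cv_from_fixture: bool = True,
    cv_bounds: tuple[float, float] = (0.1, 1.2),
) -> EffectTable:
    """Build the effect table whose expected metrics match the fixture means.

    aINS-input circuits are forced to zero weight (the published recordings
    show no observable postsynaptic responses for aINS inputs; the nonzero
    aINS AUC entries in the reference are recording noise floor).

    With ``cv_from_fixture`` (default) the between-cell weight CV of each
    combination is taken from the reference table itself, cv = sem * sqrt(n)
    / |mean AUC|, clipped to ``cv_bounds`` (the lognormal weight model cannot
    represent sign-mixed populations, so near-zero-mean circuits are capped).
    ``weight_cv`` is the fallback for silent circuits and the value used when
    ``cv_from_fixture`` is off.

    For type II neurons the APs target is split between activation
    reliability (how often a pulse elicits any spike) and burst
    amplification. The split is not identified by the mean APs alone; the
    rule used is: reliability = min(aps_II, max(``reliability_burst_split``
    x aps_I, aps_II / burst_count)), i.e. type II activates at least as
    reliably as type I (scaled by the split factor) whenever its APs budget
    allows, with the remainder carried by bursts. Where the printed type I
    APs exceed the type II APs the type II reliability is floored at the
    type I level, honoring the finding that no circuit preferentially
    activates type I neurons.
    """
    protocol = protocol or LightProtocol()
    fixture = fixture if fixture is not None else load_reference_table()
    neuron_overrides = neuron_overrides or {}
    if not np.isfinite(fixture["mean"]).all():
        raise CalibrationError("fixture contains non-finite mean values")

    indexed = fixture.set_index(["metric", "subtype", "input", "output"])
    lookup = indexed["mean"]
    sem_lookup = indexed["sem"] if "sem" in indexed.columns else None
    n_lookup = indexed["n"] if "n" in indexed.columns else None
    circuits = enumerate_circuits()
    denom = len(protocol.intensities) * protocol.n_pulses
    rate_max = (len(protocol.intensities) - 1) / len(protocol.intensities)
    effects: dict[tuple[CircuitSpec, str], SynapticEffect] = {}
    for subtype in SUBTYPES:
        neuron = default_neuron(subtype, **neuron_overrides)
        c_unit = unit_auc_constant(protocol, neuron)
        peaks = unit_pulse_peaks(protocol, neuron)
        theta = neuron.ap_threshold - neuron.resting_vm
        b = neuron.burst_spike_count
        for circuit in circuits:
            region_key = (circuit.input_region, circuit.output_region)
            try:
                target_auc = float(lookup[("auc", subtype) + region_key])
                target_aps = float(lookup[("aps", subtype) + region_key])
                aps_type_i = float(lookup[("aps", "I") + region_key])
            except KeyError as exc:
                raise CalibrationError(f"fixture missing combination {exc}") from exc
            if circuit.input_region == "aINS":
                effects[(circuit, subtype)] = SynapticEffect(0.0, weight_cv, 0.0)
                continue
            cv = weight_cv
            if cv_from_fixture and sem_lookup is not None and target_auc != 0.0:
                sem = float(sem_lookup[("auc", subtype) + region_key])
                n_cells = float(n_lookup[("auc", subtype) + region_key]) if n_lookup is not None else 15.0
                if np.isfinite(sem) and sem > 0:
                    cv = float(np.clip(sem * np.sqrt(n_cells) / abs(target_auc), *cv_bounds))
            weight = target_auc / c_unit
            gain, burst_ratio = 0.0, 1.0
            if target_aps > 0:
                if weight <= 0:
                    raise CalibrationError(
                        f"{circuit.label} [{subtype}]: positive APs target with non-positive weight"
                    )
                if b == 1:
                    rate_target, aps_eff = target_aps, target_aps
                else:
                    aps_eff = max(target_aps, aps_type_i)  # reliability parity floor
                    rate_target = min(
                        aps_eff, max(reliability_burst_split * aps_type_i, aps_eff / b)
                    )
                if rate_target >= 0.999 * rate_max:
                    raise CalibrationError(
                        f"{circuit.label} [{subtype}]: event rate target {rate_target:.3f} "
                        f"not attainable (max {rate_max:.3f})"
                    )

                def f_gain(g: float) -> float:
                    return (
                        expected_event_rate(g, weight, cv, theta, protocol, peaks)
                        - rate_target
                    )

                gain = float(brentq(f_gain, 1e-9, 1e9, xtol=1e-12, rtol=1e-12))
                extra = aps_eff - rate_target
                if b > 1 and extra > 1e-12:

                    def f_ratio(k: float) -> float:
                        bursts = _crossing_prob_sum(
                            gain, weight, cv, k * theta, protocol, peaks
                        )
                        return (b - 1) * bursts / denom - extra

                    burst_ratio = 1.0 if f_ratio(1.0) <= 0 else float(brentq(f_ratio, 1.0, 1e6))
                elif b > 1:
                    burst_ratio = 1e9  # reliability carries the whole APs budget
            if target_auc != 0.0:
                weight, gain = _refine_weight(
                    float(weight), gain, burst_ratio, target_auc, neuron, cv, protocol
                )
            effects[(circuit, subtype)] = SynapticEffect(float(weight), cv, gain, burst_ratio)
    return EffectTable(effects, circuits)


def planted_effect_table(
    input_set: tuple[str, ...],
    output_set: tuple[str, ...],
    effect_size: float = 2.0,
    mean_auc: float = 1000.0,
    protocol: LightProtocol | None = None,
) -> EffectTable:
    """Effect table with a planted biclique and silence elsewhere.

    Circuits in ``input_set x output_set`` receive a depolarizing weight whose
    per-cell AUC distribution has a one-sample standardized effect
    (mean / SD) of ``effect_size``: the between-cell CV is set to
    1 / effect_size and the mean AUC is large relative to the integration
    noise floor. All other circuits are silent.
    """
    if effect_size <= 0:
        raise CalibrationError("effect_size must be > 0")
    protocol = protocol or LightProtocol()
    planted = {CircuitSpec(i, o) for i in input_set for o in output_set}
    cv = 1.0 / effect_size
    effects = {}
    for subtype in SUBTYPES:
        c_unit = unit_auc_constant(protocol, default_neuron(subtype))
        w = mean_auc / c_unit
        for circuit in enumerate_circuits():
            if circuit in planted:
                effects[(circuit, subtype)] = SynapticEffect(w, cv, 0.0)
            else:
                effects[(circuit, subtype)] = SynapticEffect(0.0, cv, 0.0)
    return EffectTable(effects)
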
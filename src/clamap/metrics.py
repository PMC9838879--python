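"""Per-trace and per-cell response metrics.

Two synaptic-strength metrics are computed per sweep and averaged across all
light intensities tested (including the 0 mW sweep): the signed trapezoidal
area under the baseline-subtracted voltage curve (AUC, mV*ms; positive for
net depolarization, negative for net hyperpolarization) and the number of
action potentials per light pulse. A binary-response transform (any spike at
a given intensity, averaged across intensities) supports the neuron-subtype
comparisons; QC filtering applies the recording-stability discard rules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DataIntegrityError,
    IncompleteRecordError,
    UnclassifiableError,
)
from .protocol import CAPACITANCE_RANGE, LightProtocol
from .simulate import CellRecord, VoltageTrace

DEFAULT_SPIKE_THRESHOLD = 0.0  # mV
DEFAULT_REFRACTORY = 2.0  # ms
DEFAULT_RESPONSE_WINDOW = 140.0  # ms after each pulse onset


def detect_spikes(
    trace: VoltageTrace,
    threshold: float = DEFAULT_SPIKE_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
) -> np.ndarray:
    """Times (ms) of upward threshold crossings separated by >= refractory."""
    if refractory <= 0:
        raise ConfigurationError("refractory must be > 0")
    v = trace.samples
    if not np.all(np.isfinite(v)):
        raise DataIntegrityError("trace contains non-finite samples")
    crossings = np.nonzero((v[1:] >= threshold) & (v[:-1] < threshold))[0] + 1
    if crossings.size == 0:
        return np.empty(0)
    times = crossings * trace.dt_ms
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def aps_per_pulse(
    trace: VoltageTrace,
    protocol: LightProtocol,
    window: float = DEFAULT_RESPONSE_WINDOW,
    threshold: float = DEFAULT_SPIKE_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
) -> float:
    """Spikes inside the post-onset response windows, divided by n_pulses."""
    if window > protocol.inter_pulse_interval:
        raise ConfigurationError(
            f"response window ({window} ms) overlaps the next pulse "
            f"(interval {protocol.inter_pulse_interval} ms)"
        )
    spikes = detect_spikes(trace, threshold, refractory)
    count = 0
    for onset in protocol.pulse_onsets:
        count += int(np.sum((spikes >= onset) & (spikes <= onset + window)))
    return count / protocol.n_pulses


def _window_slice(trace: VoltageTrace, span: tuple[float, float]) -> slice:
    lo, hi = span
    fs_ms = trace.sampling_rate / 1000.0
    i0, i1 = int(round(lo * fs_ms)), int(round(hi * fs_ms))
    if not (0 <= i0 < i1 <= trace.samples.size):
        raise ConfigurationError(f"window {span} ms falls outside the sweep")
    return slice(i0, i1 + 1 if i1 < trace.samples.size else i1)


def _clip_spike_segments(v: np.ndarray, threshold: float) -> np.ndarray:
    """Replace supra-threshold runs by linear interpolation across them."""
    above = v >= threshold
    if not above.any():
        return v
    v = v.copy()
    idx = np.nonzero(above)[0]
    splits = np.nonzero(np.diff(idx) > 1)[0] + 1
    for run in np.split(idx, splits):
        lo = max(run[0] - 1, 0)
        hi = min(run[-1] + 1, v.size - 1)
        v[lo : hi + 1] = np.linspace(v[lo] if not above[lo] else v[hi], v[hi], hi - lo + 1)
    return v


def trace_auc(
    trace: VoltageTrace,
    baseline_window: tuple[float, float],
    response_window: tuple[float, float],
    clip_spikes: bool = False,
    spike_threshold: float = DEFAULT_SPIKE_THRESHOLD,
) -> float:
    """Signed trapezoidal integral (mV*ms) of the baseline-subtracted trace.

    The baseline is the mean over ``baseline_window`` (which must precede the
    first pulse); the integral runs over ``response_window``. With
    ``clip_spikes`` the action-potential waveforms are interpolated away so
    only the synaptic envelope is integrated.
    """
    if baseline_window[1] > trace.pulse_onsets[0]:
        raise ConfigurationError("baseline window must precede the first pulse onset")
    v = trace.samples
    if not np.all(np.isfinite(v)):
        raise DataIntegrityError("trace contains non-finite samples")
    base = v[_window_slice(trace, baseline_window)]
    resp = v[_window_slice(trace, response_window)]
    if base.size < 2 or resp.size < 2:
        raise ConfigurationError("empty baseline or response window")
    if clip_spikes:
        resp = _clip_spike_segments(resp, spike_threshold)
    return float(np.trapezoid(resp - base.mean(), dx=trace.dt_ms))


def default_windows(
    protocol: LightProtocol, window: float = DEFAULT_RESPONSE_WINDOW
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Default (baseline, response) spans: the pre-stimulus baseline, and
    first pulse onset through ``window`` ms past the last onset."""
    baseline = (0.0, protocol.pulse_onsets[0])
    response = (protocol.pulse_onsets[0], min(protocol.pulse_onsets[-1] + window, protocol.sweep_duration))
    return baseline, response


def binary_response(
    cell: CellRecord,
    protocol: LightProtocol,
    window: float = DEFAULT_RESPONSE_WINDOW,
    threshold: float = DEFAULT_SPIKE_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
) -> float:
    """Mean over intensities of the indicator {>=1 spike in any response window}."""
    missing = [i for i in protocol.intensities if i not in cell.traces]
    if missing:
        raise IncompleteRecordError(f"cell {cell.cell_id} missing intensities {missing}")
    hits = []
    for inten in protocol.intensities:
        spikes = detect_spikes(cell.traces[inten], threshold, refractory)
        hit = any(
            np.any((spikes >= onset) & (spikes <= onset + window)) for onset in protocol.pulse_onsets
        )
        hits.append(float(hit))
    return float(np.mean(hits))


def classify_subtype(
    step_response: VoltageTrace,
    threshold: float = DEFAULT_SPIKE_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
    membrane_capacitance: float | None = None,
) -> tuple[str, bool]:
    """Classify a depolarizing-step sweep: burst firing (>1 spike) -> type II.

    Returns ``(subtype, capacitance_consistent)``; the flag is True when no
    capacitance is supplied or when it falls in the subtype's expected range.
    A step sweep with zero spikes is unclassifiable.
    """
    n_spikes = detect_spikes(step_response, threshold, refractory).size
    if n_spikes == 0:
        raise UnclassifiableError("no spikes on the classification step")
    subtype = "II" if n_spikes > 1 else "I"
    consistent = True
    if membrane_capacitance is not None:
        lo, hi = CAPACITANCE_RANGE[subtype]
        consistent = lo <= membrane_capacitance <= hi
    return subtype, consistent


QC_FIELDS = ("vm_drift", "access_resistance_change", "membrane_resistance_change")


def qc_filter(
    cells: list[CellRecord],
    vm_limit: float = 10.0,
    resistance_limit: float = 0.15,
) -> tuple[list[CellRecord], list[tuple[CellRecord, list[str]]]]:
    """Apply the recording-stability discard rules (strictly greater-than).

    A cell is discarded iff its resting-potential drift exceeds ``vm_limit``
    (mV) or either resistance changed by more than ``resistance_limit``
    (fraction); reasons are recorded per discarded cell.
    """
    kept: list[CellRecord] = []
    discarded: list[tuple[CellRecord, list[str]]] = []
    for cell in cells:
        missing = [f for f in QC_FIELDS if f not in cell.qc]
        if missing:
            raise DataIntegrityError(f"cell {cell.cell_id} missing QC fields {missing}")
        reasons = []
        if cell.qc["vm_drift"] > vm_limit:
            reasons.append("vm_drift")
        if cell.qc["access_resistance_change"] > resistance_limit:
            reasons.append("access_resistance")
        if cell.qc["membrane_resistance_change"] > resistance_limit:
            reasons.append("membrane_resistance")
        (discarded.append((cell, reasons)) if reasons else kept.append(cell))
    return kept, discarded


def compute_cell_metrics(
    cell: CellRecord,
    protocol: LightProtocol,
    window: float = DEFAULT_RESPONSE_WINDOW,
    clip_spikes: bool = False,
    threshold: float = DEFAULT_SPIKE_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
) -> dict:
    """Per-cell metric row: intensity-averaged AUC and APs/pulse, binary
    response, 0 mW reference AUC, and the step-classified subtype."""
    baseline, response = default_windows(protocol, window)
    missing = [i for i in protocol.intensities if i not in cell.traces]
    if missing:
        raise IncompleteRecordError(f"cell {cell.cell_id} missing intensities {missing}")
    aucs, aps = [], []
    for inten in protocol.intensities:
        tr = cell.traces[inten]
        aucs.append(trace_auc(tr, baseline, response, clip_spikes, threshold))
        aps.append(aps_per_pulse(tr, protocol, window, threshold, refractory))
    try:
        subtype_cls, cap_ok = classify_subtype(
            cell.step_response, threshold, refractory, cell.membrane_capacitance
        )
    except UnclassifiableError:
        subtype_cls, cap_ok = "unclassifiable", False
    return {
        "cell_id": cell.cell_id,
        "input": cell.circuit.input_region,
        "output": cell.circuit.output_region,
        "subtype": cell.subtype,
        "subtype_classified": subtype_cls,
        "capacitance_consistent": cap_ok,
        "mean_auc": float(np.mean(aucs)),
        "mean_aps_per_pulse": float(np.mean(aps)),
        "binary_response": binary_response(cell, protocol, window, threshold, refractory),
        "auc_0mw": aucs[list(protocol.intensities).index(0.0)],
    }


def cell_metrics_table(
    cells: list[CellRecord],
    protocol: LightProtocol,
    window: float = DEFAULT_RESPONSE_WINDOW,
    clip_spikes: bool = False,
    vm_limit: float = 10.0,
    resistance_limit: float = 0.15,
) -> pd.DataFrame:
    """Tidy per-cell metrics table with a ``qc_status`` column.

    QC-failing cells are retained in the table (status ``discarded:<reasons>``)
    so the discard decisions remain auditable; downstream assembly keeps only
    ``pass`` rows.
    """
    kept, discarded = qc_filter(cells, vm_limit, resistance_limit)
    status = {c.cell_id: "pass" for c in kept}
    status.update({c.cell_id: "discarded:" + "+".join(r) for c, r in discarded})
    rows = []
    for cell in cells:
        row = compute_cell_metrics(cell, protocol, window, clip_spikes)
        row["qc_status"] = status[cell.cell_id]
        rows.append(row)
    return pd.DataFrame(rows)
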
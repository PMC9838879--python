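import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import clamap as cm
from clamap.exceptions import (
    ConfigurationError,
    DataIntegrityError,
    IncompleteRecordError,
    UnclassifiableError,
)
from conftest import make_trace, trace_with_spikes


class TestDetectSpikes:
    def test_flat_subthreshold_trace_has_no_spikes(self):
        tr = make_trace(np.full(6500, -70.0))
        assert cm.detect_spikes(tr, threshold=0.0).size == 0

    def test_two_spikes_ten_ms_apart(self):
        tr = trace_with_spikes([120.0, 130.0])
        times = cm.detect_spikes(tr, threshold=0.0, refractory=2.0)
        assert times.size == 2
        # crossings sit partway up the 0.5 ms rising flank
        assert np.allclose(times, [120.0, 130.0], atol=0.5)

    def test_against_exhaustive_crossing_scan_oracle(self):
        """Crossing times must match a naive per-sample scan with refractory."""
        rng = np.random.default_rng(8)
        spike_times = np.sort(rng.choice(np.arange(110, 600, 7), size=12, replace=False)).astype(float)
        tr = trace_with_spikes(list(spike_times))
        threshold, refractory = 0.0, 2.0
        v = tr.samples
        oracle, last = [], -np.inf
        for k in range(1, v.size):
            if v[k] >= threshold and v[k - 1] < threshold:
                t = k * tr.dt_ms
                if t - last >= refractory:
                    oracle.append(t)
                    last = t
        assert np.allclose(cm.detect_spikes(tr, threshold, refractory), oracle)

    def test_refractory_merges_close_crossings(self):
        tr = trace_with_spikes([120.0, 121.0])  # 1 ms apart
        assert cm.detect_spikes(tr, threshold=0.0, refractory=2.0).size == 1

    def test_non_finite_samples_rejected(self):
        bad = np.full(1000, -70.0)
        bad[5] = np.nan
        with pytest.raises(DataIntegrityError):
            cm.detect_spikes(make_trace(bad))


class TestApsPerPulse:
    def test_no_spikes_gives_zero(self, protocol):
        tr = make_trace(np.full(6500, -70.0))
        assert cm.aps_per_pulse(tr, protocol) == 0.0

    def test_one_spike_per_window_normalizes_to_one(self, protocol):
        tr = trace_with_spikes([110.0, 260.0, 410.0])
        assert cm.aps_per_pulse(tr, protocol) == 1.0

    def test_spikes_outside_windows_are_ignored(self, protocol):
        inside = trace_with_spikes([110.0, 260.0])
        with_outside = trace_with_spikes([50.0, 110.0, 260.0, 610.0])
        assert cm.aps_per_pulse(inside, protocol) == cm.aps_per_pulse(with_outside, protocol)

    def test_window_overlapping_next_pulse_rejected(self, protocol):
        tr = make_trace(np.full(6500, -70.0))
        with pytest.raises(ConfigurationError):
            cm.aps_per_pulse(tr, protocol, window=160.0)


class TestTraceAuc:
    def test_constant_trace_integrates_to_zero(self):
        tr = make_trace(np.full(6500, -65.0))
        assert cm.trace_auc(tr, (0, 100), (100, 540)) == 0.0

    def test_triangular_epsp_matches_closed_form_area(self):
        """Symmetric triangle of amplitude A and base T has area A*T/2."""
        amplitude, base_ms = 12.0, 40.0
        v = np.full(6500, -70.0)
        i0, n_half = 1500, 200  # onset 150 ms, half-base 20 ms
        v[i0 : i0 + n_half + 1] = -70.0 + np.linspace(0, amplitude, n_half + 1)
        v[i0 + n_half : i0 + 2 * n_half + 1] = -70.0 + np.linspace(amplitude, 0, n_half + 1)
        tr = make_trace(v)
        auc = cm.trace_auc(tr, (0, 100), (100, 540))
        assert auc == pytest.approx(amplitude * base_ms / 2.0, rel=1e-12)

    def test_hyperpolarization_yields_negative_auc(self):
        v = np.full(6500, -70.0)
        v[1500:3000] = -74.0
        assert cm.trace_auc(make_trace(v), (0, 100), (100, 540)) < 0

    @given(
        st.lists(
            st.tuples(st.integers(1100, 5300), st.floats(-4.0, 30.0)),
            min_size=1,
            max_size=6,
            unique_by=lambda p: p[0],
        )
    )
    def test_piecewise_linear_auc_equals_segment_area_sum(self, breakpoints):
        """For a piecewise-linear trace sampled at its breakpoints the
        trapezoidal AUC equals the exact sum of trapezoid segment areas."""
        pts = sorted([(1000, 0.0)] + breakpoints + [(5400, 0.0)])
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        v = np.full(6500, -70.0)
        v[1000:5401] = -70.0 + np.interp(np.arange(1000, 5401), xs, ys)
        tr = make_trace(v)
        exact = sum(
            (ys[k] + ys[k + 1]) / 2.0 * (xs[k + 1] - xs[k]) * 0.1 for k in range(len(xs) - 1)
        )
        assert cm.trace_auc(tr, (0, 100), (100, 540)) == pytest.approx(exact, rel=1e-9, abs=1e-7)

    def test_baseline_must_precede_first_pulse(self):
        tr = make_trace(np.full(6500, -70.0))
        with pytest.raises(ConfigurationError):
            cm.trace_auc(tr, (0, 200), (200, 540))

    def test_clip_spikes_removes_spike_area(self):
        with_spike = trace_with_spikes([150.0])
        clipped = cm.trace_auc(
            with_spike, (0, 100), (100, 540), clip_spikes=True, spike_threshold=-65.0
        )
        unclipped = cm.trace_auc(with_spike, (0, 100), (100, 540), clip_spikes=False)
        assert unclipped > clipped
        assert abs(clipped) < 5.0  # whole waveform interpolated away, envelope ~0


def _make_cell(spiking_intensities, protocol, n_spikes=1):
    traces = {}
    for inten in protocol.intensities:
        if inten in spiking_intensities:
            traces[inten] = trace_with_spikes([110.0 + 3 * k for k in range(n_spikes)])
        else:
            traces[inten] = make_trace(np.full(6500, -70.0))
    step = trace_with_spikes([52.0], duration_ms=200.0, pulse_onsets=(50.0,))
    return cm.CellRecord(
        "cell0", cm.CircuitSpec("ACC", "PtA"), "I", traces, step,
        {"vm_drift": 0.0, "access_resistance_change": 0.0, "membrane_resistance_change": 0.0},
        100.0,
    )


class TestBinaryResponse:
    def test_no_spikes_is_zero(self, protocol):
        assert cm.binary_response(_make_cell(set(), protocol), protocol) == 0.0

    def test_spikes_everywhere_is_one(self, protocol):
        cell = _make_cell(set(protocol.intensities), protocol)
        assert cm.binary_response(cell, protocol) == 1.0

    def test_three_of_six_intensities_is_half(self, protocol):
        """Mean of indicators enumerated directly: 3 spiking of 6 -> 0.5."""
        cell = _make_cell({0.6, 1.8, 3.0}, protocol)
        indicators = [1.0 if i in {0.6, 1.8, 3.0} else 0.0 for i in protocol.intensities]
        assert cm.binary_response(cell, protocol) == pytest.approx(np.mean(indicators)) == 0.5

    def test_missing_intensity_rejected(self, protocol):
        cell = _make_cell(set(), protocol)
        del cell.traces[1.2]
        with pytest.raises(IncompleteRecordError):
            cm.binary_response(cell, protocol)


class TestClassifySubtype:
    def test_single_spike_is_type_i(self):
        step = trace_with_spikes([52.0], duration_ms=200.0, pulse_onsets=(50.0,))
        assert cm.classify_subtype(step)[0] == "I"

    def test_burst_is_type_ii(self):
        step = trace_with_spikes([52.0, 55.0, 58.0], duration_ms=200.0, pulse_onsets=(50.0,))
        assert cm.classify_subtype(step)[0] == "II"

    def test_zero_spikes_is_unclassifiable(self):
        step = make_trace(np.full(2000, -70.0), pulse_onsets=(50.0,))
        with pytest.raises(UnclassifiableError):
            cm.classify_subtype(step)

    def test_capacitance_consistency_flag(self):
        step = trace_with_spikes([52.0], duration_ms=200.0, pulse_onsets=(50.0,))
        assert cm.classify_subtype(step, membrane_capacitance=100.0)[1] is True
        assert cm.classify_subtype(step, membrane_capacitance=180.0)[1] is False


class TestQcFilter:
    def _cell(self, vm=0.0, access=0.0, membrane=0.0):
        cell = _make_cell(set(), cm.LightProtocol())
        cell.qc = {
            "vm_drift": vm,
            "access_resistance_change": access,
            "membrane_resistance_change": membrane,
        }
        return cell

    def test_vm_drift_above_limit_discarded_with_reason(self):
        kept, discarded = cm.qc_filter([self._cell(vm=12.0)])
        assert not kept and discarded[0][1] == ["vm_drift"]

    def test_clean_cell_kept(self):
        kept, discarded = cm.qc_filter([self._cell()])
        assert len(kept) == 1 and not discarded

    @pytest.mark.parametrize(
        "vm,access,membrane,kept_expected",
        [
            (10.0, 0.0, 0.0, True),   # limits are strict: exactly 10 mV passes
            (10.0001, 0.0, 0.0, False),
            (0.0, 0.15, 0.0, True),   # exactly 15% passes
            (0.0, 0.1501, 0.0, False),
            (0.0, 0.0, 0.151, False),
        ],
    )
    def test_boundary_rule_enumeration(self, vm, access, membrane, kept_expected):
        kept, _ = cm.qc_filter([self._cell(vm, access, membrane)])
        assert bool(kept) is kept_expected

    def test_missing_qc_fields_rejected(self):
        cell = self._cell()
        del cell.qc["vm_drift"]
        with pytest.raises(DataIntegrityError):
            cm.qc_filter([cell])
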
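"""Unit and property tests for phrenic-nerve burst analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respiquant.nerve import (
    BurstEvent,
    NerveTrace,
    burst_metrics,
    classify_disinhibited,
    compute_envelope,
    detect_bursts,
    merge_epochs,
    spinal_activity_metrics,
)
from respiquant.synth import SimNerveConfig, gen_nerve_trace


class TestEnvelope:
    def test_zero_trace_gives_zero_envelope(self):
        trace = NerveTrace(np.zeros(10_000), 1000.0)
        env = compute_envelope(trace)
        assert np.all(env.rectified_smoothed == 0)
        assert np.all(env.integrated == 0)

    def test_constant_rectified_amplitude_plateaus_at_c_times_window(self):
        # zero-mean alternating square wave: rectified amplitude exactly c
        c, fs, window = 3.0, 1000.0, 2.0
        n = 10_000
        x = c * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        env = compute_envelope(NerveTrace(x, fs), window_s=window)
        warm = int(window * fs)
        assert np.allclose(env.integrated[warm:], c * window, rtol=1e-9)

    def test_rectangular_burst_peak_integral_is_amplitude_times_duration(
        self, alternating_burst_trace
    ):
        A, d = 10.0, 0.5
        trace = alternating_burst_trace([(10.0, 10.0 + d)], amplitude=A)
        env = compute_envelope(trace)
        dt = 1.0 / trace.sampling_rate_hz
        assert np.max(env.integrated) == pytest.approx(A * d, abs=2 * A * dt)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            compute_envelope(NerveTrace(np.zeros(100), 1000.0), window_s=2.0)

    def test_nonfinite_trace_rejected(self):
        x = np.zeros(10_000)
        x[5] = np.nan
        with pytest.raises(ValueError, match="finite"):
            compute_envelope(NerveTrace(x, 1000.0))


class TestDetect:
    @pytest.mark.parametrize(
        "epoch_ms,expected", [(49, 0), (51, 1), (50, 1)]
    )
    def test_minimum_duration_boundary(self, square_envelope, epoch_ms, expected):
        """Bursts must persist at least 50 ms; shorter epochs are rejected."""
        env = square_envelope([(10.0, 10.0 + epoch_ms / 1000.0)])
        assert len(detect_bursts(env)) == expected

    @pytest.mark.parametrize("gap_s,n_expected", [(0.9, 1), (1.1, 2)])
    def test_sub_second_gaps_merge_into_one_burst(self, square_envelope, gap_s, n_expected):
        """Activity spaced less than 1 s apart is a single burst (pauses included)."""
        env = square_envelope([(10.0, 10.2), (10.2 + gap_s, 10.4 + gap_s)])
        events = detect_bursts(env)
        assert len(events) == n_expected
        if n_expected == 1:
            assert events[0].duration_s == pytest.approx(0.4 + gap_s, abs=2e-3)

    def test_events_sorted_and_non_overlapping(self, square_envelope):
        env = square_envelope([(5, 5.3), (8, 8.3), (20, 20.3), (40, 40.3)])
        events = detect_bursts(env)
        for a, b in zip(events, events[1:]):
            assert a.offset_s <= b.onset_s

    def test_flat_envelope_returns_no_bursts(self, square_envelope):
        env = square_envelope([])
        assert detect_bursts(env) == []

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 50, allow_nan=False), st.floats(0.01, 3.0, allow_nan=False)
            ),
            min_size=0,
            max_size=15,
        ),
        st.floats(0.1, 2.0),
    )
    def test_merge_rule_matches_brute_force_union(self, raw, gap):
        """Merging epochs with < gap separation equals a brute-force interval union."""
        epochs = sorted((on, on + d) for on, d in raw)
        # drop overlapping inputs: detector epochs are disjoint by construction
        clean = []
        for on, off in epochs:
            if clean and on <= clean[-1][1]:
                continue
            clean.append((on, off))

        def oracle(eps):
            out = []
            for on, off in eps:
                placed = False
                for i, (a, b) in enumerate(out):
                    if not (on - b >= gap or a - off >= gap):
                        out[i] = (min(a, on), max(b, off))
                        placed = True
                        break
                if not placed:
                    out.append((on, off))
            # keep unioning until a fixed point
            changed = True
            while changed:
                changed = False
                out.sort()
                for i in range(len(out) - 1):
                    if out[i + 1][0] - out[i][1] < gap:
                        out[i] = (out[i][0], max(out[i][1], out[i + 1][1]))
                        del out[i + 1]
                        changed = True
                        break
            return out

        got, want = merge_epochs(clean, gap), oracle(clean)
        assert len(got) == len(want)
        if got:
            assert np.allclose(np.array(got), np.array(want))


class TestMetrics:
    def test_no_bursts_gives_zero_metrics(self, square_envelope):
        env = square_envelope([])
        m = burst_metrics(env, [], recording_min=10.0)
        assert m.n_bursts == 0
        assert m.frequency_per_min == 0.0
        assert m.total_activity_uvs == 0.0

    def test_single_rectangular_burst_activity(self, alternating_burst_trace):
        """A 10 uV, 0.5 s burst: total activity 5 uV*s, normalized 10 uV*s/s."""
        trace = alternating_burst_trace([(10.0, 10.5)], amplitude=10.0)
        env = compute_envelope(trace)
        events = detect_bursts(env)
        assert len(events) == 1
        m = burst_metrics(env, events, recording_min=1.0)
        assert m.total_activity_uvs == pytest.approx(5.0, rel=0.01)
        assert m.normalized_activity_uvs_per_s == pytest.approx(10.0, rel=0.01)

    def test_burst_subselection_and_frequency(self, square_envelope):
        """12 bursts in 10 min with max_bursts=7: 7 used, frequency 1.2/min."""
        epochs = [(30.0 * k + 5, 30.0 * k + 5.4) for k in range(12)]
        env = square_envelope(epochs, duration_s=600.0)
        events = detect_bursts(env)
        assert len(events) == 12
        m = burst_metrics(env, events, recording_min=10.0, max_bursts=7)
        assert m.bursts_used == 7
        assert m.frequency_per_min == pytest.approx(1.2)

    def test_random_selection_mode_is_seeded(self, square_envelope):
        epochs = [(30.0 * k + 5, 30.0 * k + 5.4) for k in range(12)]
        env = square_envelope(epochs, duration_s=600.0)
        events = detect_bursts(env)
        m1 = burst_metrics(env, events, 10.0, rng=np.random.default_rng(7))
        m2 = burst_metrics(env, events, 10.0, rng=np.random.default_rng(7))
        assert m1 == m2

    def test_amplitude_linearity(self, alternating_burst_trace):
        """Scaling a baseline-free trace by c scales total activity by c."""
        epochs = [(10.0, 10.5), (20.0, 20.6)]
        m = {}
        for c in (1.0, 3.0):
            trace = alternating_burst_trace(epochs, amplitude=10.0 * c)
            env = compute_envelope(trace)
            m[c] = burst_metrics(env, detect_bursts(env), 1.0).total_activity_uvs
        assert m[3.0] == pytest.approx(3.0 * m[1.0], rel=1e-6)


class TestDisinhibited:
    def _events(self, durations):
        return [
            BurstEvent(10.0 * i, 10.0 * i + d, peak_integrated_uvs=1.0)
            for i, d in enumerate(durations)
        ]

    def test_duration_threshold_partition(self):
        resp, spinal = classify_disinhibited(None, self._events([0.4, 0.5, 6.0]), 2.0)
        assert len(resp) == 2 and len(spinal) == 1
        assert spinal[0].kind == "spinal"
        assert all(b.kind == "respiratory" for b in resp)

    def test_empty_and_all_spinal(self):
        assert classify_disinhibited(None, [], 2.0) == ([], [])
        resp, spinal = classify_disinhibited(None, self._events([3.0, 4.0]), 2.0)
        assert resp == [] and len(spinal) == 2

    def test_spinal_duration_percentage(self):
        events = self._events([6.0])
        assert spinal_activity_metrics(None, events, 60.0).spinal_duration_pct == pytest.approx(10.0)
        assert spinal_activity_metrics(None, [], 60.0).spinal_duration_pct == 0.0
        full = [BurstEvent(0.0, 60.0, 1.0)]
        assert spinal_activity_metrics(None, full, 60.0).spinal_duration_pct == pytest.approx(100.0)


class TestDetectorOnSynthetic:
    def test_perfect_recall_precision_on_clean_traces(self):
        """Every ground-truth burst is detected exactly once on noiseless input."""
        cfg = SimNerveConfig(duration_s=60.0, noise_sd_uv=0.0, seed=11)
        trace, truth = gen_nerve_trace(cfg)
        env = compute_envelope(trace)
        events = detect_bursts(env)
        assert len(events) == len(truth.true_burst_intervals)
        for ev, (on, off) in zip(events, truth.true_burst_intervals):
            # detected interval overlaps its ground-truth interval
            assert ev.onset_s < off and ev.offset_s > on

    def test_spinal_events_detected_and_classified(self):
        cfg = SimNerveConfig(
            duration_s=60.0,
            noise_sd_uv=0.0,
            spinal_events=((20.0, 6.0, 0.3),),
            mean_burst_period_s=20.0,
            period_cv=0.0,
            seed=12,
        )
        trace, truth = gen_nerve_trace(cfg)
        env = compute_envelope(trace)
        resp, spinal = classify_disinhibited(env, detect_bursts(env), 2.0)
        assert len(spinal) == 1
        on, off = truth.true_spinal_intervals[0]
        assert spinal[0].onset_s < off and spinal[0].offset_s > on
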
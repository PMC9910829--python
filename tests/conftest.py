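import numpy as np
import pytest

from respiquant.nerve import EnvelopeTrace, compute_envelope, NerveTrace


@pytest.fixture
def square_envelope():
    """Build an EnvelopeTrace with rectangular supra-baseline epochs.

    Epochs are (onset_s, offset_s) at amplitude 1 on a zero background;
    the integrated envelope is the causal 2 s moving integral of the same
    rectangular signal.
    """

    def _make(epochs, duration_s=60.0, fs=1000.0, window_s=2.0):
        n = int(duration_s * fs)
        rect = np.zeros(n)
        for on, off in epochs:
            rect[int(on * fs) : int(off * fs)] = 1.0
        nw = int(window_s * fs)
        cs = np.concatenate([[0.0], np.cumsum(rect)])
        idx = np.arange(1, n + 1)
        integrated = (cs[idx] - cs[np.maximum(idx - nw, 0)]) / fs
        return EnvelopeTrace(
            rectified_smoothed=rect,
            integrated=integrated,
            sampling_rate_hz=fs,
            window_s=window_s,
        )

    return _make


@pytest.fixture
def alternating_burst_trace():
    """NerveTrace with zero-mean rectangular bursts (alternating +/-A samples)."""

    def _make(epochs, amplitude=10.0, duration_s=60.0, fs=1000.0):
        n = int(duration_s * fs)
        x = np.zeros(n)
        signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        for on, off in epochs:
            i0, i1 = int(on * fs), int(off * fs)
            x[i0:i1] = amplitude * signs[i0:i1]
        return NerveTrace(samples=x, sampling_rate_hz=fs)

    return _make
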
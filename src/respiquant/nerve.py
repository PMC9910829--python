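"""Phrenic-nerve burst analysis.

Quantifies multi-unit suction-electrode recordings of the phrenic nerve
(fictive inspiration in isolated brainstem--spinal cord preparations).
The pipeline is: rectify the voltage trace, smooth it for burst
*detection*, and run a long (2 s) moving time-integral whose per-burst
maximum is the burst *activity*; bursts are epochs of supra-baseline
activity lasting at least 50 ms, with sub-second pauses absorbed into a
single burst.  Under pharmacological disinhibition (picrotoxin +
strychnine) the nerve additionally expresses long, low-amplitude
spinal-network events, which are split off by a duration criterion and
summarised separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NerveTrace",
    "EnvelopeTrace",
    "BurstEvent",
    "BurstMetrics",
    "SpinalActivityMetrics",
    "compute_envelope",
    "detect_bursts",
    "merge_epochs",
    "burst_metrics",
    "classify_disinhibited",
    "spinal_activity_metrics",
]


@dataclass(frozen=True)
class NerveTrace:
    """A uniformly sampled nerve voltage recording, in microvolts."""

    samples: np.ndarray
    sampling_rate_hz: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("nerve trace must be one-dimensional")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass(frozen=True)
class EnvelopeTrace:
    """Detection and amplitude envelopes derived from a nerve trace.

    ``rectified_smoothed`` is the mean-subtracted, rectified trace passed
    through a short causal moving average (``smooth_s``); it drives burst
    detection.  ``integrated`` is the causal moving time-integral of the
    rectified trace over ``window_s`` (uV*s); its maximum within a burst is
    the burst activity.
    """

    rectified_smoothed: np.ndarray
    integrated: np.ndarray
    sampling_rate_hz: float
    window_s: float = 2.0
    smooth_s: float = 0.05
    rectified: np.ndarray | None = None  # unsmoothed, for onset/offset refinement

    @property
    def n_samples(self) -> int:
        return self.rectified_smoothed.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass(frozen=True)
class BurstEvent:
    """A detected burst: [onset_s, offset_s), with its peak integrated amplitude."""

    onset_s: float
    offset_s: float
    peak_integrated_uvs: float
    kind: str = "respiratory"

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError("burst offset must follow onset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class BurstMetrics:
    n_bursts: int
    frequency_per_min: float
    mean_duration_s: float
    total_activity_uvs: float
    normalized_activity_uvs_per_s: float
    bursts_used: int


@dataclass(frozen=True)
class SpinalActivityMetrics:
    spinal_duration_pct: float
    normalized_spinal_activity: float
    n_events: int = 0


def compute_envelope(
    trace: NerveTrace, smooth_s: float = 0.05, window_s: float = 2.0
) -> EnvelopeTrace:
    """Rectify a nerve trace and compute its smoothed and integrated envelopes.

    The trace is mean-subtracted then rectified.  Both windows are causal
    (rectangular, zero-padded at the start): the smoothed envelope is a
    moving average over ``smooth_s``, the integrated envelope a moving sum
    times dt over ``window_s``.
    """
    if not (window_s > smooth_s > 0):
        raise ValueError("require window_s > smooth_s > 0")
    x = trace.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    fs = trace.sampling_rate_hz
    n_window = int(round(window_s * fs))
    if n_window > x.size:
        raise ValueError("integration window longer than the trace")
    rect = np.abs(x - x.mean())

    n_smooth = max(int(round(smooth_s * fs)), 1)
    cs = np.concatenate([[0.0], np.cumsum(rect)])
    # causal moving sums: sum over (i - n + 1 .. i), truncated at the start
    idx = np.arange(1, rect.size + 1)
    smoothed = (cs[idx] - cs[np.maximum(idx - n_smooth, 0)]) / np.minimum(idx, n_smooth)
    integrated = (cs[idx] - cs[np.maximum(idx - n_window, 0)]) / fs
    return EnvelopeTrace(
        rectified_smoothed=smoothed,
        integrated=integrated,
        sampling_rate_hz=fs,
        window_s=window_s,
        smooth_s=smooth_s,
        rectified=rect,
    )


def merge_epochs(
    epochs: Sequence[tuple[float, float]], merge_gap_s: float
) -> list[tuple[float, float]]:
    """Merge sorted (onset, offset) epochs whose separating gap is < merge_gap_s.

    Pauses shorter than the gap are absorbed into a single event; a gap of
    exactly ``merge_gap_s`` splits.
    """
    merged: list[tuple[float, float]] = []
    for onset, offset in sorted(epochs):
        if merged and onset - merged[-1][1] < merge_gap_s:
            merged[-1] = (merged[-1][0], max(merged[-1][1], offset))
        else:
            merged.append((onset, offset))
    return merged


def detect_bursts(
    env: EnvelopeTrace,
    threshold_k: float = 4.0,
    min_duration_s: float = 0.050,
    merge_gap_s: float = 1.0,
) -> list[BurstEvent]:
    """Detect bursts as supra-threshold epochs of the smoothed rectified envelope.

    The baseline is the envelope median; the threshold adds ``threshold_k``
    robust standard deviations (1.4826 * MAD).  Supra-threshold epochs
    separated by less than ``merge_gap_s`` are merged (pauses counted as
    part of the burst); merged events shorter than ``min_duration_s`` are
    discarded.  Each event's amplitude is the maximum of the integrated
    envelope within the event.
    """
    if not threshold_k > 0:
        raise ValueError("threshold_k must be positive")
    rs = env.rectified_smoothed
    baseline = float(np.median(rs))
    mad = float(np.median(np.abs(rs - baseline)))
    robust_sd = 1.4826 * mad
    if robust_sd == 0.0:
        # flat envelope: fall back to a machine-scaled epsilon above baseline
        robust_sd = np.finfo(float).eps * max(float(np.max(rs)), 1.0)
        logger.warning("flat envelope (MAD = 0); threshold falls back to epsilon scale")
    threshold = baseline + threshold_k * robust_sd

    above = rs > threshold
    if not above.any():
        return []
    dt = 1.0 / env.sampling_rate_hz
    padded = np.concatenate([[0], above.astype(np.int8), [0]])
    starts = np.flatnonzero(np.diff(padded) == 1)
    ends = np.flatnonzero(np.diff(padded) == -1) - 1
    n_smooth = max(int(round(env.smooth_s * env.sampling_rate_hz)), 1)
    epochs = []
    for s, e in zip(starts, ends):
        # the causal moving average smears epoch edges by up to smooth_s;
        # refine bounds to threshold crossings of the unsmoothed rectified trace
        if env.rectified is not None:
            lo = max(s - n_smooth, 0)
            hot = np.flatnonzero(env.rectified[lo : e + 1] > threshold)
            if hot.size:
                s, e = lo + hot[0], lo + hot[-1]
        epochs.append((s * dt, (e + 1) * dt))

    events = []
    for onset, offset in merge_epochs(epochs, merge_gap_s):
        if offset - onset < min_duration_s:
            continue
        i0 = int(round(onset / dt))
        i1 = int(round(offset / dt))
        peak = float(np.max(env.integrated[i0:i1]))
        events.append(BurstEvent(onset_s=onset, offset_s=offset, peak_integrated_uvs=peak))
    return events


def _select_spread(n: int, k: int) -> np.ndarray:
    """Indices of up to k events spread evenly through a sequence of n."""
    if n <= k:
        return np.arange(n)
    return np.unique(np.round(np.linspace(0, n - 1, k)).astype(int))


def burst_metrics(
    env: EnvelopeTrace,
    bursts: Sequence[BurstEvent],
    recording_min: float,
    max_bursts: int = 7,
    rng: np.random.Generator | None = None,
) -> BurstMetrics:
    """Summarise detected bursts.

    Up to ``max_bursts`` bursts spaced evenly through the recording are
    used for the amplitude metrics (pass ``rng`` to sample them at random
    instead); frequency uses every detected burst over ``recording_min``
    minutes.  Activity is the mean per-burst peak of the integrated
    envelope; the normalized variant divides each peak by its burst's
    duration before averaging.
    """
    if not recording_min > 0:
        raise ValueError("recording_min must be positive")
    n = len(bursts)
    if n == 0:
        logger.warning("no bursts detected; activity metrics reported as zero")
        return BurstMetrics(0, 0.0, 0.0, 0.0, 0.0, 0)
    if rng is None:
        idx = _select_spread(n, max_bursts)
    else:
        idx = np.sort(rng.choice(n, size=min(n, max_bursts), replace=False))
    used = [bursts[i] for i in idx]
    peaks = np.array([b.peak_integrated_uvs for b in used])
    durs = np.array([b.duration_s for b in used])
    return BurstMetrics(
        n_bursts=n,
        frequency_per_min=n / recording_min,
        mean_duration_s=float(durs.mean()),
        total_activity_uvs=float(peaks.mean()),
        normalized_activity_uvs_per_s=float((peaks / durs).mean()),
        bursts_used=len(used),
    )


def classify_disinhibited(
    env: EnvelopeTrace,
    bursts: Sequence[BurstEvent],
    spinal_min_duration_s: float = 2.0,
) -> tuple[list[BurstEvent], list[BurstEvent]]:
    """Partition events from a disinhibited preparation by duration.

    Spinal-network events are longer (and lower amplitude) than respiratory
    bursts; events lasting at least ``spinal_min_duration_s`` are labelled
    spinal, the rest respiratory.  The partition is exhaustive and exclusive.
    """
    respiratory, spinal = [], []
    for b in bursts:
        if b.duration_s >= spinal_min_duration_s:
            spinal.append(replace(b, kind="spinal"))
        else:
            respiratory.append(replace(b, kind="respiratory"))
    return respiratory, spinal


def spinal_activity_metrics(
    env: EnvelopeTrace, spinal_events: Sequence[BurstEvent], recording_s: float
) -> SpinalActivityMetrics:
    """Total spinal-event duration (% of recording time) and normalized activity."""
    if not recording_s > 0:
        raise ValueError("recording_s must be positive")
    if len(spinal_events) == 0:
        return SpinalActivityMetrics(0.0, 0.0, 0)
    durs = np.array([b.duration_s for b in spinal_events])
    peaks = np.array([b.peak_integrated_uvs for b in spinal_events])
    return SpinalActivityMetrics(
        spinal_duration_pct=float(100.0 * durs.sum() / recording_s),
        normalized_spinal_activity=float((peaks / durs).mean()),
        n_events=len(spinal_events),
    )
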
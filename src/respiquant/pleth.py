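"""Whole-body plethysmography breath analysis.

Flow traces follow the standard convention: inspiration is a downward
deflection (negative flow, ml/s), expiration upward, and each breath is
delimited by zero crossings of the flow signal.  Tidal volume is the
magnitude of the time-integral of the inspiratory phase; minute
ventilation is tidal volume times breathing frequency.  Because raw sign
changes shatter breaths under noise, segmentation uses a Schmitt-trigger
(hysteresis) zero crossing, with the actual onset refined back to the
zero crossing itself.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence as AbcSequence
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FlowTrace",
    "Breath",
    "VentilationMetrics",
    "RestingSelection",
    "estimate_noise_sd",
    "segment_breaths",
    "tidal_volume",
    "select_resting",
    "ventilation_metrics",
    "fold_control",
]


@dataclass(frozen=True)
class FlowTrace:
    """Uniformly sampled air-flow trace (ml/s), optionally with a movement mask."""

    flow_ml_per_s: np.ndarray
    sampling_rate_hz: float
    movement_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        flow = np.asarray(self.flow_ml_per_s, dtype=float)
        object.__setattr__(self, "flow_ml_per_s", flow)
        if flow.ndim != 1:
            raise ValueError("flow trace must be one-dimensional")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.movement_mask is not None:
            mask = np.asarray(self.movement_mask, dtype=bool)
            object.__setattr__(self, "movement_mask", mask)
            if mask.size != flow.size:
                raise ValueError("movement mask length must match the trace")

    @property
    def n_samples(self) -> int:
        return self.flow_ml_per_s.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass(frozen=True)
class Breath:
    """One breath: inspiratory phase then the following expiratory phase."""

    insp_onset_s: float
    insp_offset_s: float
    exp_offset_s: float
    tidal_volume_ml: float = 0.0
    period_s: float = 0.0
    resting: bool = True

    def __post_init__(self) -> None:
        if not (self.insp_onset_s < self.insp_offset_s <= self.exp_offset_s):
            raise ValueError("require insp_onset < insp_offset <= exp_offset")


@dataclass(frozen=True)
class VentilationMetrics:
    frequency_bpm: float
    mean_tidal_volume_ml: float
    minute_ventilation_ml_per_min: float
    n_breaths_used: int
    fold_control: float | None = None


class RestingSelection(AbcSequence):
    """Resting breaths plus a shortfall flag (acts as a read-only sequence)."""

    def __init__(self, breaths: Sequence[Breath], shortfall: bool, min_breaths: int):
        self.breaths = list(breaths)
        self.shortfall = shortfall
        self.min_breaths = min_breaths

    def __getitem__(self, i):
        return self.breaths[i]

    def __len__(self) -> int:
        return len(self.breaths)

    def __repr__(self) -> str:
        flag = " SHORTFALL" if self.shortfall else ""
        return f"RestingSelection(n={len(self.breaths)}{flag})"


def estimate_noise_sd(flow: np.ndarray) -> float:
    """Robust noise SD estimate from first differences (MAD-scaled)."""
    d = np.diff(np.asarray(flow, dtype=float))
    if d.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def segment_breaths(
    trace: FlowTrace, hysteresis_ml_per_s: float | None = None
) -> list[Breath]:
    """Segment a flow trace into breaths at hysteresis zero crossings.

    A breath starts at a negative-going zero crossing (flow must then fall
    below ``-hysteresis`` to confirm inspiration) and comprises one negative
    phase followed by the next positive phase.  Onsets/offsets are refined
    to the nearest enclosed zero crossing, so on clean traces they land
    within one sample of the true phase boundaries.  Terminal cycles whose
    inspiration never completes (or whose expiration never starts) are
    dropped.  The default hysteresis is twice a robust noise-SD estimate.
    """
    flow = trace.flow_ml_per_s
    if not np.all(np.isfinite(flow)):
        raise ValueError("flow trace contains non-finite samples")
    n = flow.size
    if n < 3:
        return []
    fs = trace.sampling_rate_hz
    dt = 1.0 / fs
    if hysteresis_ml_per_s is None:
        hysteresis_ml_per_s = 2.0 * estimate_noise_sd(flow)
    h = max(float(hysteresis_ml_per_s), 0.0)
    if h == 0.0:
        h = 1e-12 * max(float(np.max(np.abs(flow))), 1.0)

    # Schmitt trigger: -1 below -h, +1 above +h, hold otherwise.
    sgn = np.where(flow < -h, -1, np.where(flow > h, 1, 0)).astype(np.int8)
    nz = np.flatnonzero(sgn)
    if nz.size == 0:
        return []
    states = sgn[nz]
    flips = np.flatnonzero(np.diff(states) != 0) + 1
    triggers = [(nz[0], states[0])] + [(nz[i], states[i]) for i in flips]

    nonneg = np.flatnonzero(flow >= 0.0)
    nonpos = np.flatnonzero(flow <= 0.0)

    def last_at_or_before(candidates: np.ndarray, i: int) -> int:
        j = np.searchsorted(candidates, i, side="right") - 1
        return int(candidates[j]) if j >= 0 else 0

    # collect (refined_zero_index, state) transitions into inspiration/expiration
    insp_onsets: list[int] = []
    exp_onsets: list[int] = []
    for idx, state in triggers:
        if state == -1:
            insp_onsets.append(last_at_or_before(nonneg, idx))
        else:
            exp_onsets.append(last_at_or_before(nonpos, idx))

    breaths: list[Breath] = []
    for k, on in enumerate(insp_onsets):
        # inspiration completes at the first expiration onset after it
        exp_candidates = [e for e in exp_onsets if e > on]
        if not exp_candidates:
            break  # incomplete terminal inspiration
        insp_off = exp_candidates[0]
        if k + 1 < len(insp_onsets) and insp_onsets[k + 1] <= insp_off:
            continue  # degenerate chatter; skip
        exp_off = insp_onsets[k + 1] if k + 1 < len(insp_onsets) else n - 1
        tv = _tidal_volume_idx(flow, on, insp_off, dt)
        if tv < h * (insp_off - on) * dt:
            continue  # mean deflection within the hysteresis band: noise, not a breath
        breaths.append(
            Breath(
                insp_onset_s=on * dt,
                insp_offset_s=insp_off * dt,
                exp_offset_s=exp_off * dt,
                tidal_volume_ml=tv,
                period_s=(exp_off - on) * dt,
            )
        )
    return breaths


def _tidal_volume_idx(flow: np.ndarray, i0: int, i1: int, dt: float) -> float:
    seg = flow[i0 : i1 + 1]
    if seg.size < 2:
        return 0.0
    return float(abs(np.trapezoid(seg, dx=dt)))


def tidal_volume(trace: FlowTrace, breath: Breath) -> float:
    """Tidal volume: |trapezoidal integral of flow over the inspiratory phase|, ml."""
    fs = trace.sampling_rate_hz
    i0 = int(round(breath.insp_onset_s * fs))
    i1 = int(round(breath.insp_offset_s * fs))
    if i0 < 0 or i1 >= trace.n_samples:
        raise ValueError("breath interval outside the trace")
    return _tidal_volume_idx(trace.flow_ml_per_s, i0, i1, 1.0 / fs)


def select_resting(
    breaths: Sequence[Breath],
    movement_mask: np.ndarray | None = None,
    sampling_rate_hz: float | None = None,
    min_breaths: int = 10,
) -> RestingSelection:
    """Exclude breaths overlapping movement-artifact epochs.

    ``movement_mask`` is a per-sample boolean array at ``sampling_rate_hz``;
    a breath touching any masked sample is excluded.  Fewer than
    ``min_breaths`` survivors sets the shortfall flag (and logs a warning)
    rather than silently passing.
    """
    if movement_mask is None:
        selected = list(breaths)
    else:
        if sampling_rate_hz is None:
            raise ValueError("sampling_rate_hz required with a movement mask")
        mask = np.asarray(movement_mask, dtype=bool)
        selected = []
        for b in breaths:
            i0 = int(b.insp_onset_s * sampling_rate_hz)
            i1 = min(int(np.ceil(b.exp_offset_s * sampling_rate_hz)), mask.size - 1)
            if not mask[i0 : i1 + 1].any():
                selected.append(b)
    shortfall = len(selected) < min_breaths
    if shortfall:
        logger.warning(
            "only %d resting breaths selected (minimum %d)", len(selected), min_breaths
        )
    return RestingSelection(selected, shortfall, min_breaths)


def ventilation_metrics(
    breaths: Iterable[Breath], epoch_duration_s: float | None = None
) -> VentilationMetrics:
    """Frequency, mean tidal volume and minute ventilation of the analysed breaths.

    Frequency is period-based (60 * n / sum of breath periods), which stays
    correct when resting breaths come from discontinuous quiet epochs;
    minute ventilation is frequency times mean tidal volume by construction.
    """
    breaths = list(breaths)
    if len(breaths) == 0:
        raise ValueError("ventilation metrics require at least one breath")
    periods = np.array([b.period_s for b in breaths])
    if not np.all(periods > 0):
        raise ValueError("breaths must carry positive periods")
    tvs = np.array([b.tidal_volume_ml for b in breaths])
    freq = 60.0 * len(breaths) / float(periods.sum())
    tv = float(tvs.mean())
    return VentilationMetrics(
        frequency_bpm=freq,
        mean_tidal_volume_ml=tv,
        minute_ventilation_ml_per_min=freq * tv,
        n_breaths_used=len(breaths),
    )


def fold_control(value: float, littermate_controls: Sequence[float]) -> float:
    """A mouse's metric divided by the mean of its (two) littermate controls."""
    controls = np.asarray(littermate_controls, dtype=float)
    mean = float(controls.mean())
    if not mean > 0:
        raise ValueError("control mean must be positive")
    return float(value) / mean
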
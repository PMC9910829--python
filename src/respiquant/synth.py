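"""Synthetic data generation with known ground truth.

Every input modality of the analysis pipeline can be simulated here so
the downstream stages are testable without animal recordings:

* multi-unit phrenic nerve traces — periodic respiratory bursts of
  Poisson motor-unit spikes rendered as biphasic 1 ms templates on
  Gaussian background noise, with an amplitude multiplier to emulate
  reduced recruitment and optional long low-amplitude disinhibited
  spinal events;
* plethysmograph flow traces — half-sine inspiratory (negative) and
  expiratory (positive) phases of equal, exactly area-normalized volume,
  with a gasping mode that inserts irregular long pauses and deeper
  deflections;
* soma coordinate tables — Gaussian clusters with genotype-dependent
  shifts, written raw (per-section scale, left somas with negative x) so
  standardization must invert the distortion;
* dendritic intensity images — background + noise + cell-body disc +
  angular rays with Gaussian angular spread.

All generators are deterministic for a fixed config (same seed gives
bit-identical output).  Generators are phenomenological: there is no
biophysical model of rhythmogenesis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dendrites import IntensityImage
from .nerve import NerveTrace
from .pleth import FlowTrace
from .topography import REFERENCE_HALFWIDTH_UM, SOMA_COLUMNS, SomaTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimNerveConfig",
    "SimFlowConfig",
    "SimSomaConfig",
    "SimDendriteConfig",
    "GroundTruth",
    "gen_nerve_trace",
    "gen_flow_trace",
    "gen_soma_table",
    "gen_dendrite_image",
]


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name}: non-finite configuration value {v!r}")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually produced, for oracle-style testing."""

    true_burst_intervals: list[tuple[float, float]] = field(default_factory=list)
    true_spinal_intervals: list[tuple[float, float]] = field(default_factory=list)
    true_breaths: list[tuple[float, float, float]] = field(default_factory=list)
    true_centroid_um: tuple[float, float] | None = None
    true_ray_angles_deg: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class SimNerveConfig:
    """Conditions for a simulated phrenic-nerve recording.

    ``amplitude_scale`` multiplies every spike amplitude (1.0 is
    control-like; values < 1 emulate reduced motor unit recruitment).
    ``period_cv`` is the coefficient of variation of inter-burst intervals
    (burst timing is irregular in perinatal preparations).  Spike
    amplitudes are in arbitrary-but-consistent uV (absolute gain is not
    calibrated).  ``spinal_events`` is a list of
    (onset_s, duration_s, amplitude_scale) long low-amplitude events.
    """

    duration_s: float = 60.0
    sampling_rate_hz: float = 5000.0
    mean_burst_period_s: float = 8.0
    period_cv: float = 0.3
    burst_duration_s: float = 0.6
    unit_rate_hz: float = 300.0
    spike_amp_uv: float = 40.0
    amplitude_scale: float = 1.0
    noise_sd_uv: float = 0.2
    spinal_events: tuple[tuple[float, float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        _require_finite(
            "SimNerveConfig",
            self.duration_s,
            self.sampling_rate_hz,
            self.mean_burst_period_s,
            self.period_cv,
            self.burst_duration_s,
            self.unit_rate_hz,
            self.spike_amp_uv,
            self.amplitude_scale,
            self.noise_sd_uv,
        )
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if self.sampling_rate_hz < 1000:
            raise ValueError("sampling_rate_hz must be at least 1000 Hz")
        if self.amplitude_scale < 0:
            raise ValueError("amplitude_scale must be non-negative")
        if self.period_cv < 0:
            raise ValueError("period_cv must be non-negative")
        if not self.mean_burst_period_s > 0 or not self.burst_duration_s > 0:
            raise ValueError("burst period and duration must be positive")


def _spike_template(fs: float) -> np.ndarray:
    """Biphasic 1 ms spike template (one full sine cycle), unit peak amplitude."""
    n = max(int(round(0.001 * fs)), 4)
    return np.sin(2.0 * np.pi * np.arange(n) / n)


def _render_spikes(
    samples: np.ndarray,
    rng: np.random.Generator,
    fs: float,
    onset_s: float,
    duration_s: float,
    rate_hz: float,
    amp_uv: float,
) -> None:
    """Superimpose a Poisson motor-unit spike train onto ``samples`` in place."""
    template = _spike_template(fs)
    n_spikes = rng.poisson(rate_hz * duration_s)
    times = onset_s + rng.random(n_spikes) * duration_s
    amps = amp_uv * rng.lognormal(mean=0.0, sigma=0.25, size=n_spikes)
    signs = rng.choice([-1.0, 1.0], size=n_spikes)
    for t, a, s in zip(np.sort(times), amps, signs):
        i0 = int(round(t * fs))
        i1 = min(i0 + template.size, samples.size)
        if i0 >= samples.size:
            continue
        samples[i0:i1] += s * a * template[: i1 - i0]


def gen_nerve_trace(config: SimNerveConfig) -> tuple[NerveTrace, GroundTruth]:
    """Simulate a multi-unit nerve recording with periodic respiratory bursts.

    Inter-burst intervals are Gamma-distributed with the configured mean
    and CV (deterministic spacing when CV = 0, with the first burst at half
    a period); within each ground-truth burst interval spikes occur as a
    Poisson process at ``unit_rate_hz``, each a biphasic 1 ms template of
    random polarity with lognormal amplitude around
    ``spike_amp_uv * amplitude_scale``.  Elsewhere the trace is Gaussian
    noise only; ``spinal_events`` add sustained low-amplitude activity.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    n = int(round(config.duration_s * fs))
    samples = np.zeros(n)

    # burst onset schedule
    mean_p, cv = config.mean_burst_period_s, config.period_cv
    intervals: list[float] = []
    if cv == 0:
        onset = 0.5 * mean_p
        while onset + config.burst_duration_s <= config.duration_s:
            intervals.append(onset)
            onset += mean_p
    else:
        shape = 1.0 / cv**2
        scale = mean_p * cv**2
        onset = 0.5 * rng.gamma(shape, scale)
        while onset + config.burst_duration_s <= config.duration_s:
            intervals.append(onset)
            onset += rng.gamma(shape, scale)
    burst_intervals = [(o, o + config.burst_duration_s) for o in intervals]

    amp = config.spike_amp_uv * config.amplitude_scale
    for onset, offset in burst_intervals:
        _render_spikes(samples, rng, fs, onset, offset - onset, config.unit_rate_hz, amp)

    spinal_intervals: list[tuple[float, float]] = []
    for onset, dur, scale in config.spinal_events:
        _require_finite("spinal_event", onset, dur, scale)
        offset = min(onset + dur, config.duration_s)
        if offset <= onset:
            continue
        _render_spikes(
            samples, rng, fs, onset, offset - onset, config.unit_rate_hz,
            config.spike_amp_uv * scale,
        )
        spinal_intervals.append((onset, offset))

    if config.noise_sd_uv > 0:
        samples += rng.normal(0.0, config.noise_sd_uv, n)

    trace = NerveTrace(samples=samples, sampling_rate_hz=fs, label=f"sim seed={config.seed}")
    truth = GroundTruth(
        true_burst_intervals=burst_intervals, true_spinal_intervals=spinal_intervals
    )
    return trace, truth


@dataclass(frozen=True)
class SimFlowConfig:
    """Conditions for a simulated plethysmograph flow trace.

    Each breath is a negative (inspiratory) half-sine whose integral
    magnitude equals ``tidal_volume_ml`` exactly on the sample grid,
    followed by a positive (expiratory) half-sine of equal area.
    ``gasp_mode`` makes breathing slow and irregular: random breaths gain
    long pauses and deeper deflections.  ``movement_epochs`` lists
    (onset_s, duration_s) artifact windows recorded into the trace's
    movement mask.
    """

    duration_s: float = 30.0
    sampling_rate_hz: float = 1000.0
    rate_bpm: float = 150.0
    rate_cv: float = 0.1
    tidal_volume_ml: float = 0.05
    insp_fraction: float = 0.35
    gasp_mode: bool = False
    noise_sd: float = 0.005
    movement_epochs: tuple[tuple[float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        _require_finite(
            "SimFlowConfig",
            self.duration_s,
            self.sampling_rate_hz,
            self.rate_bpm,
            self.rate_cv,
            self.tidal_volume_ml,
            self.insp_fraction,
            self.noise_sd,
        )
        if not (0 < self.insp_fraction < 1):
            raise ValueError("insp_fraction must lie in (0, 1)")
        if self.tidal_volume_ml < 0:
            raise ValueError("tidal_volume_ml must be non-negative")
        if not self.duration_s > 0 or not self.sampling_rate_hz > 0:
            raise ValueError("duration and sampling rate must be positive")
        if not self.rate_bpm > 0:
            raise ValueError("rate_bpm must be positive")


def _render_half_sine(flow: np.ndarray, i0: int, i1: int, volume_ml: float, sign: float, fs: float) -> None:
    """Render a half-sine phase on samples [i0, i1] with exact trapezoidal area."""
    m = i1 - i0
    if m < 2 or volume_ml == 0:
        return
    phase = np.sin(np.pi * np.arange(m + 1) / m)
    area = float(np.trapezoid(phase, dx=1.0 / fs))
    stop = min(i1 + 1, flow.size)
    flow[i0:stop] += sign * (volume_ml / area) * phase[: stop - i0]


def gen_flow_trace(config: SimFlowConfig) -> tuple[FlowTrace, GroundTruth]:
    """Simulate a plethysmograph flow trace; ground truth records each breath.

    Breath onsets follow Gamma-distributed periods (mean 60/rate_bpm, CV
    ``rate_cv``; exactly periodic when CV = 0, starting at t = 0).  In gasp
    mode roughly a third of cycles are stretched 2-5x with tidal volume
    deepened 1.5-2.5x.  Onsets snap to the sample grid and the rendered
    inspiratory area is normalized to the breath's true tidal volume.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    n = int(round(config.duration_s * fs))
    flow = np.zeros(n)

    base_period = 60.0 / config.rate_bpm
    t_insp = config.insp_fraction * base_period
    truths: list[tuple[float, float, float]] = []
    t = 0.0
    while True:
        period = base_period
        if config.rate_cv > 0:
            shape = 1.0 / config.rate_cv**2
            period = rng.gamma(shape, base_period / shape)
        tv = config.tidal_volume_ml
        if config.gasp_mode and rng.random() < 1.0 / 3.0:
            period *= rng.uniform(2.0, 5.0)
            tv *= rng.uniform(1.5, 2.5)
        t_exp = min(t_insp, max(period - t_insp, 1.0 / fs))
        i0 = int(round(t * fs))
        i1 = i0 + max(int(round(t_insp * fs)), 2)
        i2 = i1 + max(int(round(t_exp * fs)), 2)
        if i2 > n - 1:
            break  # incomplete terminal cycle: not rendered
        _render_half_sine(flow, i0, i1, tv, -1.0, fs)
        _render_half_sine(flow, i1, i2, tv, +1.0, fs)
        truths.append((i0 / fs, i1 / fs, tv))
        t += period

    if config.noise_sd > 0:
        flow += rng.normal(0.0, config.noise_sd, n)

    mask = None
    if config.movement_epochs:
        mask = np.zeros(n, dtype=bool)
        for onset, dur in config.movement_epochs:
            a = max(int(onset * fs), 0)
            b = min(int((onset + dur) * fs), n)
            mask[a:b] = True

    trace = FlowTrace(flow_ml_per_s=flow, sampling_rate_hz=fs, movement_mask=mask)
    return trace, GroundTruth(true_breaths=truths)


@dataclass(frozen=True)
class SimSomaConfig:
    """Conditions for simulated soma coordinate tables.

    Somas are drawn from a 2D Gaussian at ``centroid_um + shift_um`` in
    *standardized* coordinates (dorsal positive y, so a ventral shift has
    negative dy), then written raw: scaled by
    ``measured_halfwidth_um / 390`` and with left-side somas carrying
    negative x — so standardization must exactly invert the distortion.
    """

    n_embryos: int = 3
    somas_per_embryo: int = 400
    centroid_um: tuple[float, float] = (240.0, -140.0)
    covariance_um2: tuple[tuple[float, float], tuple[float, float]] = (
        (1600.0, 0.0),
        (0.0, 1600.0),
    )
    shift_um: tuple[float, float] = (0.0, 0.0)
    measured_halfwidth_um: float = 390.0
    left_fraction: float = 0.5
    genotype: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        _require_finite(
            "SimSomaConfig",
            *self.centroid_um,
            *self.shift_um,
            self.measured_halfwidth_um,
            self.left_fraction,
        )
        cov = np.asarray(self.covariance_um2, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("covariance must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("covariance must be positive-definite")
        if not self.measured_halfwidth_um > 0:
            raise ValueError("measured_halfwidth_um must be positive")
        if not (0 <= self.left_fraction <= 1):
            raise ValueError("left_fraction must lie in [0, 1]")
        if self.n_embryos < 0 or self.somas_per_embryo < 0:
            raise ValueError("counts must be non-negative")


def gen_soma_table(config: SimSomaConfig) -> SomaTable:
    """Simulate a raw (pre-standardization) soma table.

    The returned table carries the per-embryo measured half-width so
    :func:`respiquant.topography.standardize` can undo the distortion; the
    true standardized centroid is ``centroid_um + shift_um`` by construction.
    """
    rng = np.random.default_rng(config.seed)
    mean = np.asarray(config.centroid_um) + np.asarray(config.shift_um)
    cov = np.asarray(config.covariance_um2, dtype=float)
    scale = config.measured_halfwidth_um / REFERENCE_HALFWIDTH_UM
    rows = []
    for e in range(config.n_embryos):
        embryo_id = f"{config.genotype}_e{e + 1}"
        pts = rng.multivariate_normal(mean, cov, size=config.somas_per_embryo)
        sides = np.where(rng.random(config.somas_per_embryo) < config.left_fraction, "L", "R")
        for (x, y), side in zip(pts, sides):
            x_raw = abs(x) * scale
            if side == "L":
                x_raw = -x_raw
            rows.append((embryo_id, config.genotype, side, x_raw, y * scale))
    data = pd.DataFrame(rows, columns=SOMA_COLUMNS)
    halfwidths = {
        f"{config.genotype}_e{e + 1}": config.measured_halfwidth_um
        for e in range(config.n_embryos)
    }
    return SomaTable(data=data, standardized=False, halfwidths=halfwidths)


@dataclass(frozen=True)
class SimDendriteConfig:
    """Conditions for a simulated dendritic intensity field.

    ``rays`` is a list of (angle_deg, total_intensity, angular_sd_deg,
    radial_extent_um): each ray deposits its total intensity in a Gaussian
    angular band about its angle, out to its radial extent.  Angles follow
    the analysis convention (0 = lateral, counterclockwise toward dorsal).
    """

    image_size_px: tuple[int, int] = (256, 256)
    um_per_px: float = 2.0
    center_px: tuple[float, float] = (128.0, 128.0)
    body_radius_um: float = 40.0
    rays: tuple[tuple[float, float, float, float], ...] = ()
    background: float = 0.0
    noise_sd: float = 0.0
    body_intensity: float = 100.0
    midline_col_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require_finite(
            "SimDendriteConfig",
            self.um_per_px,
            *self.center_px,
            self.body_radius_um,
            self.background,
            self.noise_sd,
        )
        if self.body_radius_um < 0:
            raise ValueError("body_radius_um must be non-negative")
        for ray in self.rays:
            if len(ray) != 4:
                raise ValueError("each ray is (angle_deg, intensity, angular_sd_deg, extent_um)")
            if ray[1] < 0:
                raise ValueError("ray intensities must be non-negative")


def gen_dendrite_image(config: SimDendriteConfig) -> tuple[IntensityImage, GroundTruth]:
    """Simulate a dendrite image: background + noise + cell-body disc + angular rays.

    Each ray's deposited intensity is normalized to its configured total
    over the in-bounds pixels; rays whose radial extent leaves the image
    are clipped with a logged warning.  Negative noise excursions are
    clipped at zero.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size_px
    r0, c0 = config.center_px
    rows = np.arange(h)[:, None] - r0
    cols = np.arange(w)[None, :] - c0
    mirrored = c0 < config.midline_col_px
    lateral = -cols if mirrored else cols
    radius_um = np.hypot(rows * np.ones_like(cols), cols * np.ones_like(rows)) * config.um_per_px
    angle_deg = np.degrees(np.arctan2(-rows * np.ones_like(cols), lateral)) % 360.0

    img = np.full((h, w), float(config.background))
    img[radius_um < config.body_radius_um] += config.body_intensity

    edge_r = min(r0, h - 1 - r0, c0, w - 1 - c0) * config.um_per_px
    angles = []
    for angle, intensity, sd, extent in config.rays:
        if extent > edge_r:
            logger.warning("ray at %.0f deg extends beyond image bounds; clipped", angle)
        d = (angle_deg - angle + 180.0) % 360.0 - 180.0
        weight = np.exp(-0.5 * (d / max(sd, 1e-6)) ** 2)
        weight[(radius_um <= 0) | (radius_um > extent)] = 0.0
        total = weight.sum()
        if total > 0:
            img += intensity * weight / total
        angles.append(float(angle))

    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
    np.clip(img, 0.0, None, out=img)

    image = IntensityImage(pixels=img, um_per_px=config.um_per_px, midline_col_px=config.midline_col_px)
    return image, GroundTruth(true_ray_angles_deg=angles)
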
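"""Reading and writing the package's plain-text and TIFF interchange formats.

Traces travel as two-column delimited text (time_s, value) with an
optional JSON sidecar holding the generating config and seed; soma
tables as CSV with the fixed schema (embryo_id, genotype, side, x_um,
y_um) plus an optional per-embryo half-width CSV; images as
single-channel 16-bit TIFF (or matrix text) with a JSON frame sidecar;
density grids and metrics as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile

from .dendrites import IntensityImage, RadialFrame
from .nerve import BurstEvent, NerveTrace
from .pleth import Breath, FlowTrace
from .topography import SOMA_COLUMNS, DensityGrid, SomaTable

__all__ = [
    "write_trace",
    "read_nerve_trace",
    "read_flow_trace",
    "write_soma_table",
    "read_soma_table",
    "read_halfwidths",
    "write_image",
    "read_image",
    "write_frame",
    "read_frame",
    "write_burst_table",
    "write_breath_table",
    "write_density_grid",
    "write_json",
    "read_json",
    "to_jsonable",
]


def to_jsonable(obj: Any) -> Any:
    """Recursively convert dataclasses / numpy types to JSON-serializable values."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Mapping):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    return obj


def write_json(path: str | Path, payload: Any) -> None:
    Path(path).write_text(json.dumps(to_jsonable(payload), indent=2) + "\n")


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------- traces

def write_trace(
    path: str | Path,
    trace: NerveTrace | FlowTrace,
    sidecar: Mapping[str, Any] | None = None,
) -> None:
    """Write a trace as two-column delimited text, with an optional JSON sidecar."""
    path = Path(path)
    values = trace.samples if isinstance(trace, NerveTrace) else trace.flow_ml_per_s
    times = np.arange(values.size) / trace.sampling_rate_hz
    cols = [times, values]
    header = "time_s,value"
    if isinstance(trace, FlowTrace) and trace.movement_mask is not None:
        cols.append(trace.movement_mask.astype(int))
        header = "time_s,value,movement"
    np.savetxt(path, np.column_stack(cols), delimiter=",", header=header, comments="")
    if sidecar is not None:
        write_json(path.with_suffix(path.suffix + ".json"), sidecar)


def _read_trace(path: str | Path) -> tuple[np.ndarray, float, np.ndarray | None]:
    df = pd.read_csv(path)
    times = df.iloc[:, 0].to_numpy(dtype=float)
    if times.size < 2:
        raise ValueError("trace needs at least two samples")
    dts = np.diff(times)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
        raise ValueError("trace must be uniformly sampled")
    fs = 1.0 / float(np.mean(dts))
    mask = df.iloc[:, 2].to_numpy(dtype=bool) if df.shape[1] > 2 else None
    return df.iloc[:, 1].to_numpy(dtype=float), fs, mask


def read_nerve_trace(path: str | Path, label: str = "") -> NerveTrace:
    values, fs, _ = _read_trace(path)
    return NerveTrace(samples=values, sampling_rate_hz=fs, label=label or str(path))


def read_flow_trace(path: str | Path) -> FlowTrace:
    values, fs, mask = _read_trace(path)
    return FlowTrace(flow_ml_per_s=values, sampling_rate_hz=fs, movement_mask=mask)


# ------------------------------------------------------------ soma tables

def write_soma_table(path: str | Path, table: SomaTable, halfwidth_path: str | Path | None = None) -> None:
    table.data[SOMA_COLUMNS].to_csv(path, index=False)
    if halfwidth_path is not None and isinstance(table.halfwidths, Mapping):
        pd.DataFrame(
            {"embryo_id": list(table.halfwidths), "halfwidth_um": list(table.halfwidths.values())}
        ).to_csv(halfwidth_path, index=False)


def read_soma_table(
    path: str | Path,
    halfwidths: Mapping[str, float] | float | None = None,
    standardized: bool = False,
) -> SomaTable:
    data = pd.read_csv(path)
    return SomaTable(data=data, standardized=standardized, halfwidths=halfwidths)


def read_halfwidths(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path)
    return dict(zip(df["embryo_id"].astype(str), df["halfwidth_um"].astype(float)))


# ---------------------------------------------------------------- images

def write_image(path: str | Path, image: IntensityImage, frame: RadialFrame | None = None) -> None:
    """Write a single-channel 16-bit TIFF (or matrix text for .txt paths)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        px = image.pixels
        peak = float(px.max())
        scale = 65535.0 / peak if peak > 0 else 1.0
        tifffile.imwrite(path, np.round(px * scale).astype(np.uint16))
        meta: dict[str, Any] = {"um_per_px": image.um_per_px, "midline_col_px": image.midline_col_px,
                               "intensity_scale": scale}
    else:
        np.savetxt(path, image.pixels)
        meta = {"um_per_px": image.um_per_px, "midline_col_px": image.midline_col_px,
                "intensity_scale": 1.0}
    if frame is not None:
        meta["center_px"] = list(frame.center_px)
        meta["body_radius_um"] = frame.body_radius_um
    write_json(path.with_suffix(path.suffix + ".json"), meta)


def read_image(path: str | Path, um_per_px: float | None = None, midline_col_px: float | None = None) -> IntensityImage:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = read_json(sidecar) if sidecar.exists() else {}
    if path.suffix.lower() in {".tif", ".tiff"}:
        px = tifffile.imread(path).astype(float)
        px /= float(meta.get("intensity_scale", 1.0))
    else:
        px = np.loadtxt(path)
    return IntensityImage(
        pixels=px,
        um_per_px=um_per_px if um_per_px is not None else float(meta.get("um_per_px", 1.0)),
        midline_col_px=(
            midline_col_px if midline_col_px is not None else float(meta.get("midline_col_px", 0.0))
        ),
    )


def write_frame(path: str | Path, frame: RadialFrame) -> None:
    write_json(path, frame)


def read_frame(path: str | Path) -> RadialFrame:
    d = read_json(path)
    return RadialFrame(
        center_px=tuple(d["center_px"]),
        body_radius_um=float(d.get("body_radius_um", 0.0)),
        outer_radius_um=d.get("outer_radius_um"),
    )


# ------------------------------------------------------------- tabular outputs

def write_burst_table(path: str | Path, bursts: list[BurstEvent]) -> None:
    pd.DataFrame(
        [
            {
                "onset_s": b.onset_s,
                "offset_s": b.offset_s,
                "duration_s": b.duration_s,
                "peak_integrated_uvs": b.peak_integrated_uvs,
                "kind": b.kind,
            }
            for b in bursts
        ]
    ).to_csv(path, index=False)


def write_breath_table(path: str | Path, breaths: list[Breath]) -> None:
    pd.DataFrame(
        [
            {
                "insp_onset_s": b.insp_onset_s,
                "insp_offset_s": b.insp_offset_s,
                "exp_offset_s": b.exp_offset_s,
                "tidal_volume_ml": b.tidal_volume_ml,
                "period_s": b.period_s,
                "resting": b.resting,
            }
            for b in breaths
        ]
    ).to_csv(path, index=False)


def write_density_grid(path: str | Path, grid: DensityGrid) -> None:
    """Export a density grid as JSON (edges + matrix), contour-plot ready."""
    write_json(
        path,
        {
            "x_edges_um": grid.x_edges,
            "y_edges_um": grid.y_edges,
            "density": grid.density,
            "bandwidth_um": grid.bandwidth_um,
            "axes": "y dorsal-positive; x lateral from midline; density rows are y",
        },
    )
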
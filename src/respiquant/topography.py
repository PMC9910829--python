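"""Motor neuron positional topography.

Soma coordinates are expressed relative to the midpoint of the spinal
cord midline (x = 0, y = 0; x mediolateral, y ventrodorsal with dorsal
positive, so a ventral shift means dy < 0).  To pool sections across
embryos, each section is rescaled isotropically onto a standardized cord
in which the midline-to-lateral-edge distance is 390 um (the e13.5
reference), and left-side somas (negative x in raw tables) are mirrored
onto the right hemicord.  Group topography is summarised as a
fixed-bandwidth Gaussian kernel density on a common grid; groups are
compared by the Pearson correlation of their density grids, and group
statistics operate on per-embryo mean positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REFERENCE_HALFWIDTH_UM = 390.0

SOMA_COLUMNS = ["embryo_id", "genotype", "side", "x_um", "y_um"]

__all__ = [
    "REFERENCE_HALFWIDTH_UM",
    "SOMA_COLUMNS",
    "SomaTable",
    "DensityGrid",
    "PositionSummary",
    "standardize",
    "density_estimate",
    "common_edges",
    "mean_positions",
    "positional_correlation",
    "correlation_matrix",
]


@dataclass(frozen=True)
class SomaTable:
    """Per-soma records (embryo, genotype, side, x_um, y_um).

    Before standardization, x is signed (left-side somas negative) and in
    the raw per-section scale; after, all somas lie on the right hemicord
    of the 390 um standardized cord.  ``halfwidths`` maps embryo_id to the
    measured midline-to-lateral-edge distance of its sections (a scalar
    applies to all embryos).
    """

    data: pd.DataFrame
    standardized: bool = False
    halfwidths: Mapping[str, float] | float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in SOMA_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"soma table missing columns: {missing}")
        xy = self.data[["x_um", "y_um"]].to_numpy(dtype=float)
        if xy.size and not np.all(np.isfinite(xy)):
            raise ValueError("soma coordinates must be finite")

    def __len__(self) -> int:
        return len(self.data)

    def coords(self) -> np.ndarray:
        return self.data[["x_um", "y_um"]].to_numpy(dtype=float)


@dataclass(frozen=True)
class DensityGrid:
    """Normalized 2D soma density over standardized coordinates."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray  # shape (n_y, n_x), integrates to 1
    bandwidth_um: float

    @property
    def cell_area(self) -> float:
        return float((self.x_edges[1] - self.x_edges[0]) * (self.y_edges[1] - self.y_edges[0]))

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            0.5 * (self.x_edges[:-1] + self.x_edges[1:]),
            0.5 * (self.y_edges[:-1] + self.y_edges[1:]),
        )


@dataclass(frozen=True)
class PositionSummary:
    embryo_id: str
    mean_x_um: float
    mean_y_um: float
    n_somas: int


def _halfwidth_for(table: SomaTable, embryo_id: str, override=None) -> float | None:
    hw = override if override is not None else table.halfwidths
    if hw is None:
        return None
    if isinstance(hw, Mapping):
        return hw.get(embryo_id)
    return float(hw)


def standardize(
    table: SomaTable,
    halfwidths: Mapping[str, float] | float | None = None,
    reference_halfwidth_um: float = REFERENCE_HALFWIDTH_UM,
) -> SomaTable:
    """Rescale soma coordinates onto the standardized cord and mirror left somas.

    Both coordinates are scaled isotropically by reference/measured
    half-width; somas whose embryo lacks a measured half-width are excluded
    (with a logged count).  Left-side somas end up with x = |x| so both
    sides pool onto one hemicord.
    """
    if table.standardized:
        raise ValueError("table is already standardized")
    frames = []
    n_dropped = 0
    for embryo_id, group in table.data.groupby("embryo_id", sort=False):
        measured = _halfwidth_for(table, embryo_id, halfwidths)
        if measured is None:
            n_dropped += len(group)
            continue
        if not measured > 0:
            raise ValueError(f"measured half-width must be positive (embryo {embryo_id})")
        scale = reference_halfwidth_um / float(measured)
        out = group.copy()
        out["x_um"] = np.abs(out["x_um"].to_numpy(dtype=float)) * scale
        out["y_um"] = out["y_um"].to_numpy(dtype=float) * scale
        frames.append(out)
    if n_dropped:
        logger.warning("excluded %d somas lacking a measured half-width", n_dropped)
    data = (
        pd.concat(frames, ignore_index=True)
        if frames
        else table.data.iloc[0:0].reset_index(drop=True)
    )
    return SomaTable(data=data, standardized=True, halfwidths=None)


def common_edges(
    tables: Sequence[SomaTable], bin_um: float = 10.0, bandwidth_um: float = 15.0
) -> tuple[np.ndarray, np.ndarray]:
    """Grid edges covering the union bounding box of several tables, padded 3 bandwidths."""
    coords = np.vstack([t.coords() for t in tables if len(t)])
    pad = 3.0 * bandwidth_um
    x0, y0 = coords.min(axis=0) - pad
    x1, y1 = coords.max(axis=0) + pad
    x_edges = np.arange(x0, x1 + bin_um, bin_um)
    y_edges = np.arange(y0, y1 + bin_um, bin_um)
    return x_edges, y_edges


def density_estimate(
    table: SomaTable,
    bin_um: float = 10.0,
    bandwidth_um: float = 15.0,
    edges: tuple[np.ndarray, np.ndarray] | None = None,
) -> DensityGrid:
    """Fixed-bandwidth isotropic Gaussian KDE on a regular grid, normalized to 1.

    The grid defaults to the table's bounding box padded by three
    bandwidths with ``bin_um`` cells; pass ``edges`` (from
    :func:`common_edges`) to co-evaluate several groups on one lattice.
    """
    if not table.standardized:
        raise ValueError("density estimation requires a standardized table")
    pts = table.coords()
    if len(pts) < 2:
        raise ValueError("density estimation requires at least two somas")
    bw = float(bandwidth_um)
    spread = float(pts.std(axis=0).max())
    if spread == 0.0:
        logger.warning("degenerate (identical) soma positions; applying bandwidth floor")
    bw = max(bw, 1e-6)
    if edges is None:
        x_edges, y_edges = common_edges([table], bin_um=bin_um, bandwidth_um=bw)
    else:
        x_edges, y_edges = edges
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    dx = (xc[None, :] - pts[:, 0][:, None]) / bw  # (n_pts, n_x)
    dy = (yc[None, :] - pts[:, 1][:, None]) / bw  # (n_pts, n_y)
    gx = np.exp(-0.5 * dx**2)
    gy = np.exp(-0.5 * dy**2)
    density = gy.T @ gx  # (n_y, n_x)
    cell_area = float((x_edges[1] - x_edges[0]) * (y_edges[1] - y_edges[0]))
    total = density.sum() * cell_area
    if total <= 0:
        raise ValueError("density normalization failed (empty support)")
    return DensityGrid(
        x_edges=np.asarray(x_edges, float),
        y_edges=np.asarray(y_edges, float),
        density=density / total,
        bandwidth_um=bw,
    )


def mean_positions(table: SomaTable) -> list[PositionSummary]:
    """Per-embryo mean positions — the statistical units for group tests."""
    if not table.standardized:
        raise ValueError("mean positions require a standardized table")
    out = []
    for embryo_id, group in table.data.groupby("embryo_id", sort=False):
        out.append(
            PositionSummary(
                embryo_id=str(embryo_id),
                mean_x_um=float(group["x_um"].mean()),
                mean_y_um=float(group["y_um"].mean()),
                n_somas=len(group),
            )
        )
    return out


def positional_correlation(grid_a: DensityGrid, grid_b: DensityGrid) -> float:
    """Pearson correlation of two density grids evaluated on the same lattice."""
    if not (
        np.array_equal(grid_a.x_edges, grid_b.x_edges)
        and np.array_equal(grid_a.y_edges, grid_b.y_edges)
    ):
        raise ValueError("density grids must share identical edges")
    a = grid_a.density.ravel()
    b = grid_b.density.ravel()
    return float(np.corrcoef(a, b)[0, 1])


def correlation_matrix(grids: Sequence[DensityGrid]) -> np.ndarray:
    """Pairwise positional correlations of k co-evaluated groups (symmetric, unit diagonal)."""
    k = len(grids)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r[i, j] = r[j, i] = positional_correlation(grids[i], grids[j])
    return r
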
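"""Synthetic cell arrangements and point-pattern file I/O.

The substrate of every simulation and analysis in this package is a flat list
of 2D cell centroids (in µm) inside a rectangular field.  Arrangements come
from two sources: the built-in generator, which emulates the cellular
geometry of a cortical slice (uniform random placement with a denser
horizontal band through the middle third, mimicking a cortical layer), or a
delimited text table exported from any external segmentation pipeline.

Generated boxes use periodic boundaries (minimum-image distances); imported
slices default to open boundaries, because real tissue has edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CellArrangement",
    "GeneratorConfig",
    "generate_arrangement",
    "read_arrangement",
    "write_arrangement",
    "mean_nnd_to_density",
    "density_to_mean_nnd",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


class FormatError(ValueError):
    """Malformed cell-position table."""


def mean_nnd_to_density(spacing: float) -> float:
    """Areal density D (µm^-2) of a homogeneous Poisson process whose mean
    nearest-neighbour distance is ``spacing``.

    For a 2D Poisson process of density D the NND is distributed as
    2*pi*r*D*exp(-pi*r^2*D), whose mean is 1/(2*sqrt(D)).
    """
    if spacing <= 0:
        raise ConfigError(f"spacing must be positive, got {spacing}")
    return 1.0 / (2.0 * spacing) ** 2


def density_to_mean_nnd(density: float) -> float:
    """Mean nearest-neighbour distance 1/(2*sqrt(D)) of a Poisson process."""
    if density <= 0:
        raise ConfigError(f"density must be positive, got {density}")
    return 1.0 / (2.0 * np.sqrt(density))


@dataclass(frozen=True)
class CellArrangement:
    """Immutable 2D point set of cell centroids with box geometry.

    Parameters
    ----------
    positions:
        ``(n, 2)`` float array of (x, y) coordinates in µm; all coordinates
        lie in ``[0, box_width) x [0, box_height)``.
    box_width, box_height:
        Field extent in µm.
    boundary_mode:
        ``"periodic"`` (minimum-image distances) or ``"open"``.
    cell_type:
        Optional per-cell categorical label (e.g. TA / CB / NFT).
    """

    positions: np.ndarray
    box_width: float
    box_height: float
    boundary_mode: str = "periodic"
    cell_type: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        object.__setattr__(self, "positions", pos)
        if self.boundary_mode not in ("periodic", "open"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")
        if self.box_width <= 0 or self.box_height <= 0:
            raise ValueError("box dimensions must be positive")
        if pos.size and (
            pos[:, 0].min() < 0
            or pos[:, 1].min() < 0
            or pos[:, 0].max() >= self.box_width
            or pos[:, 1].max() >= self.box_height
        ):
            raise ValueError("coordinates must lie within [0, box_width) x [0, box_height)")
        if self.cell_type is not None:
            ct = np.asarray(self.cell_type)
            if ct.shape[0] != pos.shape[0]:
                raise ValueError("cell_type length must match number of cells")
            object.__setattr__(self, "cell_type", ct)

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def area(self) -> float:
        return self.box_width * self.box_height

    @property
    def density(self) -> float:
        """Overall areal cell density (µm^-2)."""
        return self.n_cells / self.area

    @property
    def boxsize(self) -> Optional[np.ndarray]:
        """Box lengths for periodic KD-trees, or None for open slices."""
        if self.boundary_mode == "periodic":
            return np.array([self.box_width, self.box_height])
        return None

    def displacement(self, origin: np.ndarray) -> np.ndarray:
        """Displacements from ``origin`` (shape (2,)) to every cell,
        minimum-image under periodic boundaries."""
        d = self.positions - np.asarray(origin, dtype=float)
        if self.boundary_mode == "periodic":
            box = np.array([self.box_width, self.box_height])
            d -= box * np.round(d / box)
        return d

    def distances_from(self, origin: np.ndarray) -> np.ndarray:
        """Distance from ``origin`` to every cell (boundary-mode aware)."""
        d = self.displacement(origin)
        return np.hypot(d[:, 0], d[:, 1])


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-slice generator.

    ``target_mean_nnd`` is the overall mean nearest-neighbour distance of
    the arrangement in µm; the generator calibrates the per-region densities
    so the density-weighted mean NND equals this value, with the middle
    ``band_extent`` of the y-range packed at ``band_spacing_factor`` times
    the spacing of the outer sections.
    """

    n_cells: int = 10002
    target_mean_nnd: float = 27.3
    band_spacing_factor: float = 0.8
    band_extent: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.target_mean_nnd <= 0:
            raise ConfigError("target_mean_nnd must be positive")
        if not 0 < self.band_spacing_factor <= 1:
            raise ConfigError("band_spacing_factor must be in (0, 1]")
        if not 0 <= self.band_extent <= 1:
            raise ConfigError("band_extent must be in [0, 1]")


def _region_layout(config: GeneratorConfig) -> Tuple[float, float, float, float]:
    """Solve for (outside spacing, band spacing, band density, outside density).

    Let f = band_spacing_factor and b = band_extent.  Region densities are
    D = 1/(2*spacing)^2, so the band holds a fraction
    q = (b/f^2) / (b/f^2 + (1-b)) of the cells.  The outside spacing s_o is
    chosen so the density-weighted mean NND, q*f*s_o + (1-q)*s_o, equals
    target_mean_nnd.
    """
    f = config.band_spacing_factor
    b = config.band_extent
    w_band = b / f**2
    q = w_band / (w_band + (1.0 - b)) if (w_band + (1.0 - b)) > 0 else 1.0
    s_out = config.target_mean_nnd / (q * f + (1.0 - q))
    s_band = f * s_out
    return s_out, s_band, mean_nnd_to_density(s_band), mean_nnd_to_density(s_out)


def generate_arrangement(config: GeneratorConfig) -> CellArrangement:
    """Generate a random cell arrangement with a denser central band.

    x-coordinates are uniform over the box; y-coordinates are uniform within
    each density band.  The box is square, sized so that the region densities
    account for exactly ``n_cells`` in expectation.  Periodic boundaries.
    Identical config (including seed) reproduces the arrangement bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    s_out, s_band, d_band, d_out = _region_layout(config)
    b = config.band_extent

    # Box side from n = L^2 * (b*D_band + (1-b)*D_out).
    mean_density = b * d_band + (1.0 - b) * d_out
    side = float(np.sqrt(n / mean_density))

    # Expected share of cells in the band; realized count is the rounded share.
    q = b * d_band / mean_density
    n_band = int(round(n * q))
    n_out = n - n_band

    y_lo = side * (1.0 - b) / 2.0
    y_hi = side * (1.0 + b) / 2.0

    x = rng.uniform(0.0, side, n)
    y_band = rng.uniform(y_lo, y_hi, n_band)
    # Outer cells: uniform over the complement of the band.
    y_out = rng.uniform(0.0, side * (1.0 - b), n_out)
    y_out = np.where(y_out >= y_lo, y_out + side * b, y_out)
    y = np.concatenate([y_band, y_out])

    pos = np.column_stack([x, y])
    # Guard against the half-open interval: fold exact-boundary hits back.
    pos[pos[:, 0] >= side, 0] = 0.0
    pos[pos[:, 1] >= side, 1] = 0.0
    return CellArrangement(pos, side, side, boundary_mode="periodic")


_DEFAULT_COLUMNS: Mapping[str, str] = {
    "x": "x_um",
    "y": "y_um",
    "cell_type": "cell_type",
    "aggregated": "aggregated",
    "t_trigger": "t_trigger",
}


def read_arrangement(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    boundary_mode: str = "open",
):
    """Read a cell-position table (CSV, header row, coordinates in µm).

    Returns ``(arrangement, state)`` where ``state`` is an
    :class:`~aggsim.simulator.AggregationState` if an aggregated-flag column
    is present, else ``None``.  Rows with missing coordinates are dropped
    with a warning reporting the count.  The box is the tight bounding box
    of the data and the boundary mode defaults to open, as appropriate for
    an imported tissue slice.
    """
    from .simulator import AggregationState  # local import avoids a cycle

    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("x", "y"):
        if cols[key] not in df.columns:
            raise FormatError(f"missing mandatory column {cols[key]!r} in {path}")
    for key in ("x", "y"):
        numeric = pd.to_numeric(df[cols[key]], errors="coerce")
        bad = numeric.isna() & df[cols[key]].notna()
        if bad.any():
            raise FormatError(
                f"non-numeric {cols[key]!r} value at row index {int(bad.idxmax())}"
            )
        df[cols[key]] = numeric
    n_raw = len(df)
    df = df.dropna(subset=[cols["x"], cols["y"]])
    if len(df) < n_raw:
        warnings.warn(
            f"dropped {n_raw - len(df)} row(s) with missing coordinates",
            stacklevel=2,
        )
    xy = df[[cols["x"], cols["y"]]].to_numpy(dtype=float)
    if len(xy) == 0:
        raise FormatError(f"no valid coordinate rows in {path}")
    # Coordinates are preserved exactly; only tables with negative
    # coordinates are shifted so the box origin is the lower-left corner.
    offset = np.minimum(xy.min(axis=0), 0.0)
    if (offset < 0).any():
        warnings.warn("negative coordinates shifted to a zero-based origin", stacklevel=2)
        xy = xy - offset
    width = float(xy[:, 0].max()) or 1.0
    height = float(xy[:, 1].max()) or 1.0
    # Half-open box: nudge the extent so max coordinates are interior.
    eps = 1e-9
    arrangement = CellArrangement(
        xy,
        box_width=width * (1 + eps) + eps,
        box_height=height * (1 + eps) + eps,
        boundary_mode=boundary_mode,
        cell_type=(
            df[cols["cell_type"]].to_numpy() if cols["cell_type"] in df.columns else None
        ),
    )
    state = None
    if cols["aggregated"] in df.columns:
        x = df[cols["aggregated"]].to_numpy(dtype=float).astype(bool)
        t_trig = np.full(len(df), np.nan)
        if cols["t_trigger"] in df.columns:
            t_trig = df[cols["t_trigger"]].to_numpy(dtype=float)
        state = AggregationState(x=x, t_trigger=t_trig, t_now=float(np.nanmax(t_trig)) if np.isfinite(t_trig).any() else 0.0)
    return arrangement, state


def write_arrangement(arrangement: CellArrangement, path, state=None) -> None:
    """Write one row per cell: x_um, y_um[, cell_type][, aggregated, t_trigger].

    Comma-delimited, UTF-8, mandatory header; coordinates in µm at full
    floating-point precision (round-trips exactly through
    :func:`read_arrangement`).
    """
    data = {
        "x_um": arrangement.positions[:, 0],
        "y_um": arrangement.positions[:, 1],
    }
    if arrangement.cell_type is not None:
        data["cell_type"] = arrangement.cell_type
    if state is not None:
        data["aggregated"] = state.x.astype(int)
        data["t_trigger"] = state.t_trigger
    df = pd.DataFrame(data)
    path = Path(path)
    try:
        df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"could not write arrangement to {path}: {exc}") from exc
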
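"""Spatial summary statistics of aggregated-cell point patterns.

These are the measures used to compare data and model at two length scales:

* cellular scale — nearest-neighbour distance (NND) distributions and their
  analytic Poisson limits;
* hundreds of µm to mm — the nucleus-normalized radial distribution
  function g_norm(r), rolling density maps, and the aggregates-per-nucleus
  (APN) value contrasted between nucleus-density classes.

For a purely cell-autonomous (random) process the aggregated-cell NND
follows 2*pi*r*D*exp(-pi*r^2*D) with D the aggregate density; in the
direct-neighbour-coupling limit the same law holds with the all-cell
density D_c.  g_norm(r) = g_agg(r)/g_nuc(r) is the local fraction of cells
aggregated at distance r from an aggregated cell, so it is 1 in fully
aggregated regions and equals the overall fraction aggregated for a random
pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, optimize, stats
from scipy.spatial import cKDTree

from .fixtures import CellArrangement, density_to_mean_nnd

__all__ = [
    "NNDSample",
    "RDFCurve",
    "DensityGrid",
    "DensitySegmentation",
    "APNGrid",
    "CrossTypeNND",
    "nnd",
    "aggregated_nnd",
    "analytic_nnd_pdf",
    "analytic_nnd_cdf",
    "rdf_normalized",
    "rolling_density",
    "segment_density",
    "apn",
    "cross_type_nnd",
    "FitFailureError",
]

#: labels used by the nucleus-density segmentation
BACKGROUND, LOW, MID, HIGH = 0, 1, 2, 3


class FitFailureError(RuntimeError):
    """Gaussian fit of the density histogram failed (degenerate input)."""


@dataclass(frozen=True)
class NNDSample:
    """Per-point nearest-neighbour distances plus a normalized histogram."""

    distances: np.ndarray
    source: str = "aggregated"  # aggregated | all_cells | cross_type
    bin_width: float = 10.0

    def histogram(self, edges: Optional[np.ndarray] = None) -> Tuple[np.ndarray, np.ndarray]:
        """(edges, density) with the density integrating to 1."""
        if edges is None:
            hi = float(self.distances.max()) if self.distances.size else self.bin_width
            edges = np.arange(0.0, hi + 2 * self.bin_width, self.bin_width)
        counts, edges = np.histogram(self.distances, bins=edges, density=True)
        return edges, counts

    @property
    def mean(self) -> float:
        return float(self.distances.mean())


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, CellArrangement):
        return obj.positions
    return np.asarray(obj, dtype=float)


def _boxsize_for(boundary_mode: str, box: Optional[Tuple[float, float]]):
    if boundary_mode == "periodic":
        if box is None:
            raise ValueError("periodic boundaries require a box size")
        return np.asarray(box, dtype=float)
    return None


def nnd(
    points_query,
    points_reference,
    exclude_self: bool = False,
    boundary_mode: str = "open",
    box: Optional[Tuple[float, float]] = None,
    source: str = "aggregated",
) -> NNDSample:
    """Exact nearest-neighbour distance from each query point to the reference set.

    With ``exclude_self`` the nearest *distinct* reference point is used
    (for query == reference).  Periodic boundaries use minimum-image
    distances via a periodic KD-tree.
    """
    q = _as_points(points_query)
    ref = _as_points(points_reference)
    k = 2 if exclude_self else 1
    if ref.shape[0] < k:
        raise ValueError(f"need at least {k} reference point(s)")
    tree = cKDTree(ref, boxsize=_boxsize_for(boundary_mode, box))
    dist, _ = tree.query(q, k=k)
    if exclude_self:
        dist = dist[:, 1]
    return NNDSample(np.asarray(dist, dtype=float), source=source)


def aggregated_nnd(arrangement: CellArrangement, state) -> NNDSample:
    """NND sample of the aggregated cells of an arrangement."""
    pts = arrangement.positions[state.x]
    return nnd(
        pts,
        pts,
        exclude_self=True,
        boundary_mode=arrangement.boundary_mode,
        box=(arrangement.box_width, arrangement.box_height),
    )


def analytic_nnd_pdf(r, density: float):
    """Poisson nearest-neighbour PDF 2*pi*r*D*exp(-pi*r^2*D).

    ``density`` is the areal density of the point set (aggregate density D
    in the random limit; all-cell density D_c in the direct-neighbour
    coupling limit).
    """
    r = np.asarray(r, dtype=float)
    if density <= 0:
        raise ValueError("density must be positive")
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    return 2.0 * np.pi * r * density * np.exp(-np.pi * r**2 * density)


def analytic_nnd_cdf(r, density: float):
    """CDF of the Poisson nearest-neighbour law: 1 - exp(-pi r^2 D)."""
    r = np.asarray(r, dtype=float)
    if density <= 0:
        raise ValueError("density must be positive")
    return -np.expm1(-np.pi * r**2 * density)


@dataclass(frozen=True)
class RDFCurve:
    """Nucleus-normalized radial distribution function.

    ``g_agg`` and ``g_norm`` use aggregated cells as reference points;
    ``g_norm = g_agg / g_nuc`` is the local fraction of cells aggregated at
    distance r, NaN where the nucleus RDF is zero.  ``random_reference`` is
    the flat level expected for random aggregation (the overall fraction of
    cells aggregated).
    """

    r: np.ndarray
    dr: float
    g_agg: np.ndarray
    g_nuc: np.ndarray
    g_norm: np.ndarray
    random_reference: float
    counts_agg: np.ndarray = field(repr=False, default=None)
    counts_nuc: np.ndarray = field(repr=False, default=None)


def _annulus_counts(refs: np.ndarray, targets: np.ndarray, edges: np.ndarray, boxsize) -> np.ndarray:
    """Pair counts per annulus [r_k, r_k+1) from each reference to targets.

    Coincident (zero-distance) pairs — a reference point that is itself a
    member of the target set — are excluded, so a point never counts itself.
    """
    t_ref = cKDTree(refs, boxsize=boxsize)
    t_tar = cKDTree(targets, boxsize=boxsize)
    # edges[0] = 0, so zero-distance (self) pairs land in the cumulative
    # count at the first edge and drop out of the per-annulus differences.
    cumulative = t_ref.count_neighbors(t_tar, edges)
    return np.diff(cumulative).astype(float)


def rdf_normalized(
    aggregated,
    nuclei,
    dr: float = 50.0,
    r_max: float = 2000.0,
    boundary_mode: str = "periodic",
    box: Optional[Tuple[float, float]] = None,
) -> RDFCurve:
    """Radial distribution of aggregated cells, normalized by the nuclei RDF.

    Both RDFs use the aggregated cells as reference points:
    g(r) = <dn_r / (2 pi r dr)> with dn_r the pair counts in the annulus
    [r, r+dr).  Periodic boxes use minimum-image distances (no edge
    correction needed); open slices exclude reference points closer than
    r_max to the boundary.  r_max is clipped to half the shorter box side.
    """
    agg = _as_points(aggregated)
    nuc = _as_points(nuclei)
    if agg.shape[0] == 0:
        raise ValueError("empty aggregated set: cannot compute an RDF")
    if dr <= 0:
        raise ValueError("dr must be positive")
    if box is not None:
        r_max = min(r_max, min(box) / 2.0)
    edges = np.arange(0.0, r_max + dr, dr)
    if len(edges) < 2:
        raise ValueError("r_max must allow at least one annulus")
    boxsize = _boxsize_for(boundary_mode, box)

    refs = agg
    if boundary_mode == "open":
        if box is None:
            lo, hi = nuc.min(axis=0), nuc.max(axis=0)
        else:
            lo, hi = np.zeros(2), np.asarray(box, dtype=float)
        interior = np.all((refs >= lo + r_max) & (refs <= hi - r_max), axis=1)
        if not interior.any():
            raise ValueError(
                "no reference points at least r_max from the slice boundary; "
                "reduce r_max"
            )
        refs = refs[interior]

    counts_agg = _annulus_counts(refs, agg, edges, boxsize)
    counts_nuc = _annulus_counts(refs, nuc, edges, boxsize)
    centers = 0.5 * (edges[:-1] + edges[1:])
    norm = refs.shape[0] * 2.0 * np.pi * centers * dr
    g_agg = counts_agg / norm
    g_nuc = counts_nuc / norm
    with np.errstate(divide="ignore", invalid="ignore"):
        g_norm = np.where(counts_nuc > 0, counts_agg / counts_nuc, np.nan)
    return RDFCurve(
        r=centers,
        dr=dr,
        g_agg=g_agg,
        g_nuc=g_nuc,
        g_norm=g_norm,
        random_reference=agg.shape[0] / nuc.shape[0],
        counts_agg=counts_agg,
        counts_nuc=counts_nuc,
    )


@dataclass(frozen=True)
class DensityGrid:
    """Rolling-averaged areal density on a square grid.

    ``values[iy, ix]`` is the box-filtered density (counts/µm²) of the
    window-sized grid cell at ``origin + (ix, iy) * window``.
    """

    values: np.ndarray
    window: float
    smoothing: int
    origin: Tuple[float, float]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


def rolling_density(
    points,
    window: float = 100.0,
    smoothing: int = 7,
    box: Optional[Tuple[float, float]] = None,
) -> DensityGrid:
    """Count points in window x window µm grid cells, divide by the window
    area, then average each cell over its smoothing x smoothing in-bounds
    neighbourhood (edge cells average over fewer neighbours)."""
    pts = _as_points(points)
    if isinstance(points, CellArrangement) and box is None:
        box = (points.box_width, points.box_height)
    if window <= 0:
        raise ValueError("window must be positive")
    if smoothing < 1 or smoothing % 2 == 0:
        raise ValueError("smoothing must be a positive odd number of grid cells")
    if box is None:
        box = (float(pts[:, 0].max()) + 1e-9, float(pts[:, 1].max()) + 1e-9)
    nx = max(1, int(np.ceil(box[0] / window)))
    ny = max(1, int(np.ceil(box[1] / window)))
    counts, _, _ = np.histogram2d(
        pts[:, 1], pts[:, 0], bins=[ny, nx], range=[[0, ny * window], [0, nx * window]]
    )
    density = counts / window**2
    if smoothing > 1:
        kernel_sum = ndimage.uniform_filter(density, size=smoothing, mode="constant")
        valid = ndimage.uniform_filter(
            np.ones_like(density), size=smoothing, mode="constant"
        )
        density = kernel_sum / valid
    return DensityGrid(density, window, smoothing, origin=(0.0, 0.0))


@dataclass(frozen=True)
class DensitySegmentation:
    """Gaussian-fit-based nucleus-density classes.

    The histogram of rolling nucleus densities is fitted with a Gaussian
    (mu, sd); grid cells below mu - 2 sd are background (excluded
    downstream), and the remaining cells are split into low / mid / high at
    mu - sd/2 and mu + sd/2.
    """

    mu_fit: float
    sd_fit: float
    boundaries: Tuple[float, float, float]  # (background, low/mid, mid/high)
    labels: np.ndarray  # per-grid-cell class: BACKGROUND/LOW/MID/HIGH


def _gaussian(x, a, mu, sd):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sd**2))


def segment_density(grid: DensityGrid) -> DensitySegmentation:
    """Fit a Gaussian to the histogram of grid densities and classify cells.

    Histogram bin widths follow the Freedman-Diaconis rule; the fit is least
    squares on bin heights.  Degenerate (near-constant) grids raise
    :class:`FitFailureError` advising manual thresholds.
    """
    values = grid.values.ravel()
    positive = values[values > 0]
    if np.unique(positive).size < 3:
        raise FitFailureError(
            "density grid is near-constant; set class boundaries manually"
        )
    iqr = stats.iqr(positive)
    if iqr <= 0:
        raise FitFailureError(
            "density grid has zero interquartile range; set boundaries manually"
        )
    bw = 2.0 * iqr / np.cbrt(positive.size)
    n_bins = max(5, int(np.ceil((positive.max() - positive.min()) / bw)))
    heights, edges = np.histogram(positive, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(heights.max()), float(positive.mean()), float(positive.std()) or bw)
    try:
        popt, _ = optimize.curve_fit(
            _gaussian, centers, heights, p0=p0, maxfev=10000
        )
    except RuntimeError as exc:
        raise FitFailureError(
            f"Gaussian fit did not converge ({exc}); set boundaries manually"
        ) from exc
    _, mu, sd = popt
    sd = abs(float(sd))
    mu = float(mu)
    if sd == 0:
        raise FitFailureError("fitted width is zero; set boundaries manually")
    b_bg, b_low, b_high = mu - 2.0 * sd, mu - 0.5 * sd, mu + 0.5 * sd
    labels = np.full(grid.values.shape, LOW, dtype=np.int8)
    labels[grid.values < b_bg] = BACKGROUND
    labels[(grid.values >= b_low) & (grid.values < b_high)] = MID
    labels[grid.values >= b_high] = HIGH
    return DensitySegmentation(mu, sd, (b_bg, b_low, b_high), labels)


@dataclass(frozen=True)
class APNGrid:
    """Aggregates-per-nucleus map: local fraction of cells aggregated.

    APN is the rolling aggregate density divided by the rolling nucleus
    density; NaN where the nucleus density is zero or the cell is
    background.  ``apn_ratio`` is mean APN in high- over low-density cells
    (the headline diagnostic of spatial coupling: ~1 for cell-autonomous
    aggregation, > 1 under coupling).
    """

    values: np.ndarray
    by_class: dict  # {LOW/MID/HIGH: mean APN}
    apn_ratio: float
    n_masked: int  # non-background cells with zero nucleus density

    def histogram(
        self, n_bins: int = 50, edges: Optional[np.ndarray] = None
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Normalized APN histogram (heights sum to 1) over valid cells."""
        vals = self.values[np.isfinite(self.values)]
        if edges is None:
            hi = float(vals.max()) if vals.size and vals.max() > 0 else 1.0
            edges = np.linspace(0.0, hi, n_bins + 1)
        heights, edges = np.histogram(vals, bins=edges)
        total = heights.sum()
        heights = heights / total if total > 0 else heights.astype(float)
        return edges, heights


def apn(
    agg_grid: DensityGrid,
    nuc_grid: DensityGrid,
    segmentation: DensitySegmentation,
) -> APNGrid:
    """Per-grid-cell aggregates-per-nucleus with background masked out."""
    if agg_grid.values.shape != nuc_grid.values.shape or agg_grid.window != nuc_grid.window:
        raise ValueError("aggregate and nucleus grids must share geometry")
    if segmentation.labels.shape != nuc_grid.values.shape:
        raise ValueError("segmentation does not match the grid geometry")
    labels = segmentation.labels
    valid = (labels != BACKGROUND) & (nuc_grid.values > 0)
    n_masked = int(((labels != BACKGROUND) & (nuc_grid.values <= 0)).sum())
    values = np.full(nuc_grid.values.shape, np.nan)
    values[valid] = agg_grid.values[valid] / nuc_grid.values[valid]
    by_class = {}
    for cls in (LOW, MID, HIGH):
        sel = valid & (labels == cls)
        by_class[cls] = float(values[sel].mean()) if sel.any() else np.nan
    low, high = by_class[LOW], by_class[HIGH]
    ratio = high / low if (np.isfinite(low) and low > 0 and np.isfinite(high)) else np.nan
    return APNGrid(values, by_class, ratio, n_masked)


@dataclass(frozen=True)
class CrossTypeNND:
    """Mean NND from type-A aggregates to the nearest type-B aggregate,
    with the random-placement baseline 1/(2 sqrt(D_B))."""

    type_pair: Tuple[str, str]
    mean_observed: float
    mean_random_baseline: float


def cross_type_nnd(
    arrangement: CellArrangement, state, type_a: str, type_b: str
) -> CrossTypeNND:
    """Distance from each aggregated A-cell to the nearest aggregated B-cell.

    The baseline is the Poisson expectation at the areal density of
    aggregated B cells; an observed mean well below it indicates
    preferential triggering between the types.  A == B reduces to the
    within-type NND (self-excluded).
    """
    if arrangement.cell_type is None:
        raise ValueError("arrangement has no cell_type labels")
    agg = np.asarray(state.x, dtype=bool)
    sel_a = agg & (arrangement.cell_type == type_a)
    sel_b = agg & (arrangement.cell_type == type_b)
    if not sel_a.any() or not sel_b.any():
        raise ValueError("need at least one aggregated cell of each type")
    pts_a = arrangement.positions[sel_a]
    pts_b = arrangement.positions[sel_b]
    sample = nnd(
        pts_a,
        pts_b,
        exclude_self=(type_a == type_b),
        boundary_mode=arrangement.boundary_mode,
        box=(arrangement.box_width, arrangement.box_height),
        source="cross_type",
    )
    d_b = pts_b.shape[0] / arrangement.area
    return CrossTypeNND((type_a, type_b), sample.mean, density_to_mean_nnd(d_b))
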
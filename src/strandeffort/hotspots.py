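"""Planar hotspot pipeline: event aggregation, ISA, Getis-Ord Gi*, IDW.

The pipeline mirrors the standard GIS hotspot workflow on projected
(metre) coordinates:

1. ``integrate_collect`` snaps nearby stranding points together (default
   25 km tolerance) into weighted events, the weight x_j being the
   number of aggregated records;
2. ``isa_profile`` (incremental spatial autocorrelation) scans global
   Moran's I over increasing distance bands and picks the smallest
   distance where clustering peaks — the neighbourhood scale;
3. ``gi_star`` computes the local Getis-Ord Gi* Z-score per event,

       Gi* = [sum_j w_ij x_j - xbar * sum_j w_ij] /
             { S * sqrt[ (n * sum_j w_ij^2 - (sum_j w_ij)^2) / (n-1) ] }

   with S = sqrt(sum_j x_j^2 / n - xbar^2), self-weight w_ii = 1, and a
   zone-of-indifference weight kernel (full weight within the threshold
   distance, hyperbolic decay d0/d beyond it);
4. ``idw_surface`` interpolates the Z-scores onto a raster by inverse
   distance weighting, ``clip_to_buffer`` masks cells beyond the ISA
   peak distance from every event, and ``significant_area`` converts
   cells above a Z threshold (1.96 by default) into km².
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

__all__ = [
    "EventField",
    "WeightKind",
    "WeightScheme",
    "GiScore",
    "ISAProfile",
    "MoranResult",
    "Surface",
    "integrate_collect",
    "morans_i",
    "isa_profile",
    "gi_star",
    "idw_surface",
    "clip_to_buffer",
    "significant_area",
    "default_isa_bands",
]

_EPS = 1e-12


@dataclass
class EventField:
    """Aggregated weighted events plus the field statistics feeding Gi*."""

    points: np.ndarray  # (n, 2) planar metres
    weights: np.ndarray  # (n,) positive x_j

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.points.shape[0] != self.weights.shape[0]:
            raise ValueError("points and weights must align")
        if (self.weights <= 0).any():
            raise ValueError("event weights must be positive")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def x_bar(self) -> float:
        return float(self.weights.mean())

    @property
    def s_field(self) -> float:
        """sqrt(mean of x_j^2 minus squared mean); zero iff all weights equal."""
        v = float((self.weights**2).mean() - self.x_bar**2)
        return float(np.sqrt(max(v, 0.0)))

    def pairwise_distances(self) -> np.ndarray:
        return cdist(self.points, self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_id": np.arange(self.n),
                "easting_m": self.points[:, 0],
                "northing_m": self.points[:, 1],
                "weight": self.weights,
            }
        )


def integrate_collect(
    points: np.ndarray,
    tolerance: float = 25000.0,
    weights: np.ndarray | None = None,
) -> EventField:
    """Aggregate nearby points into weighted events (Integrate + Collect).

    Deterministic single-pass snapping: points are processed in ascending
    index order; each joins the cluster of the first earlier point lying
    within ``tolerance``, otherwise it seeds a new cluster.  A cluster is
    located at the weighted centroid of its members and carries the sum
    of member weights, so the total record count is conserved.  The GIS
    tools this emulates are order-dependent; fixing ascending-id order
    makes runs reproducible.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    npts = pts.shape[0]
    w = np.ones(npts) if weights is None else np.asarray(weights, dtype=float)
    if npts == 0:
        return EventField(points=np.empty((0, 2)), weights=np.empty(0))

    cluster_of = np.full(npts, -1, dtype=int)
    n_clusters = 0
    for i in range(npts):
        d = np.hypot(pts[:i, 0] - pts[i, 0], pts[:i, 1] - pts[i, 1])
        hits = np.nonzero(d <= tolerance)[0]
        if hits.size:
            cluster_of[i] = cluster_of[hits[0]]
        else:
            cluster_of[i] = n_clusters
            n_clusters += 1

    centers = np.zeros((n_clusters, 2))
    totals = np.zeros(n_clusters)
    for c in range(n_clusters):
        members = cluster_of == c
        wm = w[members]
        centers[c] = (pts[members] * wm[:, None]).sum(axis=0) / wm.sum()
        totals[c] = wm.sum()
    return EventField(points=centers, weights=totals)


# --------------------------------------------------------------------------
# global Moran's I and incremental spatial autocorrelation

@dataclass(frozen=True)
class MoranResult:
    band: float
    I: float
    expected_i: float
    variance_i: float
    z_score: float
    usable: bool
    note: str = ""


def _moran_stats(W: np.ndarray, z: np.ndarray) -> tuple[float, float, float]:
    """Moran's I with expectation and randomization-null variance."""
    n = len(z)
    W_sum = W.sum()
    m2 = float((z**2).sum())
    I = (n / W_sum) * float(z @ W @ z) / m2
    E = -1.0 / (n - 1)
    S1 = 0.5 * float(((W + W.T) ** 2).sum())
    S2 = float(((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum())
    b2 = n * float((z**4).sum()) / m2**2
    num = n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * W_sum**2) - b2 * (
        (n**2 - n) * S1 - 2 * n * S2 + 6 * W_sum**2
    )
    den = (n - 1) * (n - 2) * (n - 3) * W_sum**2
    var = num / den - E**2
    return I, E, var


def morans_i(field: EventField, band: float) -> MoranResult:
    """Global Moran's I of event weights with binary distance-band weights.

    Neighbours are events within ``band`` metres (self excluded).  The
    expectation under the randomization null is -1/(n-1); the variance is
    the standard randomization-null formula.  Bands leaving any event
    neighbourless, or fields with constant weights, return an unusable
    flagged result rather than raising, so ISA can skip them.
    """
    if field.n < 4:
        raise ValueError("Moran's I needs at least 4 events")
    D = field.pairwise_distances()
    W = ((D <= band) & (D > 0)).astype(float)
    np.fill_diagonal(W, 0.0)
    if (W.sum(axis=1) == 0).any():
        return MoranResult(band, np.nan, np.nan, np.nan, np.nan, False, "isolated event at this band")
    z = field.weights - field.x_bar
    if np.allclose(z, 0.0):
        return MoranResult(band, np.nan, np.nan, np.nan, np.nan, False, "constant weights")
    I, E, var = _moran_stats(W, z)
    if var <= 0:
        return MoranResult(band, I, E, var, np.nan, False, "non-positive null variance")
    return MoranResult(band, I, E, var, (I - E) / np.sqrt(var), True)


@dataclass
class ISAProfile:
    distances: np.ndarray
    results: list[MoranResult]
    peak_distance: float
    peak_index: int
    no_local_peak: bool

    @property
    def z_scores(self) -> np.ndarray:
        return np.array([r.z_score for r in self.results])


def default_isa_bands(field: EventField, n_bands: int = 10) -> tuple[float, float]:
    """(start, step) defaults: start is the smallest distance at which every
    event has a neighbour; step is half the start."""
    D = field.pairwise_distances()
    np.fill_diagonal(D, np.inf)
    start = float(D.min(axis=1).max())
    return start, start / 2.0


def isa_profile(
    field: EventField,
    start: float | None = None,
    step: float | None = None,
    n_bands: int = 10,
) -> ISAProfile:
    """Incremental spatial autocorrelation: Moran's I over growing bands.

    The peak is the smallest band whose Z-score is a local maximum of the
    Z-versus-distance profile and a running maximum (clustering "most
    pronounced" at the smallest scale); with no interior local maximum
    the global maximum is used and flagged.  Ties break to the smaller
    distance.
    """
    if start is None or step is None:
        d0, d_step = default_isa_bands(field, n_bands)
        start = start if start is not None else d0
        step = step if step is not None else d_step
    bands = start + step * np.arange(n_bands)
    results = [morans_i(field, b) for b in bands]
    usable = [r for r in results if r.usable]
    if not usable:
        raise ValueError("no usable distance band for ISA")
    z = np.array([r.z_score if r.usable else -np.inf for r in results])

    peak_idx = None
    running = -np.inf
    for k in range(len(z)):
        if z[k] < running:
            continue
        running = z[k]
        left_ok = k == 0 or z[k] >= z[k - 1]
        right_ok = k < len(z) - 1 and z[k] >= z[k + 1]
        if left_ok and right_ok:
            peak_idx = k
            break
    no_local = peak_idx is None
    if no_local:
        peak_idx = int(np.argmax(z))  # first occurrence = smallest distance
    return ISAProfile(
        distances=bands,
        results=results,
        peak_distance=float(bands[peak_idx]),
        peak_index=int(peak_idx),
        no_local_peak=no_local,
    )


# --------------------------------------------------------------------------
# Getis-Ord Gi*

class WeightKind(str, enum.Enum):
    ZONE_OF_INDIFFERENCE = "ZONE_OF_INDIFFERENCE"
    FIXED_BAND = "FIXED_BAND"
    INVERSE_DISTANCE = "INVERSE_DISTANCE"


@dataclass(frozen=True)
class WeightScheme:
    """Spatial-relationship kernel for Gi*.

    Zone of indifference: w(d) = 1 for d <= d0, d0/d beyond — full weight
    inside the threshold, smoothly decaying influence outside.  Fixed
    band: binary within d0.  Inverse distance: w(d) = d0/(d0+d), a
    smooth everywhere-positive decay.  The self-weight is included
    (w_ii = 1) for the Gi* (as opposed to Gi) statistic.
    """

    kind: WeightKind = WeightKind.ZONE_OF_INDIFFERENCE
    threshold_d0: float = 0.0
    includes_self: bool = True

    def __post_init__(self) -> None:
        if self.threshold_d0 <= 0:
            raise ValueError("weight scheme requires a positive threshold distance")

    def matrix(self, D: np.ndarray) -> np.ndarray:
        d0 = self.threshold_d0
        if self.kind is WeightKind.ZONE_OF_INDIFFERENCE:
            with np.errstate(divide="ignore"):
                W = np.where(D <= d0, 1.0, d0 / np.maximum(D, _EPS))
        elif self.kind is WeightKind.FIXED_BAND:
            W = (D <= d0).astype(float)
        else:
            W = d0 / (d0 + D)
        np.fill_diagonal(W, 1.0 if self.includes_self else 0.0)
        return W


class HotspotClass(str, enum.Enum):
    NS = "NS"
    P10 = "P10"  # hot, alpha < 0.10
    P05 = "P05"
    P01 = "P01"
    COLD10 = "COLD10"
    COLD05 = "COLD05"
    COLD01 = "COLD01"


def _classify(z: float) -> HotspotClass:
    if z > 2.576:
        return HotspotClass.P01
    if z > 1.96:
        return HotspotClass.P05
    if z > 1.645:
        return HotspotClass.P10
    if z < -2.576:
        return HotspotClass.COLD01
    if z < -1.96:
        return HotspotClass.COLD05
    if z < -1.645:
        return HotspotClass.COLD10
    return HotspotClass.NS


@dataclass(frozen=True)
class GiScore:
    event_index: int
    gi_star: float
    p_value: float
    hotspot_class: HotspotClass
    flagged: str = ""


def gi_star(field: EventField, scheme: WeightScheme) -> list[GiScore]:
    """Getis-Ord Gi* Z-score for every event under a weight scheme.

    A constant-weight field (S = 0) or a saturated neighbourhood (all
    weights equal for an event, making both the numerator and the
    variance bracket vanish) yields a defined score of 0, flagged rather
    than NaN, since "no local departure from the mean" is the honest
    reading of those degenerate cases.
    """
    if field.n < 2:
        raise ValueError("Gi* needs at least 2 events")
    n = field.n
    x = field.weights
    x_bar = field.x_bar
    S = field.s_field
    W = scheme.matrix(field.pairwise_distances())

    scores: list[GiScore] = []
    if S == 0.0:
        return [
            GiScore(i, 0.0, 1.0, HotspotClass.NS, "constant field (S = 0)") for i in range(n)
        ]
    for i in range(n):
        wi = W[i]
        w_sum = wi.sum()
        numerator = float(wi @ x - x_bar * w_sum)
        bracket = (n * float((wi**2).sum()) - w_sum**2) / (n - 1)
        if bracket <= _EPS * n:
            scores.append(GiScore(i, 0.0, 1.0, HotspotClass.NS, "saturated neighbourhood"))
            continue
        z = numerator / (S * np.sqrt(bracket))
        p = 2.0 * float(stats.norm.sf(abs(z)))
        scores.append(GiScore(i, float(z), p, _classify(z)))
    return scores


def gi_scores_frame(field: EventField, scores: Sequence[GiScore]) -> pd.DataFrame:
    df = field.to_frame()
    df["gi_z"] = [s.gi_star for s in scores]
    df["p"] = [s.p_value for s in scores]
    df["class"] = [s.hotspot_class.value for s in scores]
    df["flag"] = [s.flagged for s in scores]
    return df


# --------------------------------------------------------------------------
# IDW surfaces

@dataclass
class Surface:
    """Raster of interpolated Z-scores on a regular metre grid.

    ``values[0, 0]`` is the north-west cell (row 0 = top), matching the
    ESRI ASCII grid layout used for export.  ``origin`` is the outer
    corner of the lower-left cell.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray  # (nrows, ncols)
    mask: np.ndarray = field(default=None)  # True = masked (no data)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, same shape as values."""
        nrows, ncols = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(nrows) + 0.5) * self.cell_size
        X, Y = np.meshgrid(xs, ys[::-1])  # row 0 at top
        return X, Y

    def write_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        """Write as an ESRI ASCII grid (plain text raster)."""
        nrows, ncols = self.values.shape
        vals = np.where(self.mask, nodata, self.values)
        header = (
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {self.origin[0]:.3f}\nyllcorner {self.origin[1]:.3f}\n"
            f"cellsize {self.cell_size:.3f}\nNODATA_value {nodata}\n"
        )
        body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in vals)
        Path(path).write_text(header + body + "\n")


def idw_surface(
    points: np.ndarray,
    values: Sequence[float],
    cell_size: float,
    power: float = 2.0,
    bounds: tuple[float, float, float, float] | None = None,
) -> Surface:
    """Inverse-distance-weighted interpolation of scores onto a raster.

    value(cell) = sum_i z_i d_i^-p / sum_i d_i^-p over all scored events;
    the interpolator is exact, so a cell containing an event takes that
    event's score.  ``bounds`` is (xmin, ymin, xmax, ymax); it defaults
    to the events' bounding box padded by one cell.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    z = np.asarray(values, dtype=float)
    if pts.shape[0] == 0:
        raise ValueError("need at least one scored event")
    if bounds is None:
        xmin, ymin = pts.min(axis=0) - cell_size
        xmax, ymax = pts.max(axis=0) + cell_size
    else:
        xmin, ymin, xmax, ymax = bounds
    ncols = max(1, int(np.ceil((xmax - xmin) / cell_size)))
    nrows = max(1, int(np.ceil((ymax - ymin) / cell_size)))
    surf = Surface(origin=(xmin, ymin), cell_size=cell_size, values=np.zeros((nrows, ncols)))
    X, Y = surf.cell_centers()
    centers = np.column_stack([X.ravel(), Y.ravel()])
    D = cdist(centers, pts)
    with np.errstate(divide="ignore"):
        Wt = D ** (-power)
    exact = D < _EPS
    vals = np.empty(centers.shape[0])
    finite = ~exact.any(axis=1)
    vals[finite] = (Wt[finite] * z).sum(axis=1) / Wt[finite].sum(axis=1)
    for row in np.nonzero(~finite)[0]:
        vals[row] = z[np.argmin(D[row])]
    surf.values = vals.reshape(nrows, ncols)

    # a cell containing an event takes that event's exact score
    for (px, py), zi in zip(pts, z):
        col = int((px - xmin) // cell_size)
        row_from_bottom = int((py - ymin) // cell_size)
        r = nrows - 1 - row_from_bottom
        if 0 <= r < nrows and 0 <= col < ncols:
            surf.values[r, col] = zi
    return surf


def clip_to_buffer(surface: Surface, field_or_points, radius: float) -> Surface:
    """Mask all cells farther than ``radius`` from every event point."""
    if radius <= 0:
        raise ValueError("buffer radius must be positive")
    pts = field_or_points.points if isinstance(field_or_points, EventField) else np.atleast_2d(
        np.asarray(field_or_points, dtype=float)
    )
    X, Y = surface.cell_centers()
    centers = np.column_stack([X.ravel(), Y.ravel()])
    dmin = cdist(centers, pts).min(axis=1).reshape(surface.shape)
    new_mask = surface.mask | (dmin > radius)
    return Surface(surface.origin, surface.cell_size, surface.values.copy(), new_mask)


def significant_area(surface: Surface, z_threshold: float = 1.96) -> float:
    """Area (km²) of unmasked cells whose interpolated Z exceeds the threshold."""
    hot = (~surface.mask) & (surface.values > z_threshold)
    return float(hot.sum()) * surface.cell_size**2 / 1e6
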
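"""Rosette size/shape traits and mask-guided temperature from binary masks.

Conventions (pinned so every trait has a bit-exact definition):

* connected components use 8-connectivity, holes are filled before analysis;
* area is the foreground pixel count times ``scale**2``;
* perimeter uses the *crack* convention — the number of pixel edges exposed
  to background (4-neighbourhood), times ``scale``.  A filled ``n x n``
  square therefore has perimeter exactly ``4 n scale``;
* convex-hull area is the polygon area of the convex hull of the pixel
  *corner* points (each pixel a unit square), so a filled rectangle has
  compactness exactly 1;
* compactness = area / convex-hull area;
* roundness = 4*pi*area / perimeter**2, clipped to <= 1;
* eccentricity and isotropy come from the eigenvalues ``l1 >= l2`` of the
  central second-moment (inertia) tensor: eccentricity = sqrt(1 - l2/l1)
  (equivalent-ellipse convention), isotropy = l2/l1;
* RMS (rotational mass symmetry) is the mean Jaccard overlap between the
  mask and its rotations by ``360 j / k`` degrees (j = 1..k-1) about the
  binary centroid, nearest-neighbour resampling, default k = 8;
* SOL (slenderness of leaves) = (skeleton length)**2 / area in pixel units,
  with the skeleton from topological thinning and its length the weighted
  pixel count (sqrt(2) for pixels linked only diagonally).

These dialects are versioned here; the commercial platform the experiment
ran on uses its own (unpublished) formulas, so numerical agreement with it
is not claimed — only the standard monotone behaviour (heat stress lowers
compactness and SOL, transiently raises isotropy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.morphology import skeletonize

SHAPE_DIALECT_VERSION = "phenoheat-1"


class EmptyMaskError(ValueError):
    """Raster contains no foreground after cleaning."""


@dataclass(frozen=True)
class RosetteMask:
    """Cleaned binary top-view rosette mask.

    grid is a 2-D boolean raster (row-major, origin top-left); scale is the
    side length of one pixel in mm.
    """

    grid: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=bool))
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if not self.scale > 0:
            raise ValueError("scale must be positive (mm per pixel)")

    @property
    def pixel_count(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class ThermalRaster:
    """Per-pixel surface temperature in deg C, same shape as its mask."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.float64)
        if grid.ndim != 2:
            raise ValueError("thermal grid must be 2-D")
        if not np.all(np.isfinite(grid)):
            raise ValueError("thermal raster contains non-finite values")
        object.__setattr__(self, "grid", grid)


@dataclass(frozen=True)
class MorphoTraits:
    area: float  # mm^2
    perimeter: float  # mm
    compactness: float
    roundness: float
    eccentricity: float
    isotropy: float
    rms: float
    sol: float

    def as_dict(self) -> dict[str, float]:
        return {
            "area": self.area,
            "perimeter": self.perimeter,
            "compactness": self.compactness,
            "roundness": self.roundness,
            "eccentricity": self.eccentricity,
            "isotropy": self.isotropy,
            "RMS": self.rms,
            "SOL": self.sol,
        }


def clean_mask(raw: np.ndarray, scale: float = 1.0) -> RosetteMask:
    """Fill holes and keep the largest 8-connected component.

    Raises :class:`EmptyMaskError` if no foreground remains.
    """
    grid = np.asarray(raw) != 0
    if grid.ndim != 2:
        raise ValueError("mask raster must be 2-D")
    if not grid.any():
        raise EmptyMaskError("mask has no foreground pixels")
    labels, n = ndimage.label(grid, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(grid, labels, index=np.arange(1, n + 1))
        grid = labels == (int(np.argmax(sizes)) + 1)
    grid = ndimage.binary_fill_holes(grid)
    return RosetteMask(grid=grid, scale=scale)


def crack_perimeter_px(grid: np.ndarray) -> int:
    """Number of foreground pixel edges exposed to background (crack length)."""
    g = np.asarray(grid, dtype=bool)
    padded = np.pad(g, 1)
    exposed = 0
    for shift_axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neigh = np.roll(padded, shift, axis=shift_axis)
        exposed += int(np.count_nonzero(padded & ~neigh))
    return exposed


def convex_hull_area_px(grid: np.ndarray) -> float:
    """Polygon area of the convex hull of the foreground pixel corner points.

    Each pixel is treated as a unit square with corners at +-0.5 around its
    center, so the hull always contains the foreground and a filled
    rectangle has hull area equal to its pixel count.
    """
    ys, xs = np.nonzero(np.asarray(grid, dtype=bool))
    if ys.size == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    corners = np.empty((4 * ys.size, 2), dtype=np.float64)
    for i, (dy, dx) in enumerate(((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))):
        corners[i * ys.size : (i + 1) * ys.size, 0] = ys + dy
        corners[i * ys.size : (i + 1) * ys.size, 1] = xs + dx
    return float(ConvexHull(corners).volume)  # "volume" is area in 2-D


def basic_geometry(mask: RosetteMask) -> tuple[float, float, float, float, float]:
    """Return ``(area, perimeter, convex_hull_area, compactness, roundness)``.

    Area/hull area in mm^2, perimeter in mm; compactness and roundness are
    dimensionless.
    """
    npx = mask.pixel_count
    if npx == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    area = npx * mask.scale**2
    perim = crack_perimeter_px(mask.grid) * mask.scale
    hull_area = convex_hull_area_px(mask.grid) * mask.scale**2
    compactness = min(1.0, area / hull_area)  # guard hull-area float error
    roundness = min(1.0, 4.0 * math.pi * area / perim**2)
    return area, perim, hull_area, compactness, roundness


def centroid(grid: np.ndarray) -> tuple[float, float]:
    """Binary centroid (row, col) of the foreground."""
    ys, xs = np.nonzero(grid)
    return float(ys.mean()), float(xs.mean())


def moment_shape(mask: RosetteMask) -> tuple[float, float]:
    """Return ``(eccentricity, isotropy)`` from central second moments.

    Degenerate (collinear) masks have a zero minor eigenvalue; they map to
    the limit eccentricity -> 1, isotropy -> 0.
    """
    ys, xs = np.nonzero(mask.grid)
    if ys.size < 3:
        raise ValueError("moment shape needs at least 3 foreground pixels")
    cy, cx = ys.mean(), xs.mean()
    dy, dx = ys - cy, xs - cx
    mu20 = float(np.mean(dx * dx))
    mu02 = float(np.mean(dy * dy))
    mu11 = float(np.mean(dx * dy))
    eigvals = np.linalg.eigvalsh(np.array([[mu20, mu11], [mu11, mu02]]))
    l2, l1 = float(eigvals[0]), float(eigvals[1])
    l2 = max(l2, 0.0)
    if l1 <= 0:
        return 1.0, 0.0
    ratio = l2 / l1
    return math.sqrt(max(0.0, 1.0 - ratio)), ratio


def rotate_mask_nn(grid: np.ndarray, angle_deg: float, center: tuple[float, float]) -> np.ndarray:
    """Rotate a binary grid about ``center`` by nearest-neighbour resampling.

    Pixels whose rotated source falls outside the grid become background.
    """
    g = np.asarray(grid, dtype=bool)
    h, w = g.shape
    yy, xx = np.indices((h, w))
    theta = math.radians(angle_deg)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    dy = yy - center[0]
    dx = xx - center[1]
    # inverse map: target pixel -> source coordinate
    sy = center[0] + cos_t * dy + sin_t * dx
    sx = center[1] - sin_t * dy + cos_t * dx
    iy = np.rint(sy).astype(np.int64)
    ix = np.rint(sx).astype(np.int64)
    valid = (iy >= 0) & (iy < h) & (ix >= 0) & (ix < w)
    out = np.zeros_like(g)
    out[valid] = g[iy[valid], ix[valid]]
    return out


def rotational_mass_symmetry(mask: RosetteMask, k: int = 8) -> float:
    """Mean Jaccard overlap of the mask with its k-1 centroid rotations."""
    if k < 2:
        raise ValueError("k must be >= 2")
    grid = mask.grid
    if not grid.any():
        raise EmptyMaskError("mask has no foreground pixels")
    # pad so no rotation can push foreground off the raster
    ys, xs = np.nonzero(grid)
    cy, cx = float(ys.mean()), float(xs.mean())
    reach = int(np.ceil(np.sqrt((ys - cy) ** 2 + (xs - cx) ** 2).max())) + 2
    h, w = grid.shape
    pad_top = max(0, reach - int(cy))
    pad_bottom = max(0, reach - int(h - 1 - cy))
    pad_left = max(0, reach - int(cx))
    pad_right = max(0, reach - int(w - 1 - cx))
    g = np.pad(grid, ((pad_top, pad_bottom), (pad_left, pad_right)))
    center = (cy + pad_top, cx + pad_left)
    overlaps = []
    for j in range(1, k):
        rot = rotate_mask_nn(g, 360.0 * j / k, center)
        inter = np.count_nonzero(g & rot)
        union = np.count_nonzero(g | rot)
        overlaps.append(inter / union)
    return float(np.mean(overlaps))


def skeleton_length_px(skeleton: np.ndarray) -> float:
    """Weighted pixel count of a skeleton.

    A skeleton pixel counts 1 if it touches another skeleton pixel through
    an edge (or is isolated), sqrt(2) if its only skeleton neighbours are
    diagonal.
    """
    sk = np.asarray(skeleton, dtype=bool)
    if not sk.any():
        return 0.0
    padded = np.pad(sk, 1)
    has_orth = np.zeros_like(padded)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        has_orth |= np.roll(padded, shift, axis=axis)
    has_diag = np.zeros_like(padded)
    for sy in (1, -1):
        for sx in (1, -1):
            has_diag |= np.roll(np.roll(padded, sy, axis=0), sx, axis=1)
    diag_only = padded & has_diag & ~has_orth
    n_diag_only = int(np.count_nonzero(diag_only))
    n_total = int(np.count_nonzero(padded))
    return (n_total - n_diag_only) + math.sqrt(2.0) * n_diag_only


def slenderness_of_leaves(mask: RosetteMask) -> float:
    """SOL = (skeleton length)^2 / foreground area, in pixel units.

    Dimensionless, so independent of ``scale``.  A single-pixel mask has
    SOL = 1 by convention (its skeleton is the pixel itself).
    """
    npx = mask.pixel_count
    if npx == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    if npx == 1:
        return 1.0
    sk = skeletonize(mask.grid)
    length = skeleton_length_px(sk)
    return length**2 / npx


def rosette_temperature(mask: RosetteMask, thermal: ThermalRaster) -> float:
    """Mean temperature (deg C) over the foreground pixels of the mask."""
    if mask.grid.shape != thermal.grid.shape:
        raise ValueError(
            f"mask shape {mask.grid.shape} != thermal shape {thermal.grid.shape}"
        )
    if not mask.grid.any():
        raise EmptyMaskError("mask has no foreground pixels")
    return float(thermal.grid[mask.grid].mean())


def extract_morpho_traits(mask: RosetteMask, rms_k: int = 8) -> MorphoTraits:
    """Compute the full morphology trait set for one cleaned mask."""
    area, perim, _, compactness, roundness = basic_geometry(mask)
    ecc, iso = moment_shape(mask)
    rms = rotational_mass_symmetry(mask, k=rms_k)
    sol = slenderness_of_leaves(mask)
    return MorphoTraits(
        area=area,
        perimeter=perim,
        compactness=compactness,
        roundness=roundness,
        eccentricity=ecc,
        isotropy=iso,
        rms=rms,
        sol=sol,
    )
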
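"""Per-islet shape and composition measurements.

Implements the morphometric battery used for islet phenotyping: planar
cross-sectional area, Feret (longest caliper) diameter, circularity
``4*pi*a / p**2``, per-hormone areas, nucleus-based beta-cell counts,
mean beta-cell size and marker-positive beta-cell fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure as skmeasure
from skimage.measure import approximate_polygon, find_contours, label, perimeter_crofton

__all__ = [
    "IsletRecord",
    "measure_area",
    "perimeter_length",
    "feret_diameter",
    "circularity",
    "hormone_area",
    "count_beta_cells",
    "beta_cell_size",
    "marker_positive_fraction",
]


@dataclass
class IsletRecord:
    """Morphometry of a single retained islet.

    Areas are in um^2, lengths in um; ``beta_cell_size`` is um^2 per cell and
    is ``nan`` when the islet holds no counted beta cell.
    """

    islet_id: int
    mouse_id: str
    section_index: int
    area_um2: float
    perimeter_um: float
    feret_um: float
    circularity: float
    beta_area_um2: float
    alpha_area_um2: float
    delta_area_um2: float
    beta_count: int
    beta_cell_size_um2: float
    marker_pos_beta: int
    marker_neg_beta: int


def _as_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool:
        mask = mask > 0
    return mask


def measure_area(mask: np.ndarray, pixel_size: float) -> float:
    """Cross-sectional area: pixel count times (um/px)^2."""
    mask = _as_mask(mask)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    return n * pixel_size**2


def perimeter_length(
    mask: np.ndarray,
    pixel_size: float,
    method: str = "contour",
    contour_tolerance_px: float = 1.0,
) -> float:
    """Boundary length of a binary region.

    ``method="contour"`` traces the subpixel 0.5-level marching-squares
    contour and simplifies it with Douglas-Peucker (tolerance in px) before
    summing segment lengths; this removes the staircase bias that makes
    naive pixel-edge counting overestimate smooth boundaries.
    ``method="crofton"`` uses the 4-direction Crofton estimator.
    """
    mask = _as_mask(mask)
    if not mask.any():
        raise ValueError("empty mask")
    if method == "crofton":
        return float(perimeter_crofton(mask, directions=4)) * pixel_size
    if method != "contour":
        raise ValueError(f"unknown perimeter method {method!r}")
    padded = np.pad(mask, 1).astype(float)
    total = 0.0
    for contour in find_contours(padded, 0.5):
        if contour_tolerance_px > 0:
            contour = approximate_polygon(contour, tolerance=contour_tolerance_px)
        diffs = np.diff(contour, axis=0)
        total += float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())
    return total * pixel_size


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Centres of the region's boundary pixels (pixels with a background 4-neighbour)."""
    padded = np.pad(mask, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = mask & ~interior
    return np.argwhere(boundary).astype(float)


def feret_diameter(mask: np.ndarray, pixel_size: float) -> float:
    """Longest caliper distance across the region, in um.

    Computed as the diameter of the convex hull of boundary-pixel centres
    (identical to the maximum pairwise boundary distance, since the farthest
    pair of any point set lies on its convex hull).
    """
    mask = _as_mask(mask)
    pts = _boundary_points(mask)
    if len(pts) == 0:
        raise ValueError("empty mask")
    if len(pts) == 1:
        return 0.0
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (collinear) point sets
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max()) * pixel_size


def circularity(
    mask: np.ndarray,
    pixel_size: float = 1.0,
    method: str = "contour",
    contour_tolerance_px: float = 1.0,
) -> float:
    """Shape circularity ``4*pi*a / p**2`` (1 for a circle, lower when elongated).

    Scale-invariant; values slightly above 1 can occur from discretization
    and are not clamped.  Requires a single connected region.
    """
    mask = _as_mask(mask)
    if not mask.any():
        raise ValueError("empty mask")
    if label(mask, connectivity=2).max() > 1:
        raise ValueError("mask must be a single connected region")
    a = measure_area(mask, pixel_size)
    p = perimeter_length(mask, pixel_size, method, contour_tolerance_px)
    return 4.0 * math.pi * a / p**2


def hormone_area(
    islet_mask: np.ndarray, channel_mask: np.ndarray, pixel_size: float
) -> float:
    """Area of hormone-positive signal inside an islet (um^2); 0 when disjoint."""
    inter = _as_mask(islet_mask) & _as_mask(channel_mask)
    return int(inter.sum()) * pixel_size**2


def _beta_nucleus_labels(
    islet_mask: np.ndarray,
    insulin_mask: np.ndarray,
    nuclei_labels: np.ndarray,
    overlap_fraction: float = 0.5,
) -> np.ndarray:
    """Labels of nuclei belonging to beta cells of this islet.

    A nucleus is a beta-cell nucleus when its centroid lies in the islet and
    at least ``overlap_fraction`` of its pixels carry insulin signal.  The
    overlap rule (rather than centroid-in-insulin) tolerates the
    cytoplasmic, perinuclear localisation of insulin staining.
    """
    islet_mask = _as_mask(islet_mask)
    insulin_mask = _as_mask(insulin_mask)
    props = skmeasure.regionprops(nuclei_labels)
    out = []
    for p in props:
        r, c = int(round(p.centroid[0])), int(round(p.centroid[1]))
        if not (0 <= r < islet_mask.shape[0] and 0 <= c < islet_mask.shape[1]):
            continue
        if not islet_mask[r, c]:
            continue
        rr, cc = p.coords[:, 0], p.coords[:, 1]
        frac = insulin_mask[rr, cc].mean()
        if frac >= overlap_fraction:
            out.append(p.label)
    return np.asarray(out, dtype=int)


def count_beta_cells(
    islet_mask: np.ndarray,
    insulin_mask: np.ndarray,
    nuclei_labels: np.ndarray,
    overlap_fraction: float = 0.5,
) -> int:
    """Number of insulin-positive, DAPI-stained cells within the islet."""
    return len(
        _beta_nucleus_labels(islet_mask, insulin_mask, nuclei_labels, overlap_fraction)
    )


def beta_cell_size(beta_area_um2: float, beta_count: int) -> float:
    """Mean beta-cell size: beta area divided by beta count (um^2/cell).

    Undefined (raises) for islets without counted beta cells; such islets
    are omitted from beta-size averages upstream.
    """
    if beta_count < 1:
        raise ValueError("beta_cell_size undefined for beta_count < 1")
    return beta_area_um2 / beta_count


def marker_positive_fraction(
    islet_masks: list[np.ndarray],
    marker2_mask: np.ndarray,
    insulin_mask: np.ndarray,
    nuclei_labels: np.ndarray,
    overlap_fraction: float = 0.5,
    insulin_overlap_fraction: float = 0.5,
) -> float:
    """Percent of beta cells positive for the second marker, pooled over islets.

    A beta cell is marker-positive when at least ``overlap_fraction`` of its
    nucleus overlaps the marker mask (serves nuclear or cellular markers of
    apoptosis/proliferation).  Returns ``nan`` when no beta cell is found.
    """
    marker2_mask = _as_mask(marker2_mask)
    pos = tot = 0
    props = {p.label: p for p in skmeasure.regionprops(nuclei_labels)}
    for islet_mask in islet_masks:
        for lab in _beta_nucleus_labels(
            islet_mask, insulin_mask, nuclei_labels, insulin_overlap_fraction
        ):
            p = props[lab]
            rr, cc = p.coords[:, 0], p.coords[:, 1]
            tot += 1
            if marker2_mask[rr, cc].mean() >= overlap_fraction:
                pos += 1
    if tot == 0:
        return float("nan")
    return 100.0 * pos / tot
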
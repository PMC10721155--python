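"""Synthetic pancreas-section generator with exact ground truth.

Emulates the immunofluorescence histology the analysis assumes: islets as
clusters of nucleated cells with centrally located insulin-positive beta
cells and a peripheral mantle of glucagon-positive alpha cells, lognormal
islet-size variation, group-level multiplicative effects on mean islet area
and beta-cell number, and the confounders real sections contain (hormone
signal without nuclei, non-beta-only regions, sub-threshold specks, blurred
islets, near-contiguous micro-clusters).

Every rendered object is recorded in a ground-truth structure whose areas
are computed from the rendered masks themselves (pixel count times the
squared pixel size), so downstream stages can be validated without any real
slide.  Identical seeds and designs give bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

from . import morphometry
from .imaging_io import DEFAULT_CHANNEL_MAP, SectionImage, write_section_image

__all__ = [
    "SyntheticIsletSpec",
    "ConfounderSpec",
    "IsletTruth",
    "ConfounderTruth",
    "SectionGroundTruth",
    "GroupEffect",
    "CohortDesign",
    "PackingError",
    "PlacementError",
    "render_islet",
    "render_section",
    "generate_cohort",
    "sample_cohort_truth",
    "sample_mouse_mean_areas",
    "islet_cell_capacity",
    "CELL_FOOTPRINT_UM2",
]

CONFOUNDER_KINDS = (
    "hormone_no_dapi",
    "nonbeta_only",
    "subthreshold_speck",
    "blurred_islet",
    "near_contiguous_microclusters",
)

# cell geometry (um): typical rodent islet-cell scale
NUCLEUS_RADIUS = 3.0
CYTO_OUTER_RADIUS = 6.0
# in 8-um sections the cytoplasmic hormone signal projects over most of the
# nucleus; only a small perinuclear core stays hormone-free
CYTO_INNER_RADIUS = 1.0
CELL_SPACING = 8.0  # hexagonal lattice pitch
CELL_FOOTPRINT_UM2 = CELL_SPACING**2 * math.sqrt(3) / 2  # ~55.4 um^2 per cell
# the ground-truth islet outline smooths the scalloped disc union with the
# same closing radius the segmentation stage uses, so truth and measurement
# share one definition of the tissue boundary
OUTLINE_SMOOTH_UM = 5.0

HORMONE_INTENSITY = 200
DAPI_INTENSITY = 230
BACKGROUND = 10.0


class PackingError(ValueError):
    """Requested cell count does not fit the target area at the cell geometry."""


class PlacementError(RuntimeError):
    """Object placement on the section canvas failed after max retries."""


@dataclass
class SyntheticIsletSpec:
    """Blueprint of one synthetic islet.

    ``architecture="core_mantle"`` puts every alpha (and delta) cell on the
    outer ring and all beta cells interior; ``"mixed"`` shuffles cell types.
    """

    center_um: tuple[float, float]  # (x, y)
    target_area_um2: float
    n_beta_cells: int
    n_alpha_cells: int = 0
    n_delta_cells: int = 0
    eccentricity: float = 0.0
    marker_positive_beta_fraction: float = 0.0
    architecture: str = "core_mantle"

    def __post_init__(self) -> None:
        if self.target_area_um2 <= 0:
            raise ValueError("target_area_um2 must be positive")
        if min(self.n_beta_cells, self.n_alpha_cells, self.n_delta_cells) < 0:
            raise ValueError("cell counts must be non-negative")
        if not (0 <= self.eccentricity < 1):
            raise ValueError("eccentricity must be in [0, 1)")
        if not (0 <= self.marker_positive_beta_fraction <= 1):
            raise ValueError("marker_positive_beta_fraction must be in [0, 1]")
        if self.architecture not in ("core_mantle", "mixed"):
            raise ValueError(f"unknown architecture {self.architecture!r}")

    @property
    def n_cells(self) -> int:
        return self.n_beta_cells + self.n_alpha_cells + self.n_delta_cells


@dataclass
class ConfounderSpec:
    """Blueprint of one planted exclusion confounder."""

    kind: str
    center_um: tuple[float, float] = (0.0, 0.0)
    area_um2: float = 40.0  # subthreshold_speck / hormone_no_dapi blob area
    n_cells: int = 5  # nonbeta_only / blurred_islet cell count
    blur_sigma_px: float = 3.0  # blurred_islet
    n_clusters: int = 2  # near_contiguous_microclusters
    cells_per_cluster: int = 2
    gap_um: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in CONFOUNDER_KINDS:
            raise ValueError(f"unknown confounder kind {self.kind!r}")
        if self.kind == "subthreshold_speck" and self.area_um2 > 50.0:
            raise ValueError("subthreshold_speck area must be <= inclusion floor")
        if self.kind == "near_contiguous_microclusters":
            if self.n_clusters < 2:
                raise ValueError("need >= 2 micro-clusters")


@dataclass
class IsletTruth:
    """Ground truth of one rendered islet, measured on its rendered masks."""

    islet_id: int
    centroid_um: tuple[float, float]  # (x, y)
    area_um2: float
    feret_um: float
    circularity: float
    beta_area_um2: float
    alpha_area_um2: float
    delta_area_um2: float
    beta_count: int
    marker_pos_beta: int


@dataclass
class ConfounderTruth:
    confounder_id: int
    kind: str
    centroid_um: tuple[float, float]
    area_um2: float


@dataclass
class SectionGroundTruth:
    """Exact truth for one synthetic section.

    ``islet_labels`` and ``confounder_labels`` are disjoint label images in
    pixel space; scalar truth fields equal mask pixel counts times
    (um/px)^2 by construction.
    """

    islets: list[IsletTruth]
    confounders: list[ConfounderTruth]
    islet_labels: np.ndarray
    confounder_labels: np.ndarray
    pixel_size: float
    section_area_um2: float

    def to_json(self, path: str | Path) -> None:
        """Write the scalar truth (no label images) as JSON."""
        payload = {
            "pixel_size_um": self.pixel_size,
            "section_area_um2": self.section_area_um2,
            "islets": [vars(t) for t in self.islets],
            "confounders": [vars(t) for t in self.confounders],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def scalars_from_json(path: str | Path) -> dict:
        return json.loads(Path(path).read_text())


@dataclass
class GroupEffect:
    """Multiplicative group-level effects on islet morphology."""

    area_multiplier: float = 1.0
    beta_count_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if min(self.area_multiplier, self.beta_count_multiplier) <= 0:
            raise ValueError("multipliers must be positive")


@dataclass
class CohortDesign:
    """Design of a synthetic mouse cohort.

    Per-islet areas are drawn from ``lognormal(log_area_mu, log_area_sigma)``
    (um^2) scaled by the group's area multiplier; islets per section are
    Poisson with mean ``islets_per_section``.  Four head-to-tail sections per
    mouse is the sampling scheme the morphometry assumes.
    """

    groups: list[tuple[str, int]] = field(
        default_factory=lambda: [("control", 5), ("treated", 5)]
    )
    sections_per_mouse: int = 4
    islets_per_section: float = 30.0
    log_area_mu: float = math.log(1800.0)  # median islet area 1800 um^2
    log_area_sigma: float = 0.5
    group_effects: dict[str, GroupEffect] = field(default_factory=dict)
    alpha_cell_fraction: float = 0.2
    # 0 emulates the plain hormone-stain slide series; apoptosis/proliferation
    # marker planting is an explicit experimental condition
    marker_positive_beta_fraction: float = 0.0
    eccentricity_max: float = 0.6
    canvas_um: tuple[float, float] = (1600.0, 1600.0)
    pixel_size: float = 1.0
    noise_sigma: float = 4.0
    pancreas_spleen_weight_g: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for _, n in self.groups):
            raise ValueError("each group needs >= 1 mouse")
        for g, _ in self.groups:
            self.group_effects.setdefault(g, GroupEffect())

    def effect(self, group: str) -> GroupEffect:
        return self.group_effects.get(group, GroupEffect())


# ---------------------------------------------------------------------------
# cell layout


def _cell_layout(target_area_um2: float, eccentricity: float) -> np.ndarray:
    """Unjittered cell-centre layout for an islet of the requested size.

    A hexagonal interior lattice plus a boundary ring of cells spaced at
    equal arc length along the islet ellipse.  The boundary-ring disc union
    is the Minkowski offset of that ellipse by the cytoplasm radius, so (by
    the Steiner formula) the rendered footprint area tracks
    ``target_area_um2`` closely across sizes and eccentricities.  Returns
    (N, 2) offsets in um, interior points first (sorted inside-out), ring
    points last; N is the islet's deterministic cell capacity.
    """
    ratio = math.sqrt(1.0 - eccentricity**2)
    r_t = math.sqrt(target_area_um2 / math.pi)
    a_t = r_t / math.sqrt(ratio)  # semi-major of the target outline
    b_t = r_t * math.sqrt(ratio)
    a_r = a_t - CYTO_OUTER_RADIUS  # ring ellipse (cell centres)
    b_r = b_t - CYTO_OUTER_RADIUS
    if min(a_r, b_r) < 1.5:
        return np.zeros((1, 2))
    # ring: equal arc-length spacing via dense sampling of the ellipse
    theta = np.linspace(0.0, 2.0 * math.pi, 4096, endpoint=False)
    xy = np.column_stack([a_r * np.cos(theta), b_r * np.sin(theta)])
    seg = np.hypot(*np.diff(np.vstack([xy, xy[:1]]), axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n_ring = max(3, int(total // CELL_SPACING))
    targets = np.arange(n_ring) * total / n_ring
    ring = xy[np.searchsorted(arc, targets, side="left").clip(max=len(xy) - 1)]
    # interior: hex lattice inset from the ring so neighbouring nuclei
    # stay separated even after jitter
    inset = CELL_SPACING * 0.95
    a_i, b_i = a_r - inset, b_r - inset
    interior = []
    if min(a_i, b_i) > 0.5:
        dx = CELL_SPACING
        dy = CELL_SPACING * math.sqrt(3) / 2
        j = 0
        y = -(math.ceil(b_i / dy) + 1) * dy
        while y <= b_i + dy:
            off = 0.5 * dx if (j % 2) else 0.0
            x = -(math.ceil(a_i / dx) + 1) * dx + off
            while x <= a_i + dx:
                if (x / a_i) ** 2 + (y / b_i) ** 2 <= 1.0:
                    interior.append((x, y))
                x += dx
            y += dy
            j += 1
    if interior:
        interior = np.asarray(interior, dtype=float)
        r_ell = (interior[:, 0] / a_i) ** 2 + (interior[:, 1] / b_i) ** 2
        interior = interior[np.argsort(r_ell, kind="stable")]
        return np.vstack([interior, ring])
    return ring


def islet_cell_capacity(target_area_um2: float, eccentricity: float = 0.0) -> int:
    """Number of cells the renderer can pack into an islet of this size."""
    return len(_cell_layout(target_area_um2, eccentricity))


def _draw_disc(img: np.ndarray, cy: float, cx: float, radius_px: float, value: int) -> None:
    rr, cc = draw_disk((cy, cx), radius_px, shape=img.shape)
    img[rr, cc] = value


def _disc_mask(mask: np.ndarray, cy: float, cx: float, radius_px: float) -> None:
    rr, cc = draw_disk((cy, cx), radius_px, shape=mask.shape)
    mask[rr, cc] = True


def _disk_structure(radius_px: int) -> np.ndarray:
    y, x = np.ogrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    return x**2 + y**2 <= radius_px**2


# ---------------------------------------------------------------------------
# rendering


def render_islet(
    spec: SyntheticIsletSpec,
    pixel_size: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, np.ndarray], IsletTruth]:
    """Render one islet on its own tile.

    Cells sit on a jittered hexagonal lattice inside an ellipse sized from
    ``target_area_um2``.  Each cell is a DAPI nucleus disc plus a hormone
    cytoplasm annulus (insulin for beta, second marker for alpha/delta);
    marker-positive beta cells additionally carry second-marker signal over
    the nucleus.  Returns (tile H x W x 3 uint8, masks dict, truth record);
    all truth fields are measured on the rendered masks.

    Raises :class:`PackingError` when the cell count exceeds the lattice
    capacity of the target area.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    lattice = _cell_layout(spec.target_area_um2, spec.eccentricity)
    if spec.n_cells > len(lattice):
        raise PackingError(
            f"{spec.n_cells} cells exceed capacity {len(lattice)} of "
            f"target area {spec.target_area_um2:.0f} um^2"
        )
    pts = lattice[: spec.n_cells].copy()
    # jitter small enough that nuclei (radius 3, pitch 8) never touch
    pts += rng.uniform(-0.5, 0.5, size=pts.shape)

    # assign types: inside-out order => innermost are beta under core_mantle
    n_b, n_a, n_d = spec.n_beta_cells, spec.n_alpha_cells, spec.n_delta_cells
    order = np.arange(spec.n_cells)
    if spec.architecture == "mixed":
        order = rng.permutation(spec.n_cells)
    beta_idx = order[:n_b]
    delta_idx = order[n_b : n_b + n_d]
    alpha_idx = order[n_b + n_d :]

    # tile geometry
    extent = (np.abs(pts).max(initial=0.0) + CYTO_OUTER_RADIUS + 4.0) if len(pts) else 10.0
    half_px = int(math.ceil(extent / pixel_size)) + 2
    size = 2 * half_px + 1
    tile = np.zeros((size, size, 3), dtype=np.uint8)
    cell_mask = np.zeros((size, size), dtype=bool)
    beta_mask = np.zeros_like(cell_mask)
    alpha_mask = np.zeros_like(cell_mask)
    delta_mask = np.zeros_like(cell_mask)

    ch = DEFAULT_CHANNEL_MAP
    r_nuc = NUCLEUS_RADIUS / pixel_size
    r_out = CYTO_OUTER_RADIUS / pixel_size
    r_in = CYTO_INNER_RADIUS / pixel_size

    n_marker_pos = int(rng.binomial(n_b, spec.marker_positive_beta_fraction)) if n_b else 0
    marker_pos = set(rng.choice(n_b, size=n_marker_pos, replace=False)) if n_marker_pos else set()

    beta_set, delta_set = set(beta_idx.tolist()), set(delta_idx.tolist())
    annulus = np.zeros_like(cell_mask)
    for k, (x, y) in enumerate(pts):
        cy = half_px + y / pixel_size
        cx = half_px + x / pixel_size
        hormone = ch["insulin"] if k in beta_set else ch["marker2"]
        annulus[:] = False
        _disc_mask(annulus, cy, cx, r_out)
        inner = np.zeros_like(annulus)
        _disc_mask(inner, cy, cx, r_in)
        tile[:, :, hormone][annulus & ~inner] = HORMONE_INTENSITY
        _draw_disc(tile[:, :, ch["dapi"]], cy, cx, r_nuc, DAPI_INTENSITY)
        _disc_mask(cell_mask, cy, cx, r_out)
        # truth masks use the full cell footprint: the perinuclear
        # hormone-free core is below any mask-cleanup hole size
        if k in beta_set:
            beta_mask |= annulus
            if k in marker_pos:
                _draw_disc(tile[:, :, ch["marker2"]], cy, cx, r_nuc, HORMONE_INTENSITY)
        elif k in delta_set:
            delta_mask |= annulus
        else:
            alpha_mask |= annulus

    # smooth the scalloped disc-union outline into a tissue-like boundary
    smooth_px = max(1, int(round(OUTLINE_SMOOTH_UM / pixel_size)))
    islet_mask = ndi.binary_closing(
        np.pad(cell_mask, smooth_px + 1),
        structure=_disk_structure(smooth_px),
    )[smooth_px + 1 : -(smooth_px + 1), smooth_px + 1 : -(smooth_px + 1)]
    islet_mask = ndi.binary_fill_holes(islet_mask)
    beta_mask = ndi.binary_fill_holes(beta_mask) & islet_mask
    alpha_mask = ndi.binary_fill_holes(alpha_mask) & islet_mask
    delta_mask = ndi.binary_fill_holes(delta_mask) & islet_mask
    px2 = pixel_size**2
    cy_c, cx_c = ndi.center_of_mass(islet_mask)
    truth = IsletTruth(
        islet_id=0,
        centroid_um=(
            (cx_c - half_px) * pixel_size + spec.center_um[0],
            (cy_c - half_px) * pixel_size + spec.center_um[1],
        ),
        area_um2=float(islet_mask.sum()) * px2,
        feret_um=morphometry.feret_diameter(islet_mask, pixel_size),
        circularity=morphometry.circularity(islet_mask, pixel_size),
        beta_area_um2=float((beta_mask & islet_mask).sum()) * px2,
        alpha_area_um2=float((alpha_mask & islet_mask).sum()) * px2,
        delta_area_um2=float((delta_mask & islet_mask).sum()) * px2,
        beta_count=int(n_b),
        marker_pos_beta=len(marker_pos),
    )
    masks = {
        "islet": islet_mask,
        "beta": beta_mask,
        "alpha": alpha_mask,
        "delta": delta_mask,
    }
    return tile, masks, truth


def _render_confounder(
    spec: ConfounderSpec, pixel_size: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Render one confounder tile; returns (tile, object mask)."""
    ch = DEFAULT_CHANNEL_MAP
    if spec.kind == "hormone_no_dapi":
        r = math.sqrt(spec.area_um2 / math.pi) / pixel_size
        half = int(math.ceil(r)) + 4
        size = 2 * half + 1
        tile = np.zeros((size, size, 3), dtype=np.uint8)
        mask = np.zeros((size, size), dtype=bool)
        _draw_disc(tile[:, :, ch["insulin"]], half, half, r, HORMONE_INTENSITY)
        _disc_mask(mask, half, half, r)
        return tile, mask

    if spec.kind == "subthreshold_speck":
        r_cell = math.sqrt(spec.area_um2 / math.pi) / pixel_size
        r_nuc = min(2.2 / pixel_size, 0.65 * r_cell)
        half = int(math.ceil(r_cell)) + 4
        size = 2 * half + 1
        tile = np.zeros((size, size, 3), dtype=np.uint8)
        mask = np.zeros((size, size), dtype=bool)
        _draw_disc(tile[:, :, ch["insulin"]], half, half, r_cell, HORMONE_INTENSITY)
        _draw_disc(tile[:, :, ch["dapi"]], half, half, r_nuc, DAPI_INTENSITY)
        _disc_mask(mask, half, half, r_cell)
        return tile, mask

    if spec.kind == "nonbeta_only":
        islet = SyntheticIsletSpec(
            center_um=(0, 0),
            target_area_um2=max(300.0, spec.n_cells * CELL_FOOTPRINT_UM2 * 2.0),
            n_beta_cells=0,
            n_alpha_cells=spec.n_cells,
        )
        tile, masks, _ = render_islet(islet, pixel_size, rng)
        return tile, masks["islet"]

    if spec.kind == "blurred_islet":
        islet = SyntheticIsletSpec(
            center_um=(0, 0),
            target_area_um2=max(500.0, spec.n_cells * CELL_FOOTPRINT_UM2 * 2.0),
            n_beta_cells=spec.n_cells,
        )
        tile, masks, _ = render_islet(islet, pixel_size, rng)
        blurred = np.empty_like(tile)
        for c in range(3):
            blurred[:, :, c] = np.clip(
                np.rint(
                    ndi.gaussian_filter(
                        tile[:, :, c].astype(float), spec.blur_sigma_px
                    )
                ),
                0,
                255,
            ).astype(np.uint8)
        return blurred, masks["islet"]

    if spec.kind == "near_contiguous_microclusters":
        n = spec.n_clusters
        m = spec.cells_per_cluster
        # clusters along a line, boundary gap = gap_um between cluster discs
        cluster_r = CYTO_OUTER_RADIUS + (m - 1) * CELL_SPACING / 2.0
        pitch = 2 * cluster_r + spec.gap_um
        width = (n - 1) * pitch + 2 * cluster_r + 8.0
        half = int(math.ceil(width / 2.0 / pixel_size)) + 4
        size = 2 * half + 1
        tile = np.zeros((size, size, 3), dtype=np.uint8)
        mask = np.zeros((size, size), dtype=bool)
        ch_ins = ch["insulin"]
        r_nuc = NUCLEUS_RADIUS / pixel_size
        r_out = CYTO_OUTER_RADIUS / pixel_size
        x0 = -(n - 1) * pitch / 2.0
        for i in range(n):
            for k in range(m):
                x = x0 + i * pitch + (k - (m - 1) / 2.0) * CELL_SPACING
                cy, cx = half, half + x / pixel_size
                _draw_disc(tile[:, :, ch_ins], cy, cx, r_out, HORMONE_INTENSITY)
                _draw_disc(tile[:, :, ch["dapi"]], cy, cx, r_nuc, DAPI_INTENSITY)
                _disc_mask(mask, cy, cx, r_out)
        return tile, mask

    raise ValueError(f"unknown confounder kind {spec.kind!r}")


def render_section(
    islets: list[SyntheticIsletSpec],
    confounders: list[ConfounderSpec] | None = None,
    canvas_um: tuple[float, float] = (1600.0, 1600.0),
    pixel_size: float = 1.0,
    noise_sigma: float = 4.0,
    rng: np.random.Generator | None = None,
    max_retries: int = 100,
) -> tuple[SectionImage, SectionGroundTruth]:
    """Render a full synthetic section.

    Islet/confounder tiles are composited (pixelwise max) at their centres;
    objects whose centres are unset (``(0, 0)``) are placed by rejection
    sampling without overlap, up to ``max_retries`` attempts each (then
    :class:`PlacementError` naming the offending object).  Background level
    and per-channel Gaussian noise are added last.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    confounders = confounders or []
    w_um, h_um = canvas_um
    W = int(round(w_um / pixel_size))
    H = int(round(h_um / pixel_size))
    canvas = np.zeros((H, W, 3), dtype=np.uint8)
    islet_labels = np.zeros((H, W), dtype=np.int32)
    conf_labels = np.zeros((H, W), dtype=np.int32)
    occupied = np.zeros((H, W), dtype=bool)
    margin_px = int(round(10.0 / pixel_size))

    def _place(tile: np.ndarray, obj_mask: np.ndarray, center_um, name: str):
        th, tw = obj_mask.shape
        fixed = center_um is not None and tuple(center_um) != (0.0, 0.0)
        grown = ndi.binary_dilation(obj_mask, iterations=margin_px)
        for _ in range(max_retries):
            if fixed:
                cx = int(round(center_um[0] / pixel_size))
                cy = int(round(center_um[1] / pixel_size))
            else:
                cx = int(rng.integers(tw // 2 + 1, W - tw // 2 - 1))
                cy = int(rng.integers(th // 2 + 1, H - th // 2 - 1))
            r0, c0 = cy - th // 2, cx - tw // 2
            if r0 < 0 or c0 < 0 or r0 + th > H or c0 + tw > W:
                if fixed:
                    raise PlacementError(f"{name}: fixed centre does not fit canvas")
                continue
            if (occupied[r0 : r0 + th, c0 : c0 + tw] & grown).any():
                if fixed:
                    raise PlacementError(f"{name}: fixed centre overlaps existing object")
                continue
            region = canvas[r0 : r0 + th, c0 : c0 + tw]
            np.maximum(region, tile, out=region)
            occupied[r0 : r0 + th, c0 : c0 + tw] |= grown
            return r0, c0, (cx * pixel_size, cy * pixel_size)
        raise PlacementError(f"placement failed after {max_retries} retries for {name}")

    truths: list[IsletTruth] = []
    for i, spec in enumerate(islets, start=1):
        tile, masks, truth = render_islet(spec, pixel_size, rng)
        r0, c0, center = _place(tile, masks["islet"], spec.center_um, f"islet {i}")
        th, tw = masks["islet"].shape
        islet_labels[r0 : r0 + th, c0 : c0 + tw][masks["islet"]] = i
        truth.islet_id = i
        cy_c, cx_c = ndi.center_of_mass(masks["islet"])
        truth.centroid_um = (
            (c0 + cx_c) * pixel_size,
            (r0 + cy_c) * pixel_size,
        )
        truths.append(truth)

    conf_truths: list[ConfounderTruth] = []
    for j, cspec in enumerate(confounders, start=1):
        tile, mask = _render_confounder(cspec, pixel_size, rng)
        r0, c0, center = _place(tile, mask, cspec.center_um, f"confounder {j} ({cspec.kind})")
        th, tw = mask.shape
        conf_labels[r0 : r0 + th, c0 : c0 + tw][mask] = j
        cy_c, cx_c = ndi.center_of_mass(mask)
        conf_truths.append(
            ConfounderTruth(
                confounder_id=j,
                kind=cspec.kind,
                centroid_um=((c0 + cx_c) * pixel_size, (r0 + cy_c) * pixel_size),
                area_um2=float(mask.sum()) * pixel_size**2,
            )
        )

    noisy = canvas.astype(np.float64) + BACKGROUND
    if noise_sigma > 0:
        noisy += rng.normal(0.0, noise_sigma, size=noisy.shape)
    pixels = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    img = SectionImage(pixels=pixels, pixel_size=pixel_size)
    truth = SectionGroundTruth(
        islets=truths,
        confounders=conf_truths,
        islet_labels=islet_labels,
        confounder_labels=conf_labels,
        pixel_size=pixel_size,
        section_area_um2=float(H * W) * pixel_size**2,
    )
    return img, truth


# ---------------------------------------------------------------------------
# cohort generation


def _mouse_islet_specs(
    design: CohortDesign, group: str, rng: np.random.Generator
) -> list[list[SyntheticIsletSpec]]:
    """Islet blueprints for one mouse: one list per section."""
    eff = design.effect(group)
    sections = []
    for _ in range(design.sections_per_mouse):
        n_islets = max(1, int(rng.poisson(design.islets_per_section)))
        specs = []
        for _ in range(n_islets):
            area = float(rng.lognormal(design.log_area_mu, design.log_area_sigma))
            area *= eff.area_multiplier
            area = float(np.clip(area, 150.0, 40_000.0))
            ecc = float(rng.uniform(0.0, design.eccentricity_max))
            cap = islet_cell_capacity(area, ecc)
            n_alpha = int(round(design.alpha_cell_fraction * cap)) if cap >= 4 else 0
            n_beta = max(1, int(round((cap - n_alpha) * eff.beta_count_multiplier)))
            # islet grows with extra beta cells so they still pack
            render_area = area * (n_beta + n_alpha) / max(cap, 1)
            specs.append(
                SyntheticIsletSpec(
                    center_um=(0.0, 0.0),
                    target_area_um2=render_area,
                    n_beta_cells=n_beta,
                    n_alpha_cells=n_alpha,
                    eccentricity=ecc,
                    marker_positive_beta_fraction=design.marker_positive_beta_fraction,
                )
            )
        sections.append(specs)
    return sections


def generate_cohort(design: CohortDesign, outdir: str | Path) -> Path:
    """Generate a full synthetic cohort on disk; returns the manifest path.

    Writes one 3-channel 8-bit TIFF and one ground-truth JSON per section,
    plus ``manifest.csv`` with one row per section (mouse id, group, section
    path, pixel size, pancreas-plus-spleen weight).  Bit-identical for a
    fixed design and seed.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(design.rng_seed)
    rows = []
    for group, n_mice in design.groups:
        for m in range(n_mice):
            mouse_id = f"{group}_{m + 1:02d}"
            for s, specs in enumerate(_mouse_islet_specs(design, group, rng)):
                img, truth = render_section(
                    specs,
                    [],
                    canvas_um=design.canvas_um,
                    pixel_size=design.pixel_size,
                    noise_sigma=design.noise_sigma,
                    rng=rng,
                )
                stem = f"{mouse_id}_s{s + 1}"
                write_section_image(outdir / f"{stem}.tif", img.pixels)
                truth.to_json(outdir / f"{stem}_truth.json")
                rows.append(
                    {
                        "mouse_id": mouse_id,
                        "group": group,
                        "section_path": f"{stem}.tif",
                        "truth_path": f"{stem}_truth.json",
                        "pixel_size_um": design.pixel_size,
                        "pancreas_spleen_weight_g": design.pancreas_spleen_weight_g,
                    }
                )
    manifest_path = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


def sample_mouse_mean_areas(
    design: CohortDesign, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Per-mouse mean true islet areas, drawn without per-islet bookkeeping.

    Follows the cohort sampling path (Poisson islet counts over the mouse's
    sections, lognormal areas times the group multiplier, clipped to the
    renderable range) but aggregates to the per-mouse mean immediately;
    suited to replicate-scale power and type-I simulations.  Returns
    ``{group: array of per-mouse means}``.
    """
    rng = rng if rng is not None else np.random.default_rng(design.rng_seed)
    out: dict[str, np.ndarray] = {}
    for group, n_mice in design.groups:
        mult = design.effect(group).area_multiplier
        means = np.empty(n_mice)
        for m in range(n_mice):
            n = max(
                design.sections_per_mouse,
                int(rng.poisson(design.islets_per_section * design.sections_per_mouse)),
            )
            areas = rng.lognormal(design.log_area_mu, design.log_area_sigma, n)
            means[m] = float(np.clip(areas * mult, 150.0, 40_000.0).mean())
        out[group] = means
    return out


def sample_cohort_truth(design: CohortDesign, rng: np.random.Generator | None = None):
    """Draw per-islet truth for a cohort without rasterizing images.

    Follows the same sampling path as :func:`generate_cohort` (Poisson islet
    counts, lognormal areas times group multipliers, capacity-derived beta
    counts) and returns a tidy DataFrame with columns ``mouse_id``,
    ``group``, ``section_index``, ``area_um2``, ``beta_count``.  Useful for
    replicate-scale simulations where only cohort summaries matter.
    """
    import pandas as pd

    rng = rng if rng is not None else np.random.default_rng(design.rng_seed)
    rows = []
    for group, n_mice in design.groups:
        eff = design.effect(group)
        for m in range(n_mice):
            mouse_id = f"{group}_{m + 1:02d}"
            for s in range(design.sections_per_mouse):
                n_islets = max(1, int(rng.poisson(design.islets_per_section)))
                areas = rng.lognormal(design.log_area_mu, design.log_area_sigma, n_islets)
                areas = np.clip(areas * eff.area_multiplier, 150.0, 40_000.0)
                for a in areas:
                    n_cells = a / CELL_FOOTPRINT_UM2
                    n_beta = max(
                        1,
                        int(round(n_cells * (1 - design.alpha_cell_fraction)
                                  * eff.beta_count_multiplier)),
                    )
                    rows.append(
                        {
                            "mouse_id": mouse_id,
                            "group": group,
                            "section_index": s,
                            "area_um2": float(a),
                            "beta_count": n_beta,
                        }
                    )
    return pd.DataFrame(rows)
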
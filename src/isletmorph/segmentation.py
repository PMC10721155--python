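"""Islet detection and inclusion/exclusion filtering.

An islet is operationally a connected hormone-positive region holding at
least one insulin-positive, DAPI-stained cell, with cross-sectional area
strictly above 50 um^2.  Candidates failing this definition — hormone signal
without nuclei, regions with only non-beta hormones, sub-threshold specks,
out-of-focus (blurred) regions, and ambiguous near-contiguous micro-clusters
— are excluded, each tagged with the reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk, remove_small_holes, remove_small_objects
from skimage.segmentation import watershed

from .config import AnalysisConfig
from .imaging_io import SectionImage

__all__ = [
    "ChannelMasks",
    "CandidateRegion",
    "NucleusTable",
    "EXCLUSION_FLAGS",
    "threshold_channel",
    "detect_nuclei",
    "nucleus_table",
    "extract_candidates",
    "focus_score",
    "filter_candidates",
    "segment_section",
]

EXCLUSION_FLAGS = (
    "no_insulin_dapi_cell",
    "subthreshold_area",
    "nonbeta_only",
    "out_of_focus",
    "ambiguous_microclusters",
)


@dataclass
class ChannelMasks:
    """Binary positivity masks for the three channels plus thresholds used."""

    insulin: np.ndarray
    marker2: np.ndarray
    dapi: np.ndarray
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.insulin, self.marker2, self.dapi)}
        if len(shapes) != 1:
            raise ValueError("channel masks must share one shape")
        for name in ("insulin", "marker2", "dapi"):
            if getattr(self, name).dtype != bool:
                raise ValueError(f"{name} mask must be boolean")


@dataclass
class NucleusTable:
    """Per-nucleus statistics for one section, computed once.

    ``insulin_frac``/``marker_frac`` are the fractions of each nucleus'
    pixels lying in the respective hormone mask; centroids are rounded to
    pixel indices for fast region-membership lookups.
    """

    labels: np.ndarray  # (N,) nucleus label ids
    row: np.ndarray  # (N,) centroid row, int
    col: np.ndarray  # (N,) centroid col, int
    insulin_frac: np.ndarray
    marker_frac: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class CandidateRegion:
    """One connected candidate region with its exclusion bookkeeping.

    ``mask`` is local to ``bbox`` (the region's bounding-box slices in the
    full frame).
    """

    label: int
    mask: np.ndarray
    bbox: tuple[slice, slice]
    area_um2: float
    n_insulin_dapi_cells: int
    n_marker_pos_beta: int = 0
    focus: float = float("nan")
    exclusion_flags: set[str] = field(default_factory=set)

    @property
    def excluded(self) -> bool:
        return bool(self.exclusion_flags)

    def centroid_px(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return (
            float(rr.mean()) + self.bbox[0].start,
            float(cc.mean()) + self.bbox[1].start,
        )


def threshold_channel(
    channel: np.ndarray,
    method: str = "otsu",
    fixed_value: float | None = None,
    min_object_px: int = 9,
    min_hole_px: int = 64,
) -> tuple[np.ndarray, float]:
    """Binarize one 8-bit channel; returns (mask, threshold used).

    Positivity is strict (``intensity > t``).  Specks strictly smaller than
    ``min_object_px`` pixels are removed and holes smaller than
    ``min_hole_px`` filled, deterministically.  An all-constant channel
    yields an empty mask.
    """
    channel = np.asarray(channel)
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed thresholding needs fixed_value")
        t = float(fixed_value)
    elif method == "otsu":
        if channel.max() == channel.min():
            return np.zeros(channel.shape, bool), float(channel.max())
        t = float(threshold_otsu(channel))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = channel > t
    if min_object_px > 1:
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    if min_hole_px > 1:
        mask = remove_small_holes(mask, max_size=min_hole_px - 1)
    return mask, t


def detect_nuclei(
    dapi_mask: np.ndarray, pixel_size: float, min_sep_um: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Label nuclei, splitting touching ones by distance-transform watershed.

    Seeds are local maxima of the Euclidean distance transform with minimum
    separation ``min_sep_um``.  Returns (label image, centroid array (N, 2)
    in row/col pixels).
    """
    dapi_mask = dapi_mask.astype(bool)
    if not dapi_mask.any():
        return np.zeros(dapi_mask.shape, dtype=np.int32), np.empty((0, 2))
    dist = ndi.distance_transform_edt(dapi_mask)
    min_dist = max(1, int(round(min_sep_um / pixel_size)))
    peaks = peak_local_max(
        dist, min_distance=min_dist, labels=dapi_mask, exclude_border=False
    )
    markers = np.zeros(dapi_mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:  # pathological: no peak found, fall back to components
        labels = label(dapi_mask).astype(np.int32)
    else:
        labels = watershed(-dist, markers, mask=dapi_mask).astype(np.int32)
    n = int(labels.max())
    centroids = np.asarray(
        ndi.center_of_mass(dapi_mask, labels, np.arange(1, n + 1)), dtype=float
    ).reshape(-1, 2)
    return labels, centroids


def nucleus_table(
    nuclei_labels: np.ndarray,
    insulin_mask: np.ndarray,
    marker2_mask: np.ndarray,
) -> NucleusTable:
    """Vectorized per-nucleus sizes, centroids and hormone-overlap fractions."""
    n = int(nuclei_labels.max())
    if n == 0:
        empty = np.empty(0)
        return NucleusTable(
            labels=np.empty(0, int), row=np.empty(0, int), col=np.empty(0, int),
            insulin_frac=empty, marker_frac=empty.copy(),
        )
    sizes = np.bincount(nuclei_labels.ravel(), minlength=n + 1)[1:]
    ins = np.bincount(
        nuclei_labels[insulin_mask].ravel(), minlength=n + 1
    )[1:]
    mrk = np.bincount(
        nuclei_labels[marker2_mask].ravel(), minlength=n + 1
    )[1:]
    cents = np.asarray(
        ndi.center_of_mass(nuclei_labels > 0, nuclei_labels, np.arange(1, n + 1))
    ).reshape(-1, 2)
    keep = sizes > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ins_frac = np.where(keep, ins / np.maximum(sizes, 1), 0.0)
        mrk_frac = np.where(keep, mrk / np.maximum(sizes, 1), 0.0)
    return NucleusTable(
        labels=np.arange(1, n + 1)[keep],
        row=np.rint(cents[keep, 0]).astype(int),
        col=np.rint(cents[keep, 1]).astype(int),
        insulin_frac=ins_frac[keep],
        marker_frac=mrk_frac[keep],
    )


def extract_candidates(
    masks: ChannelMasks,
    pixel_size: float,
    nuclei: NucleusTable,
    config: AnalysisConfig | None = None,
) -> tuple[list[CandidateRegion], np.ndarray]:
    """Connected candidate regions from the closed hormone-mask union.

    The union of insulin and second-marker masks is morphologically closed
    (radius ``r_close_um``) and hole-filled, so the beta core and alpha
    mantle of one islet join into a single candidate.  Per candidate, the
    insulin+/DAPI+ cells are the nuclei whose centroid falls in the
    candidate and whose insulin-overlap fraction reaches
    ``insulin_overlap_fraction``; marker-positive beta cells additionally
    reach ``marker_overlap_fraction`` in the second-marker mask.  Returns
    (candidates, candidate label image).
    """
    config = config or AnalysisConfig()
    union = masks.insulin | masks.marker2
    r_px = max(1, int(round(config.r_close_um / pixel_size)))
    closed = closing(np.pad(union, r_px + 1), disk(r_px))[
        r_px + 1 : -(r_px + 1), r_px + 1 : -(r_px + 1)
    ]
    closed = ndi.binary_fill_holes(closed)
    labels = label(closed, connectivity=2)
    cand_at_nucleus = (
        labels[nuclei.row, nuclei.col] if len(nuclei) else np.empty(0, int)
    )
    is_beta = (
        (nuclei.insulin_frac >= config.insulin_overlap_fraction)
        if len(nuclei)
        else np.empty(0, bool)
    )
    is_marker = (
        is_beta & (nuclei.marker_frac >= config.marker_overlap_fraction)
        if len(nuclei)
        else np.empty(0, bool)
    )
    out: list[CandidateRegion] = []
    for p in regionprops(labels):
        mine = cand_at_nucleus == p.label
        out.append(
            CandidateRegion(
                label=int(p.label),
                mask=p.image,
                bbox=(slice(p.bbox[0], p.bbox[2]), slice(p.bbox[1], p.bbox[3])),
                area_um2=float(p.area) * pixel_size**2,
                n_insulin_dapi_cells=int((mine & is_beta).sum()),
                n_marker_pos_beta=int((mine & is_marker).sum()),
            )
        )
    return out, labels


def focus_score(image_channel: np.ndarray, region_mask: np.ndarray) -> float:
    """Sharpness of a region: variance of the Laplacian over squared mean intensity.

    The mean-squared normalisation makes the score invariant to global
    intensity scaling, so bright and dim-but-sharp regions rank alike;
    uniform regions score 0.  Higher is sharper.
    """
    region_mask = region_mask.astype(bool)
    if not region_mask.any():
        raise ValueError("empty region")
    img = np.asarray(image_channel, dtype=float)
    lap = ndi.laplace(img)
    vals = lap[region_mask]
    mean = img[region_mask].mean()
    if mean <= 0:
        return 0.0
    return float(vals.var() / mean**2)


def _microcluster_flag(
    cand: CandidateRegion,
    masks: ChannelMasks,
    nuclei: NucleusTable,
    pixel_size: float,
    config: AnalysisConfig,
) -> bool:
    """Ambiguous micro-cluster rule, evaluated on the pre-closing components.

    True when the candidate decomposes (before closing) into >= 2 hormone
    components, each holding at most ``microcluster_max_cells``
    insulin+/DAPI+ cells, with every pairwise boundary gap below
    ``microcluster_max_gap_um``: impossible to call one islet vs several.
    All work happens inside the candidate's bounding box.
    """
    sl = cand.bbox
    raw = (masks.insulin[sl] | masks.marker2[sl]) & cand.mask
    comp = label(raw, connectivity=2)
    n = int(comp.max())
    if n < 2:
        return False
    # cells per raw component, via nucleus centroids falling inside the box
    r0, c0 = sl[0].start, sl[1].start
    inside = (
        (nuclei.row >= r0) & (nuclei.row < sl[0].stop)
        & (nuclei.col >= c0) & (nuclei.col < sl[1].stop)
        & (nuclei.insulin_frac >= config.insulin_overlap_fraction)
    )
    comp_of_cell = comp[nuclei.row[inside] - r0, nuclei.col[inside] - c0]
    counts = np.bincount(comp_of_cell, minlength=n + 1)[1:]
    if (counts > config.microcluster_max_cells).any():
        return False
    gap_max_px = config.microcluster_max_gap_um / pixel_size
    for i in range(1, n + 1):
        dist_i = ndi.distance_transform_edt(comp != i)
        for j in range(i + 1, n + 1):
            if dist_i[comp == j].min() - 1 >= gap_max_px:
                return False
    return True


def filter_candidates(
    candidates: list[CandidateRegion],
    masks: ChannelMasks,
    nuclei: NucleusTable,
    dapi_channel: np.ndarray,
    pixel_size: float,
    config: AnalysisConfig | None = None,
) -> tuple[list[CandidateRegion], list[CandidateRegion]]:
    """Partition candidates into retained islets and flagged exclusions.

    Rules are checked in a fixed priority so each exclusion carries the
    single most informative flag: non-beta-only regions first, then hormone
    signal without an insulin+/DAPI+ cell, the >50 um^2 area floor,
    ambiguous micro-clusters, and finally the focus criterion (score below
    ``focus_fraction`` x the median score of the section's provisional
    islets).  The result is independent of candidate order.
    """
    config = config or AnalysisConfig()
    for cand in candidates:
        cand.exclusion_flags = set()
        sl = cand.bbox
        cand.focus = focus_score(dapi_channel[sl], cand.mask)
        insulin_px = int((masks.insulin[sl] & cand.mask).sum())
        marker_px = int((masks.marker2[sl] & cand.mask).sum())
        if insulin_px == 0 and marker_px > 0:
            cand.exclusion_flags.add("nonbeta_only")
        elif cand.n_insulin_dapi_cells < 1:
            cand.exclusion_flags.add("no_insulin_dapi_cell")
        elif cand.area_um2 <= config.min_islet_area_um2:
            cand.exclusion_flags.add("subthreshold_area")
        elif _microcluster_flag(cand, masks, nuclei, pixel_size, config):
            cand.exclusion_flags.add("ambiguous_microclusters")
    provisional = [c for c in candidates if not c.exclusion_flags]
    if provisional:
        median_focus = float(np.median([c.focus for c in provisional]))
        cutoff = config.focus_fraction * median_focus
        for cand in provisional:
            if cand.focus < cutoff:
                cand.exclusion_flags.add("out_of_focus")
    islets = [c for c in candidates if not c.exclusion_flags]
    excluded = [c for c in candidates if c.exclusion_flags]
    return islets, excluded


def segment_section(
    img: SectionImage, config: AnalysisConfig | None = None
) -> tuple[list[CandidateRegion], list[CandidateRegion], ChannelMasks, np.ndarray]:
    """Full per-section segmentation.

    Thresholds the three channels, labels nuclei, extracts candidates and
    applies the exclusion filter.  Returns (islets, excluded, channel masks,
    nucleus label image).
    """
    config = config or AnalysisConfig()
    masks = {}
    thresholds = {}
    for name in ("insulin", "marker2", "dapi"):
        m, t = threshold_channel(
            img.channel(name),
            method=config.threshold_method,
            fixed_value=config.fixed_thresholds.get(name),
            min_object_px=config.min_object_px,
            min_hole_px=config.min_hole_px,
        )
        masks[name] = m
        thresholds[name] = t
    channel_masks = ChannelMasks(
        insulin=masks["insulin"],
        marker2=masks["marker2"],
        dapi=masks["dapi"],
        thresholds=thresholds,
    )
    nuclei_labels, _ = detect_nuclei(
        channel_masks.dapi, img.pixel_size, config.nucleus_min_sep_um
    )
    nuclei = nucleus_table(nuclei_labels, channel_masks.insulin, channel_masks.marker2)
    candidates, _ = extract_candidates(channel_masks, img.pixel_size, nuclei, config)
    islets, excluded = filter_candidates(
        candidates, channel_masks, nuclei, img.channel("dapi"), img.pixel_size, config
    )
    return islets, excluded, channel_masks, nuclei_labels
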
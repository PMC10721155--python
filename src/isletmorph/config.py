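"""Analysis configuration.

All thresholds and geometric parameters used by the segmentation and
morphometry stages live in one flat dataclass so a whole run is reproducible
from a single config file.  Lengths are in micrometres unless the name says
otherwise; areas in square micrometres.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the islet analysis pipeline.

    Parameters
    ----------
    channel_map
        Mapping from semantic channel name (``insulin``, ``marker2``,
        ``dapi``) to RGB index.  Default follows the common staining layout:
        red = second marker, green = insulin, blue = DAPI.
    threshold_method
        ``"otsu"`` for automatic per-channel Otsu thresholds, or ``"fixed"``
        to use ``fixed_thresholds`` (strict ``> value`` convention).
    min_islet_area_um2
        Inclusion floor for islets; a candidate must exceed this
        cross-sectional area (strictly) to be retained.
    r_close_um
        Radius of the morphological closing applied to the hormone-mask
        union before connected-component labelling, bridging the small gaps
        between beta-cell cores and alpha-cell mantles of one islet.
    nucleus_min_sep_um
        Minimum separation of watershed seeds when splitting touching
        nuclei.
    insulin_overlap_fraction
        Fraction of a nucleus' pixels that must lie in the insulin mask for
        the cell to count as an insulin-positive, DAPI-stained cell.
    microcluster_max_cells, microcluster_max_gap_um
        A merged candidate whose pre-closing components each hold at most
        ``microcluster_max_cells`` insulin+/DAPI+ cells, with pairwise
        boundary gaps below ``microcluster_max_gap_um``, is excluded as an
        ambiguous micro-cluster (single islet vs several tiny ones cannot be
        decided).
    focus_fraction
        A candidate is excluded as out of focus when its focus score falls
        below ``focus_fraction`` times the median focus score of the
        section's provisional islets.
    marker_overlap_fraction
        Fraction of a beta-cell nucleus that must overlap the second-marker
        mask for the cell to count as marker-positive.
    perimeter_method
        ``"contour"`` (subpixel marching-squares polygon, simplified with
        Douglas-Peucker tolerance ``contour_tolerance_px``) or ``"crofton"``
        (4-direction Crofton estimator).
    rescale_trigger_intensity
        Brightness rescaling is applied to a channel only when its
        ``rescale_high_pct`` percentile intensity is below this value
        (suboptimal signal/noise).
    """

    channel_map: dict[str, int] = field(
        default_factory=lambda: {"marker2": 0, "insulin": 1, "dapi": 2}
    )

    # channel thresholding
    threshold_method: str = "otsu"
    fixed_thresholds: dict[str, float] = field(
        default_factory=lambda: {"insulin": 50.0, "marker2": 50.0, "dapi": 40.0}
    )
    min_object_px: int = 9
    min_hole_px: int = 64

    # islet definition / exclusion rules
    min_islet_area_um2: float = 50.0
    r_close_um: float = 5.0
    nucleus_min_sep_um: float = 4.0
    insulin_overlap_fraction: float = 0.5
    microcluster_max_cells: int = 3
    microcluster_max_gap_um: float = 10.0
    focus_fraction: float = 0.2

    # morphometry
    marker_overlap_fraction: float = 0.5
    perimeter_method: str = "contour"
    contour_tolerance_px: float = 1.0

    # brightness rescaling (high anchor is the bright tail: on whole
    # sections the 99th percentile is still background)
    rescale_low_pct: float = 1.0
    rescale_high_pct: float = 99.9
    rescale_trigger_intensity: float = 128.0

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.perimeter_method not in ("contour", "crofton"):
            raise ValueError(f"unknown perimeter_method {self.perimeter_method!r}")
        if sorted(self.channel_map.values()) != [0, 1, 2]:
            raise ValueError("channel_map must be a bijection onto {0, 1, 2}")

    def replace(self, **kwargs: Any) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a flat ``key = value`` file.

    The file uses TOML-compatible syntax; unknown keys raise.  Channel maps
    and fixed thresholds use dotted keys (``channel_map.insulin = 1``).
    """
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = AnalysisConfig()
    fields = {f.name for f in dataclasses.fields(AnalysisConfig)}
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key not in fields:
            raise KeyError(f"unknown config key {key!r} in {path}")
        if isinstance(value, dict):
            merged = dict(getattr(cfg, key))
            merged.update(value)
            value = merged
        kwargs[key] = value
    return AnalysisConfig(**kwargs)
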
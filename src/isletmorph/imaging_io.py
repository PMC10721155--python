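"""Reading calibrated section images, manifests and table output.

Sections arrive as 8-bit RGB TIFF or PNG files; the micrometre-per-pixel
calibration travels in the cohort manifest rather than in image metadata,
because TIFF resolution tags are unreliable across writers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "SectionImage",
    "Manifest",
    "read_section",
    "rescale_brightness",
    "auto_rescale",
    "write_section_image",
]

logger = logging.getLogger("isletmorph")

DEFAULT_CHANNEL_MAP = {"marker2": 0, "insulin": 1, "dapi": 2}


@dataclass
class SectionImage:
    """A calibrated 3-channel, 8-bit pancreas-section image.

    ``channel_map`` maps the semantic channels (``insulin``, ``marker2``,
    ``dapi``) to indices of the last array axis.
    """

    pixels: np.ndarray  # H x W x 3, uint8
    pixel_size: float  # um / px
    mouse_id: str = ""
    section_index: int = 0
    channel_map: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_MAP)
    )

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit")
        if sorted(self.channel_map.values()) != [0, 1, 2]:
            raise ValueError("channel_map must be a bijection onto {0, 1, 2}")

    def channel(self, name: str) -> np.ndarray:
        """Return one semantic channel as a 2-D uint8 array."""
        return self.pixels[:, :, self.channel_map[name]]

    @property
    def section_area_um2(self) -> float:
        h, w = self.pixels.shape[:2]
        return float(h * w) * self.pixel_size**2


@dataclass
class Manifest:
    """Cohort manifest: one row per section, grouped by mouse.

    Required columns: ``mouse_id``, ``group``, ``section_path``,
    ``pixel_size_um``, ``pancreas_spleen_weight_g``.  Optional columns
    (``body_weight_g``, plasma values) pass through untouched.
    """

    table: pd.DataFrame
    root: Path = Path(".")

    REQUIRED = (
        "mouse_id",
        "group",
        "section_path",
        "pixel_size_um",
        "pancreas_spleen_weight_g",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if self.table.groupby("mouse_id").size().min() < 1:
            raise ValueError("every mouse needs at least one section")

    @classmethod
    def read(cls, path: str | Path, check_paths: bool = True) -> "Manifest":
        path = Path(path)
        table = pd.read_csv(path, dtype={"mouse_id": str})
        m = cls(table=table, root=path.parent)
        if check_paths:
            bad = [p for p in m.section_paths() if not p.exists()]
            if bad:
                raise FileNotFoundError(f"manifest references missing files: {bad}")
        return m

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def section_paths(self) -> list[Path]:
        return [self.root / p for p in self.table["section_path"]]

    def mice(self) -> list[str]:
        return list(dict.fromkeys(self.table["mouse_id"]))

    def rows_for(self, mouse_id: str) -> pd.DataFrame:
        return self.table[self.table["mouse_id"] == mouse_id]

    def sections_for(self, mouse_id: str) -> list[SectionImage]:
        """Load every section image of one mouse, in manifest order."""
        out = []
        for i, (_, row) in enumerate(self.rows_for(mouse_id).iterrows()):
            out.append(
                read_section(
                    self.root / row["section_path"],
                    pixel_size=float(row["pixel_size_um"]),
                    mouse_id=mouse_id,
                    section_index=i,
                )
            )
        return out


def read_section(
    path: str | Path,
    pixel_size: float,
    channel_map: dict[str, int] | None = None,
    mouse_id: str = "",
    section_index: int = 0,
) -> SectionImage:
    """Read a 3-channel 8-bit TIFF/PNG into a :class:`SectionImage`.

    Pixels are returned exactly as stored; a wrong channel count or bit
    depth raises ``ValueError`` naming the file.
    """
    path = Path(path)
    pixels = np.asarray(iio.imread(path))
    if pixels.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit image, got {pixels.dtype}")
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"{path}: expected 3 channels, got shape {pixels.shape}")
    return SectionImage(
        pixels=pixels,
        pixel_size=pixel_size,
        mouse_id=mouse_id,
        section_index=section_index,
        channel_map=dict(channel_map or DEFAULT_CHANNEL_MAP),
    )


def write_section_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write an H x W x 3 uint8 array as TIFF or PNG by extension."""
    iio.imwrite(Path(path), np.ascontiguousarray(pixels))


def rescale_brightness(
    img: SectionImage, low_pct: float = 1.0, high_pct: float = 99.0
) -> SectionImage:
    """Per-channel linear brightness stretch.

    Maps each channel's ``low_pct`` percentile to 0 and ``high_pct``
    percentile to 255, clipping outside; monotone within every channel.  A
    channel with zero dynamic range between the two percentiles is returned
    unchanged with a logged warning.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    out = img.pixels.astype(np.float64).copy()
    for c in range(3):
        lo, hi = np.percentile(img.pixels[:, :, c], [low_pct, high_pct])
        if hi <= lo:
            logger.warning(
                "channel %d has zero dynamic range (p%.4g = p%.4g = %g); left unchanged",
                c, low_pct, high_pct, lo,
            )
            continue
        out[:, :, c] = (out[:, :, c] - lo) * (255.0 / (hi - lo))
    pixels = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return SectionImage(
        pixels=pixels,
        pixel_size=img.pixel_size,
        mouse_id=img.mouse_id,
        section_index=img.section_index,
        channel_map=dict(img.channel_map),
    )


def auto_rescale(
    img: SectionImage,
    low_pct: float = 1.0,
    high_pct: float = 99.9,
    trigger_intensity: float = 128.0,
) -> SectionImage:
    """Rescale brightness only for suboptimal signal/noise images.

    A channel is considered suboptimal when its bright-tail intensity (the
    ``high_pct`` percentile) falls below ``trigger_intensity``; only such
    channels are stretched.  On whole sections, where stained tissue covers
    a few percent of the frame, the bright tail must sit well above the
    median (which is background) — hence the 99.9 default here.
    """
    need = []
    for c in range(3):
        ch = img.pixels[:, :, c]
        p_high = np.percentile(ch, high_pct)
        # dim signal, not signal-free: the bright tail must still stand
        # clear of the background median or there is nothing to stretch
        if p_high < trigger_intensity and p_high >= 3.0 * max(np.median(ch), 1.0):
            need.append(c)
    if not need:
        return img
    stretched = rescale_brightness(img, low_pct, high_pct)
    pixels = img.pixels.copy()
    for c in need:
        pixels[:, :, c] = stretched.pixels[:, :, c]
        logger.info(
            "section %s/%d: rescaled channel %d (suboptimal signal/noise)",
            img.mouse_id, img.section_index, c,
        )
    return SectionImage(
        pixels=pixels,
        pixel_size=img.pixel_size,
        mouse_id=img.mouse_id,
        section_index=img.section_index,
        channel_map=dict(img.channel_map),
    )
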
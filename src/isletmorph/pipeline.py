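"""End-to-end orchestration: section image -> islet records -> mouse summaries."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import morphometry
from .cohort_metrics import MouseSummary, summaries_to_frame, summarize_mouse
from .config import AnalysisConfig
from .imaging_io import Manifest, SectionImage, auto_rescale
from .morphometry import IsletRecord
from .segmentation import CandidateRegion, ChannelMasks, segment_section

__all__ = ["measure_section", "analyze_section", "analyze_cohort"]

logger = logging.getLogger("isletmorph")


def measure_section(
    img: SectionImage,
    islets: list[CandidateRegion],
    masks: ChannelMasks,
    config: AnalysisConfig | None = None,
) -> list[IsletRecord]:
    """Morphometry for every retained islet of one segmented section."""
    config = config or AnalysisConfig()
    px = img.pixel_size
    records = []
    for cand in islets:
        sl = cand.bbox
        mask = cand.mask
        area = morphometry.measure_area(mask, px)
        perim = morphometry.perimeter_length(
            mask, px, config.perimeter_method, config.contour_tolerance_px
        )
        feret = morphometry.feret_diameter(mask, px)
        circ = morphometry.circularity(
            mask, px, config.perimeter_method, config.contour_tolerance_px
        )
        beta_area = morphometry.hormone_area(mask, masks.insulin[sl], px)
        alpha_area = morphometry.hormone_area(mask, masks.marker2[sl], px)
        beta_count = cand.n_insulin_dapi_cells
        marker_pos = cand.n_marker_pos_beta
        records.append(
            IsletRecord(
                islet_id=cand.label,
                mouse_id=img.mouse_id,
                section_index=img.section_index,
                area_um2=area,
                perimeter_um=perim,
                feret_um=feret,
                circularity=circ,
                beta_area_um2=beta_area,
                alpha_area_um2=alpha_area,
                delta_area_um2=float("nan"),
                beta_count=beta_count,
                beta_cell_size_um2=(
                    beta_area / beta_count if beta_count >= 1 else float("nan")
                ),
                marker_pos_beta=marker_pos,
                marker_neg_beta=beta_count - marker_pos,
            )
        )
    return records


def analyze_section(
    img: SectionImage, config: AnalysisConfig | None = None, rescale: bool = True
) -> tuple[list[IsletRecord], list[CandidateRegion]]:
    """Segment and measure one section; returns (islet records, excluded candidates)."""
    config = config or AnalysisConfig()
    if rescale:
        img = auto_rescale(
            img,
            config.rescale_low_pct,
            config.rescale_high_pct,
            config.rescale_trigger_intensity,
        )
    islets, excluded, masks, _ = segment_section(img, config)
    records = measure_section(img, islets, masks, config)
    logger.info(
        "section %s/%d: %d islets retained, %d excluded",
        img.mouse_id, img.section_index, len(records), len(excluded),
    )
    return records, excluded


def analyze_cohort(
    manifest: Manifest | str | Path,
    config: AnalysisConfig | None = None,
    rescale: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full pipeline over a cohort manifest.

    Returns (per-islet table, per-mouse summary table).  Sections are
    processed in manifest order; per-mouse totals pool all of the mouse's
    sections.
    """
    if not isinstance(manifest, Manifest):
        manifest = Manifest.read(manifest)
    config = config or AnalysisConfig()
    all_records: list[IsletRecord] = []
    summaries: list[MouseSummary] = []
    for mouse_id in manifest.mice():
        rows = manifest.rows_for(mouse_id)
        mouse_records: list[IsletRecord] = []
        total_area = 0.0
        for img in manifest.sections_for(mouse_id):
            records, _ = analyze_section(img, config, rescale=rescale)
            mouse_records.extend(records)
            total_area += img.section_area_um2
        all_records.extend(mouse_records)
        summaries.append(
            summarize_mouse(
                mouse_records,
                total_section_area_um2=total_area,
                mouse_id=mouse_id,
                group=str(rows["group"].iloc[0]),
                pancreas_spleen_weight_g=float(
                    rows["pancreas_spleen_weight_g"].iloc[0]
                ),
            )
        )
    islet_df = pd.DataFrame([vars(r) for r in all_records])
    return islet_df, summaries_to_frame(summaries)
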
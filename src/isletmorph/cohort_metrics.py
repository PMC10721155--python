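"""Per-mouse aggregation of islet records and cohort-level derived metrics.

All quantities follow the section-based conventions of quantitative islet
histology: totals are taken over the four head-to-tail sections of a mouse,
relative areas are percentages of the total sectioned pancreas area, and
beta-cell mass scales the sectional beta-area fraction by the weight of the
dissected pancreas (weighed together with the spleen, as a proxy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import IsletRecord

__all__ = [
    "MouseSummary",
    "SizeHistogram",
    "relative_islet_area",
    "beta_cell_mass",
    "islet_density",
    "size_class_distribution",
    "summarize_mouse",
    "summaries_to_frame",
]


@dataclass
class MouseSummary:
    """Aggregates of one mouse's retained islets over its sections."""

    mouse_id: str
    group: str
    n_islets: int
    mean_islet_area_um2: float
    mean_feret_um: float
    mean_circularity: float
    mean_beta_area_um2: float
    mean_alpha_area_um2: float
    mean_beta_count: float
    mean_beta_cell_size_um2: float
    total_section_area_um2: float
    relative_islet_area_pct: float
    relative_beta_area_pct: float
    beta_cell_mass_g: float
    islet_density_per_mm2: float
    marker_pos_beta_pct: float


@dataclass
class SizeHistogram:
    """Per-mouse islet size-class distribution (percent of islets per bin).

    ``bin_edges`` are the finite left edges; the last bin is open-ended.
    Percentages sum to 100 for every mouse with at least one islet.
    """

    bin_edges: np.ndarray
    open_last_from: float
    percents: pd.DataFrame  # index mouse_id, one column per bin
    labels: list[str] = field(default_factory=list)


def relative_islet_area(total_islet_area: float, total_section_area: float) -> float:
    """Percent of sectioned pancreas area occupied by islet tissue.

    ``100 * total_islet_area / total_section_area``; inputs must share one
    unit.  Islet area exceeding the section area indicates a mask
    bookkeeping bug and raises.
    """
    if total_section_area <= 0:
        raise ValueError("total_section_area must be positive")
    if total_islet_area > total_section_area:
        raise ValueError("islet area exceeds section area (mask bookkeeping bug)")
    return 100.0 * total_islet_area / total_section_area


def beta_cell_mass(
    total_beta_area: float, total_pancreas_area: float, pancreas_spleen_weight_g: float
) -> float:
    """Beta-cell mass proxy in grams.

    (total beta-cell area over the sections / total pancreas area of those
    sections) x pancreas-plus-spleen weight.
    """
    if total_pancreas_area <= 0:
        raise ValueError("total_pancreas_area must be positive")
    if pancreas_spleen_weight_g <= 0:
        raise ValueError("weight must be positive")
    return (total_beta_area / total_pancreas_area) * pancreas_spleen_weight_g


def islet_density(n_islets: int, total_pancreas_area_mm2: float) -> float:
    """Islets per mm^2 of sectioned pancreas."""
    if total_pancreas_area_mm2 <= 0:
        raise ValueError("total_pancreas_area_mm2 must be positive")
    return n_islets / total_pancreas_area_mm2


def size_class_distribution(
    records: pd.DataFrame,
    bin_width: float,
    open_last_from: float,
    area_column: str = "area_um2",
    mouse_column: str = "mouse_id",
) -> SizeHistogram:
    """Per-mouse percent of islets in consecutive area classes.

    Bins are left-closed right-open ``[0, w), [w, 2w), ...`` up to
    ``open_last_from``, plus a final open-ended class ``[open_last_from,
    inf)``.  ``bin_width`` and ``open_last_from`` share the unit of
    ``area_column``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if open_last_from <= 0 or open_last_from % bin_width:
        n_closed = int(math.ceil(open_last_from / bin_width))
    else:
        n_closed = int(round(open_last_from / bin_width))
    edges = np.arange(n_closed + 1) * bin_width
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(n_closed)]
    labels.append(f">={open_last_from:g}")
    rows = {}
    for mouse, sub in records.groupby(mouse_column, sort=True):
        areas = sub[area_column].to_numpy()
        counts = np.zeros(n_closed + 1)
        idx = np.minimum(
            np.floor(areas / bin_width).astype(int), n_closed
        )
        idx[areas >= open_last_from] = n_closed
        for i in idx:
            counts[i] += 1
        rows[mouse] = 100.0 * counts / counts.sum()
    percents = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    percents.index.name = mouse_column
    return SizeHistogram(
        bin_edges=edges, open_last_from=open_last_from, percents=percents, labels=labels
    )


def summarize_mouse(
    records: list[IsletRecord] | pd.DataFrame,
    total_section_area_um2: float,
    mouse_id: str,
    group: str = "",
    pancreas_spleen_weight_g: float | None = None,
) -> MouseSummary:
    """Aggregate one mouse's retained islet records into a MouseSummary.

    Means are over islets; totals over all of the mouse's sections.  Islets
    without counted beta cells are omitted from the beta-cell-size mean.
    With zero retained islets the summary carries ``n_islets=0`` and NaN
    derived fields.
    """
    if isinstance(records, list):
        df = pd.DataFrame([vars(r) for r in records])
    else:
        df = records.copy()
    if len(df) == 0:
        return MouseSummary(
            mouse_id=mouse_id, group=group, n_islets=0,
            mean_islet_area_um2=float("nan"), mean_feret_um=float("nan"),
            mean_circularity=float("nan"), mean_beta_area_um2=float("nan"),
            mean_alpha_area_um2=float("nan"), mean_beta_count=float("nan"),
            mean_beta_cell_size_um2=float("nan"),
            total_section_area_um2=total_section_area_um2,
            relative_islet_area_pct=float("nan"),
            relative_beta_area_pct=float("nan"),
            beta_cell_mass_g=float("nan"), islet_density_per_mm2=float("nan"),
            marker_pos_beta_pct=float("nan"),
        )
    tot_islet = float(df["area_um2"].sum())
    tot_beta = float(df["beta_area_um2"].sum())
    with_beta = df[df["beta_count"] >= 1]
    mass = (
        beta_cell_mass(tot_beta, total_section_area_um2, pancreas_spleen_weight_g)
        if pancreas_spleen_weight_g
        else float("nan")
    )
    n_marker_pos = float(df["marker_pos_beta"].sum())
    n_beta_tot = float(df["beta_count"].sum())
    return MouseSummary(
        mouse_id=mouse_id,
        group=group,
        n_islets=int(len(df)),
        mean_islet_area_um2=float(df["area_um2"].mean()),
        mean_feret_um=float(df["feret_um"].mean()),
        mean_circularity=float(df["circularity"].mean()),
        mean_beta_area_um2=float(df["beta_area_um2"].mean()),
        mean_alpha_area_um2=float(df["alpha_area_um2"].mean()),
        mean_beta_count=float(df["beta_count"].mean()),
        mean_beta_cell_size_um2=(
            float(with_beta["beta_cell_size_um2"].mean()) if len(with_beta) else float("nan")
        ),
        total_section_area_um2=total_section_area_um2,
        relative_islet_area_pct=relative_islet_area(tot_islet, total_section_area_um2),
        relative_beta_area_pct=relative_islet_area(tot_beta, total_section_area_um2),
        beta_cell_mass_g=mass,
        islet_density_per_mm2=islet_density(len(df), total_section_area_um2 / 1e6),
        marker_pos_beta_pct=(
            100.0 * n_marker_pos / n_beta_tot if n_beta_tot else float("nan")
        ),
    )


def summaries_to_frame(summaries: list[MouseSummary]) -> pd.DataFrame:
    """Stack MouseSummary records into a per-mouse DataFrame."""
    return pd.DataFrame([vars(s) for s in summaries])
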
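"""Shared fixtures: synthetic sections with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from isletmorph.config import AnalysisConfig
from isletmorph.segmentation import segment_section
from isletmorph.synthetic_data import (
    CONFOUNDER_KINDS,
    ConfounderSpec,
    SyntheticIsletSpec,
    islet_cell_capacity,
    render_section,
)


@pytest.fixture(scope="session")
def syn_config() -> AnalysisConfig:
    """Analysis configuration matched to the generator's fixed intensities."""
    return AnalysisConfig(threshold_method="fixed")


def make_islet_spec(
    area: float, ecc: float = 0.0, alpha_frac: float = 0.2, **kwargs
) -> SyntheticIsletSpec:
    """Islet blueprint at full lattice capacity for the requested area."""
    cap = islet_cell_capacity(area, ecc)
    n_alpha = round(alpha_frac * cap) if cap >= 4 else 0
    return SyntheticIsletSpec(
        center_um=(0.0, 0.0),
        target_area_um2=area,
        n_beta_cells=cap - n_alpha,
        n_alpha_cells=n_alpha,
        eccentricity=ecc,
        **kwargs,
    )


@pytest.fixture(scope="session")
def fixture_section():
    """One section: 3 valid islets plus one confounder of each of the 5 kinds."""
    islets = [make_islet_spec(a) for a in (900.0, 1800.0, 3200.0)]
    confounders = [ConfounderSpec(kind=k) for k in CONFOUNDER_KINDS]
    img, truth = render_section(
        islets,
        confounders,
        canvas_um=(800.0, 800.0),
        rng=np.random.default_rng(42),
    )
    return img, truth


@pytest.fixture(scope="session")
def segmented_fixture(fixture_section, syn_config):
    img, truth = fixture_section
    islets, excluded, masks, nuclei = segment_section(img, syn_config)
    return img, truth, islets, excluded, masks, nuclei
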
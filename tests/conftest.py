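"""Shared fixtures: small synthetic plates generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from netscan.imaging_io import PlateLayout, WellRole, WellSpec
from netscan.pipeline import analyze_fields
from netscan.synthplate import PhenotypeModel, TrueState, generate_field


def make_record(**kw):
    """CellRecord with innocuous defaults, overridable per test."""
    from netscan.features import CellRecord

    defaults = dict(
        object_id=1, well_id="A01", field_index=1, time_point_min=0.0,
        centroid_row=10.0, centroid_col=10.0, area_ch1_um2=40.0,
        target_area_ch2_um2=0.0, avg_intensity_ch2=0.0,
        avg_intensity_ch1=500.0, border=False,
    )
    defaults.update(kw)
    return CellRecord(**defaults)


@pytest.fixture(scope="session")
def small_model() -> PhenotypeModel:
    return PhenotypeModel(field_shape=(512, 512))


@pytest.fixture(scope="session")
def two_well_layout() -> PlateLayout:
    return PlateLayout(
        wells=[
            WellSpec("A01", "vehicle", 0.0, "", WellRole.CONTROL),
            WellSpec("A02", "PMA", 100.0, "nM", WellRole.STIMULATED),
        ],
        fields_per_well=1,
    )


@pytest.fixture(scope="session")
def small_plate(small_model, two_well_layout):
    """One control + one stimulated field with ground truth, analyzed."""
    stim_fr = {TrueState.LIVE: 0.6, TrueState.NET: 0.3, TrueState.NECROTIC: 0.1}
    ctrl_fr = {TrueState.LIVE: 0.95, TrueState.NET: 0.02, TrueState.NECROTIC: 0.03}
    f_stim, gt_stim = generate_field(
        120, stim_fr, small_model, seed=11, well_id="A02", field_index=1
    )
    f_ctrl, gt_ctrl = generate_field(
        120, ctrl_fr, small_model, seed=12, well_id="A01", field_index=1
    )
    result = analyze_fields([f_ctrl, f_stim], two_well_layout)
    return {
        "fields": {"A01": f_ctrl, "A02": f_stim},
        "truth": {"A01": gt_ctrl, "A02": gt_stim},
        "result": result,
        "model": small_model,
    }
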
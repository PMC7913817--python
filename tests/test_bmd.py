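"""Vertebral ROI placement and trabecular BMD measurement."""

import dataclasses

import numpy as np
import pytest

from opqct.bmd import (
    STATUS_MEASURED,
    STATUS_SKIPPED,
    BMDMeasurement,
    locate_midsagittal_slice,
    mean_l1_l3,
    measure_spine,
    measure_vertebral_bmd,
    place_roi,
    roi_voxel_indices,
)
from opqct.calibration import CalibrationModel, calibrate_scan
from opqct.errors import MeasurementError, PlacementError
from opqct.synth import generate_scan, identity_phantom, scaled_specs
from opqct.volume import LEVELS, ScanVolume, Tissue


def _meta_volume(center_x_mm: float, sx: float = 1.0) -> ScanVolume:
    data = np.zeros((130, 4, 4), dtype=np.float32)
    meta = {
        "levels": {
            "L1": {
                "center_mm": [center_x_mm, 2.0, 2.0],
                "height_mm": 30.0,
                "radius_lat_mm": 20.0,
                "radius_ap_mm": 25.0,
                "shell_mm": 2.5,
                "endplate_mm": 2.0,
                "plexus_radius_mm": 2.0,
                "plexus_y_start_mm": 2.0,
            }
        }
    }
    return ScanVolume(data=data, spacing=(sx, 1.0, 1.0), meta=meta)


def test_midsagittal_slice_at_voxel_center():
    assert locate_midsagittal_slice(_meta_volume(64.0), "L1") == 64


def test_midsagittal_tie_breaks_toward_lower_index():
    assert locate_midsagittal_slice(_meta_volume(63.5), "L1") == 63
    assert locate_midsagittal_slice(_meta_volume(63.6), "L1") == 64
    assert locate_midsagittal_slice(_meta_volume(63.4), "L1") == 63


def test_unknown_level_is_lookup_error(clean_scan):
    volume, _, _ = clean_scan
    with pytest.raises(MeasurementError, match="absent"):
        locate_midsagittal_slice(volume, "Th4")


def test_located_slices_match_ground_truth_centers(clean_scan):
    volume, _, _ = clean_scan
    sx = volume.spacing[0]
    for level in LEVELS:
        k = locate_midsagittal_slice(volume, level)
        true_x = volume.meta["levels"][level]["center_mm"][0]
        assert abs(k * sx - true_x) <= sx


def test_roi_diameter_is_two_thirds_height():
    roi = place_roi(_meta_volume(64.0), "L1")
    assert roi.diameter_mm == pytest.approx(20.0)
    assert not roi.shrunk


def test_roi_purity_against_ground_truth(clean_scan):
    """No ROI voxel is cortical, endplate or plexus on any of the 13 levels."""
    volume, truth, _ = clean_scan
    for level in LEVELS:
        roi = place_roi(volume, level)
        ix, iy, iz = roi_voxel_indices(volume, roi)
        labels = truth.label_mask[ix, iy, iz]
        assert (labels == Tissue.TRABECULAR).all(), (
            level,
            {Tissue(v).name for v in np.unique(labels)},
        )


def test_plexus_filled_body_raises_placement_error():
    vol = _meta_volume(64.0)
    vol.meta["levels"]["L1"]["plexus_y_start_mm"] = -30.0  # channel fills the body
    with pytest.raises(PlacementError, match="admissible"):
        place_roi(vol, "L1")


def test_identity_measurement_recovers_rendered_density(clean_scan):
    volume, truth, phantom = clean_scan
    model = calibrate_scan(volume, phantom)
    for level in ("Th5", "Th12", "L5"):
        m = measure_vertebral_bmd(volume, place_roi(volume, level), model)
        assert m.status == STATUS_MEASURED
        assert m.bmd == pytest.approx(truth.true_densities[level], abs=1e-3)
        assert m.voxel_count > 0


def test_calibrated_measurement_chains_conversion(clean_scan):
    """With the (0.9375, 31.25) line, a vertebra whose ROI mean HU is 150
    reads 0.9375*150 + 31.25."""
    volume, _, _ = clean_scan
    model = CalibrationModel(slope=0.9375, intercept=31.25)
    m = measure_vertebral_bmd(volume, place_roi(volume, "L2"), model)
    assert m.mean_hu == pytest.approx(150.0, abs=1e-3)
    assert m.bmd == pytest.approx(0.9375 * 150.0 + 31.25, abs=1e-2)


def test_measurement_invariant_to_internal_slope_change(specs):
    """Doubling the generator's slope (phantom re-rendered accordingly) leaves
    measured BMD unchanged: the phantom absorbs the scanner line."""
    geometry, body, phantom = specs
    densities = {lv: 150.0 for lv in LEVELS}
    doubled = dataclasses.replace(
        phantom, nominal_hu=tuple(h / 2.0 for h in phantom.nominal_hu)
    )
    results = []
    for ph in (phantom, doubled):
        vol, _ = generate_scan(geometry, body, ph, densities, noise_sd=0.0)
        model = calibrate_scan(vol, ph)
        m = measure_vertebral_bmd(vol, place_roi(vol, "Th8"), model)
        results.append(m.bmd)
    assert results[0] == pytest.approx(results[1], abs=1e-3)


def test_measure_spine_skips_prevalent_fractures(calibrated_noisy_scan):
    volume, _, model = calibrated_noisy_scan
    sm = measure_spine(volume, model, {"Th12"})
    assert len(sm.measurements) == 13
    assert [m.level for m in sm.measurements] == list(LEVELS)
    by_level = {m.level: m for m in sm.measurements}
    assert by_level["Th12"].status == STATUS_SKIPPED
    assert by_level["Th12"].bmd is None
    assert sum(m.status == STATUS_MEASURED for m in sm.measurements) == 12


@pytest.mark.parametrize(
    "bmds, expected, flag",
    [
        ({"L1": 120.0, "L2": 130.0, "L3": 110.0}, 120.0, "complete"),
        ({"L1": 120.0, "L3": 110.0}, 115.0, "partial"),
        ({}, None, "missing"),
    ],
)
def test_mean_l1_l3_handles_missing_members(bmds, expected, flag):
    ms = []
    for lv in ("L1", "L2", "L3"):
        if lv in bmds:
            ms.append(BMDMeasurement(level=lv, status=STATUS_MEASURED, bmd=bmds[lv]))
        else:
            ms.append(BMDMeasurement(level=lv, status=STATUS_SKIPPED))
    value, got_flag = mean_l1_l3(ms)
    assert got_flag == flag
    if expected is None:
        assert value is None
    else:
        assert value == pytest.approx(expected)


def test_measurements_unbiased_under_noise(specs):
    """Mean measured-minus-true over seeds shrinks toward zero per level."""
    geometry, body, phantom = specs
    densities = {lv: 150.0 for lv in LEVELS}
    errors = {lv: [] for lv in LEVELS}
    for seed in range(12):
        vol, truth = generate_scan(
            geometry, body, phantom, densities, noise_sd=20.0, seed=seed
        )
        model = calibrate_scan(vol, phantom)
        for m in measure_spine(vol, model).measurements:
            errors[m.level].append(m.bmd - truth.true_densities[m.level])
    for lv, errs in errors.items():
        assert abs(np.mean(errs)) < 3.0, lv
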
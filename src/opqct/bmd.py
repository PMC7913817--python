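"""Vertebral trabecular ROI densitometry.

For every level Th5-L5 a circular ROI is placed on the mid-sagittal slice of
the vertebral body: its diameter is standardised to two-thirds of the
vertebral height, its centre sits equidistant to both endplates at the
centroid of the anterior trabecular half, and it excludes the cortical shell,
the endplates and the basivertebral venous channel.  Mean HU over the ROI
(averaged over the native slices spanning a 3 mm sagittal reformation) is
converted to volumetric BMD via the per-scan calibration model.  Vertebrae
with a prevalent fracture are skipped, never measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationModel, hu_to_bmd
from .errors import MeasurementError, PlacementError
from .volume import LEVELS, ScanVolume

#: Sagittal reformation thickness the ROI mean is averaged over (mm).
REFORMATION_MM = 3.0
#: Safety margin (mm) between the ROI circle and every excluded structure,
#: absorbing voxel-centre discretisation of the boundaries.
FIT_MARGIN_MM = 0.75
#: Smallest ROI diameter (mm) the shrink-to-fit fallback will accept.
MIN_DIAMETER_MM = 4.0

STATUS_MEASURED = "measured"
STATUS_SKIPPED = "skipped-prevalent-fracture"
STATUS_FAILED = "failed"


@dataclass
class VertebraROI:
    """A placed circular ROI on the mid-sagittal plane of one vertebra."""

    level: str
    slice_index: int
    slice_indices: tuple[int, ...]      # native slices of the 3 mm reformation
    center_yz_mm: tuple[float, float]
    diameter_mm: float
    requested_diameter_mm: float
    shrunk: bool = False
    exclusions: tuple[str, ...] = ("cortical shell", "endplates", "venous plexus")


@dataclass
class BMDMeasurement:
    """Per-level trabecular BMD with ROI provenance."""

    level: str
    status: str
    mean_hu: float | None = None
    bmd: float | None = None
    voxel_count: int = 0
    roi: VertebraROI | None = None


@dataclass
class SpineMeasurement:
    """All 13 levels in anatomical order plus the QCT-standard L1-L3 mean."""

    measurements: list[BMDMeasurement]
    mean_l1_l3: float | None
    l1_l3_flag: str          # "complete" | "partial" | "missing"
    reproducibility_cv: dict[str, float] = field(default_factory=dict)


def _level_meta(volume: ScanVolume, level: str) -> dict:
    levels = volume.meta.get("levels", {})
    if level not in levels:
        raise MeasurementError(f"level {level!r} absent from scan metadata")
    return levels[level]


def locate_midsagittal_slice(volume: ScanVolume, level: str) -> int:
    """Index of the sagittal slice through the vertebral body centre.

    An exact tie between two slices is broken toward the lower index.
    """
    cx = _level_meta(volume, level)["center_mm"][0]
    return int(np.ceil(cx / volume.spacing[0] - 0.5))


def place_roi(volume: ScanVolume, level: str, slice_index: int | None = None) -> VertebraROI:
    """Place the two-thirds-of-height circular ROI for one vertebra.

    The circle lives in the (y, z) plane of the mid-sagittal slice: centre at
    mid-height (equidistant to both endplates) and at the centroid of the
    anterior half of the trabecular compartment.  If the standardised circle
    would touch the cortical shell, an endplate or the venous channel, it is
    shrunk to fit and the fallback recorded; if no acceptable circle exists a
    :class:`PlacementError` is raised.
    """
    m = _level_meta(volume, level)
    if slice_index is None:
        slice_index = locate_midsagittal_slice(volume, level)

    sx = volume.spacing[0]
    n_ref = max(1, int(round(REFORMATION_MM / sx)))
    start = slice_index - (n_ref - 1) // 2
    slice_indices = tuple(range(start, start + n_ref))
    if slice_indices[0] < 0 or slice_indices[-1] >= volume.shape[0]:
        raise PlacementError(f"{level}: sagittal reformation exceeds volume extent")

    vx, vy, vz = m["center_mm"]
    h = m["height_mm"]
    rl = m["radius_lat_mm"] - m["shell_mm"]      # trabecular lateral semi-axis
    ra = m["radius_ap_mm"] - m["shell_mm"]       # trabecular antero-posterior semi-axis

    # off-midline reformation slices see a slightly narrower trabecular ellipse
    dx_max = max(abs(k * sx - vx) for k in slice_indices)
    scale = np.sqrt(max(1.0 - (dx_max / rl) ** 2, 0.0)) if dx_max < rl else 0.0
    if scale <= 0:
        raise PlacementError(f"{level}: reformation slices fall outside the trabecular body")
    ra_eff = ra * scale

    requested_r = h / 3.0                         # two-thirds-of-height diameter
    y_lo = vy - ra_eff + FIT_MARGIN_MM            # anterior cortical bound
    y_hi_cortex = vy + ra_eff - FIT_MARGIN_MM
    y_hi_plexus = vy + m.get("plexus_y_start_mm", 2.0) - FIT_MARGIN_MM
    y_hi = min(y_hi_cortex, y_hi_plexus)
    z_half = h / 2.0 - m["endplate_mm"] - FIT_MARGIN_MM

    yc = vy - ra_eff / 2.0                        # anterior-half centroid
    zc = vz                                       # equidistant to both endplates
    r_fit = min(yc - y_lo, y_hi - yc, z_half)
    if r_fit < MIN_DIAMETER_MM / 2.0:
        raise PlacementError(
            f"{level}: no admissible ROI - the anterior trabecular compartment "
            f"(clear of shell, endplates and plexus) admits at most a "
            f"{max(2 * r_fit, 0):.1f} mm circle"
        )
    r = min(requested_r, r_fit)
    return VertebraROI(
        level=level,
        slice_index=int(slice_index),
        slice_indices=slice_indices,
        center_yz_mm=(float(yc), float(zc)),
        diameter_mm=float(2 * r),
        requested_diameter_mm=float(2 * requested_r),
        shrunk=bool(r < requested_r),
    )


def roi_voxel_indices(volume: ScanVolume, roi: VertebraROI):
    """Voxel indices ``(ix, iy, iz)`` covered by the ROI (voxel-centre rule)."""
    ys = volume.axis_coords(1)
    zs = volume.axis_coords(2)
    yc, zc = roi.center_yz_mm
    r = roi.diameter_mm / 2.0
    circ = (ys[:, None] - yc) ** 2 + (zs[None, :] - zc) ** 2 <= r**2
    iy, iz = np.nonzero(circ)
    k = len(roi.slice_indices)
    ix = np.repeat(np.asarray(roi.slice_indices, dtype=int), iy.size)
    return ix, np.tile(iy, k), np.tile(iz, k)


def measure_vertebral_bmd(
    volume: ScanVolume, roi: VertebraROI, model: CalibrationModel
) -> BMDMeasurement:
    """Mean ROI HU (over the 3 mm reformation) converted to BMD."""
    ix, iy, iz = roi_voxel_indices(volume, roi)
    if ix.size == 0:
        raise MeasurementError(f"{roi.level}: empty ROI at the current voxel spacing")
    mean_hu = float(volume.data[ix, iy, iz].mean())
    return BMDMeasurement(
        level=roi.level,
        status=STATUS_MEASURED,
        mean_hu=mean_hu,
        bmd=float(hu_to_bmd(model, mean_hu)),
        voxel_count=int(ix.size),
        roi=roi,
    )


def mean_l1_l3(measurements: list[BMDMeasurement]) -> tuple[float | None, str]:
    """QCT-standard mean BMD over the available L1, L2, L3 measurements.

    A level skipped for prevalent fracture (or failed) is left out and the
    mean over the remaining levels is flagged ``"partial"``; with no usable
    level the mean is ``None`` / ``"missing"``.
    """
    lumbar = [m for m in measurements if m.level in ("L1", "L2", "L3")]
    usable = [m.bmd for m in lumbar if m.status == STATUS_MEASURED and m.bmd is not None]
    if not usable:
        return None, "missing"
    flag = "complete" if len(usable) == 3 else "partial"
    return float(np.mean(usable)), flag


def measure_spine(
    volume: ScanVolume,
    model: CalibrationModel,
    prevalent_fractures: set[str] | frozenset[str] = frozenset(),
) -> SpineMeasurement:
    """Measure all 13 levels, skipping vertebrae with prevalent fractures."""
    unknown = set(prevalent_fractures) - set(LEVELS)
    if unknown:
        raise MeasurementError(f"unknown vertebral levels in fracture list: {sorted(unknown)}")
    out: list[BMDMeasurement] = []
    for level in LEVELS:
        if level in prevalent_fractures:
            out.append(BMDMeasurement(level=level, status=STATUS_SKIPPED))
            continue
        try:
            roi = place_roi(volume, level)
            out.append(measure_vertebral_bmd(volume, roi, model))
        except (PlacementError, MeasurementError):
            out.append(BMDMeasurement(level=level, status=STATUS_FAILED))
    mean13, flag = mean_l1_l3(out)
    return SpineMeasurement(measurements=out, mean_l1_l3=mean13, l1_l3_flag=flag)


def reproducibility_cv(
    geometry,
    body,
    phantom,
    true_densities,
    hu_offset: float = 0.0,
    noise_sd: float | None = None,
    n_repeats: int = 15,
    seed: int = 0,
    spacing=None,
) -> dict[str, float]:
    """Percent CV of repeated full re-measurements (new noise, new calibration).

    Regenerates the same anatomy ``n_repeats`` times with fresh noise, refits
    the calibration and re-measures every level; returns per-level
    ``100 * sd / mean`` of the BMD values.  This mirrors reported re-measurement
    reproducibility errors as a sanity band, not a hard gate.
    """
    from .calibration import calibrate_scan
    from .synth.scan import DEFAULT_NOISE_SD, DEFAULT_SPACING, generate_scan

    noise_sd = DEFAULT_NOISE_SD if noise_sd is None else noise_sd
    spacing = DEFAULT_SPACING if spacing is None else spacing
    values: dict[str, list[float]] = {lv: [] for lv in LEVELS}
    for i in range(n_repeats):
        vol, _ = generate_scan(
            geometry, body, phantom, true_densities,
            hu_offset=hu_offset, noise_sd=noise_sd, seed=seed + i, spacing=spacing,
        )
        model = calibrate_scan(vol, phantom)
        sm = measure_spine(vol, model)
        for m in sm.measurements:
            if m.status == STATUS_MEASURED:
                values[m.level].append(m.bmd)  # type: ignore[arg-type]
    return {
        lv: float(100.0 * np.std(v, ddof=1) / np.mean(v))
        for lv, v in values.items()
        if len(v) >= 2
    }
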
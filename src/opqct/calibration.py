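"""Synchronous per-scan HU-to-BMD calibration.

The two phases of the density reference phantom are sampled in cylindrical
ROIs and a linear conversion ``BMD = slope * HU + intercept`` is fit per scan.
With exactly two phases the fit interpolates both points; with more phases it
degenerates gracefully to ordinary least squares.  Because the phantom sits in
the table mat outside the vascular compartment, the fitted line is immune to
the contrast-enhancement HU offset applied to the anatomy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateFitError, SamplingError
from .synth.specs import PhantomSpec
from .volume import ScanVolume

#: Fraction of the phase radius kept when sampling (avoids the partial-volume rim).
PHASE_ROI_RADIUS_FRACTION = 0.8


@dataclass
class CalibrationModel:
    """Per-scan linear HU-to-BMD map: ``BMD = slope * HU + intercept``."""

    slope: float            # (mg/cm3) / HU
    intercept: float        # mg/cm3
    phase_samples: tuple[tuple[float, float], ...] = ()   # (mean HU, density)
    scan_id: str = ""

    def to_json(self, path: str | Path) -> None:
        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "phase_samples": [list(p) for p in self.phase_samples],
            "scan_id": self.scan_id,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            slope=float(payload["slope"]),
            intercept=float(payload["intercept"]),
            phase_samples=tuple((float(h), float(d)) for h, d in payload["phase_samples"]),
            scan_id=str(payload.get("scan_id", "")),
        )


def sample_phantom(
    volume: ScanVolume, phantom: PhantomSpec
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Sample mean HU in each phantom phase.

    The ROI per phase is a cylinder of 80% phase radius spanning the full
    phase length minus one voxel at each end, emulating central manual ROI
    placement away from partial-volume rims.  Returns the two
    ``(mean HU, known density)`` pairs ordered by density.

    Raises
    ------
    SamplingError
        if a phase footprint lies outside the volume or its eroded ROI is
        empty.
    """
    sx, sy, sz = volume.spacing
    nx, ny, nz = volume.shape
    xs = volume.axis_coords(0)
    ys = volume.axis_coords(1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    body_cx = volume.meta.get("body", {}).get("center_xy", (nx * sx / 2.0, 0.0))[0]
    pairs = []
    r = phantom.radius * PHASE_ROI_RADIUS_FRACTION
    k0, k1 = 1, nz - 1   # erode one voxel at each cylinder end
    if k1 <= k0:
        raise SamplingError("volume too short to erode the phantom phase ends")
    for i, off in enumerate(phantom.x_offsets):
        px, py = body_cx + off, phantom.y_center
        if not (0.0 <= px <= xs[-1] and 0.0 <= py <= ys[-1]):
            raise SamplingError(
                f"phantom phase {i + 1} at ({px:.1f}, {py:.1f}) mm lies outside the "
                f"volume footprint ({xs[-1]:.1f} x {ys[-1]:.1f} mm)"
            )
        roi2d = (X - px) ** 2 + (Y - py) ** 2 <= r**2
        if not roi2d.any():
            raise SamplingError(f"phantom phase {i + 1} ROI is empty after erosion")
        mean_hu = float(volume.data[:, :, k0:k1][roi2d].mean())
        pairs.append((mean_hu, phantom.densities[i]))
    pairs.sort(key=lambda p: p[1])
    return pairs[0], pairs[1]


def fit_calibration(
    pairs: Sequence[tuple[float, float]], scan_id: str = ""
) -> CalibrationModel:
    """Fit the linear HU-to-BMD conversion from (mean HU, density) pairs.

    Ordinary least squares; with exactly two pairs the line interpolates both
    exactly.

    Raises
    ------
    DegenerateFitError
        if fewer than two pairs are given, all phase HU coincide, or the
        fitted slope is not positive.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise DegenerateFitError("need at least two (HU, density) pairs")
    hu = np.array([p[0] for p in pairs], dtype=float)
    dens = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(hu) == 0:
        raise DegenerateFitError("identical HU in all phantom phases; cannot fit a line")
    if len(pairs) == 2:
        slope = (dens[1] - dens[0]) / (hu[1] - hu[0])
        intercept = dens[0] - slope * hu[0]
    else:
        slope, intercept = np.polyfit(hu, dens, 1)
    if slope <= 0:
        raise DegenerateFitError(f"non-positive calibration slope ({slope:.4g})")
    return CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        phase_samples=tuple((float(h), float(d)) for h, d in pairs),
        scan_id=scan_id,
    )


def calibrate_scan(volume: ScanVolume, phantom: PhantomSpec, scan_id: str = "") -> CalibrationModel:
    """Convenience wrapper: sample both phases and fit the line."""
    return fit_calibration(sample_phantom(volume, phantom), scan_id=scan_id)


def hu_to_bmd(model: CalibrationModel, hu):
    """Convert HU to volumetric BMD (mg/cm3); affine and order-preserving.

    Negative BMD values are permitted (they can arise from noise at very low
    densities) and are simply returned.
    """
    return model.slope * np.asarray(hu, dtype=float) + model.intercept
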
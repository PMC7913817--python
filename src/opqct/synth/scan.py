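"""Voxel-level synthetic CT generator with exact ground truth.

Renders a Th5-L5 spine inside an abdominal body cross-section together with a
two-phase density reference phantom, producing a HU volume plus a voxelwise
tissue-label mask.  Trabecular bone is rendered by inverting the
phantom-defined HU-to-density line, so synchronous calibration applied
downstream can recover true densities exactly in the noise-free case.  A
scan-wide additive HU offset emulates intravenous contrast enhancement: it is
applied to all anatomy but not to the phantom, which sits in the table mat
outside the vascular compartment.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np

from ..errors import GeometryError, ParameterError
from ..volume import LEVELS, ScanVolume, Tissue
from .specs import BodyCompositionSpec, PhantomSpec, SpineGeometry, default_spine_geometry

DEFAULT_SPACING: tuple[float, float, float] = (1.5, 1.5, 2.5)
#: Default additive HU noise, chosen to emulate trabecular-bone noise on a
#: 120 kVp / ~200 mAs routine abdominal MDCT protocol.
DEFAULT_NOISE_SD: float = 20.0


@dataclass
class GroundTruth:
    """Exact generator state: the oracle for every measurement stage."""

    true_densities: dict[str, float]
    label_mask: np.ndarray
    sat_volume_cm3: float
    vat_volume_cm3: float
    window: tuple[int, int, int, int, int]
    hu_offset: float
    noise_sd: float
    seed: int
    cal_slope: float
    cal_intercept: float

    def label_volume_cm3(self, label: Tissue, voxel_volume_mm3: float) -> float:
        return float(np.count_nonzero(self.label_mask == label)) * voxel_volume_mm3 / 1000.0


def default_true_densities() -> dict[str, float]:
    """Default per-level trabecular densities: the reference control means."""
    from ..reference import REFERENCE_BMD

    return {lv: REFERENCE_BMD[lv][0] for lv in LEVELS}


def _in_ellipse(X, Y, cx, cy, a, b):
    return ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0


def _axial_index(z_mm: float, sz: float) -> int:
    # nearest voxel, exact midpoints broken toward the lower index
    return int(np.ceil(z_mm / sz - 0.5))


def generate_scan(
    geometry: SpineGeometry | None = None,
    body: BodyCompositionSpec | None = None,
    phantom: PhantomSpec | None = None,
    true_densities: Mapping[str, float] | None = None,
    hu_offset: float = 0.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> tuple[ScanVolume, GroundTruth]:
    """Render a synthetic scan and its ground truth.

    Identical arguments (including ``seed``) produce bit-identical output.

    Raises
    ------
    GeometryError
        on overlapping anatomy or phantom-anatomy collision (the message
        names the colliding labels).
    ParameterError
        for negative ``noise_sd``.
    """
    geometry = geometry if geometry is not None else default_spine_geometry()
    body = body if body is not None else BodyCompositionSpec()
    phantom = phantom if phantom is not None else PhantomSpec()
    densities = dict(true_densities) if true_densities is not None else default_true_densities()

    geometry.validate()
    body.validate()
    phantom.validate()
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0 (got {noise_sd})")
    missing = [lv for lv in LEVELS if lv not in densities]
    if missing:
        raise ParameterError(f"missing true densities for levels: {missing}")

    sx, sy, sz = (float(s) for s in spacing)
    cx, cy = body.center_xy
    a, b = body.outer_semiaxes

    x_max = max(cx + a, cx + max(phantom.x_offsets) + phantom.radius) + 5.0
    y_max = max(cy + b, phantom.y_center + phantom.radius) + 5.0
    z_max = geometry.vertebrae[-1].z_bottom + 12.0
    nx, ny, nz = (int(np.floor(m / s)) + 1 for m, s in ((x_max, sx), (y_max, sy), (z_max, sz)))

    xs = np.arange(nx) * sx
    ys = np.arange(ny) * sy
    zs = np.arange(nz) * sz
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    # ---- abdominal cross-section (constant along z) -----------------------
    tc, ts, tm = body.cutis_thickness, body.sat_thickness, body.muscle_thickness
    body2d = _in_ellipse(X, Y, cx, cy, a, b)
    inner1 = _in_ellipse(X, Y, cx, cy, a - tc, b - tc)
    muscle_o = _in_ellipse(X, Y, cx, cy, a - tc - ts, b - tc - ts)
    muscle_i = _in_ellipse(X, Y, cx, cy, *body.inner_semiaxes)
    scx, scy = body.spine_center_xy
    pa, pb = body.paravertebral_semiaxes
    block2d = _in_ellipse(X, Y, scx, scy, pa, pb) & inner1
    organ2d = (
        _in_ellipse(
            X, Y, cx, cy + body.organ_offset_y, *body.organ_semiaxes
        )
        & muscle_i
    )

    lbl2d = np.zeros((nx, ny), dtype=np.uint8)
    lbl2d[inner1 & ~muscle_o] = Tissue.SAT
    lbl2d[muscle_o & ~muscle_i] = Tissue.MUSCLE
    lbl2d[muscle_i] = Tissue.VAT
    lbl2d[organ2d] = Tissue.ORGAN
    lbl2d[block2d] = Tissue.MUSCLE
    lbl2d[body2d & ~inner1] = Tissue.CUTIS

    # ---- phantom (full scan length, in the table mat) ---------------------
    phase2d = []
    for i, off in enumerate(phantom.x_offsets):
        ph = (X - (cx + off)) ** 2 + (Y - phantom.y_center) ** 2 <= phantom.radius**2
        if (ph & (lbl2d != 0)).any():
            hit = sorted({Tissue(v).name for v in np.unique(lbl2d[ph]) if v != 0})
            raise GeometryError(
                f"phantom phase {i + 1} intersects anatomy labels {hit}"
            )
        phase2d.append(ph)
        lbl2d[ph] = Tissue.PHANTOM_PHASE_1 if i == 0 else Tissue.PHANTOM_PHASE_2

    labels = np.repeat(lbl2d[:, :, None], nz, axis=2)

    # ---- vertebral bodies -------------------------------------------------
    for v in geometry.vertebrae:
        vx, vy, vz = v.center
        ell = _in_ellipse(X, Y, vx, vy, v.radius_lat, v.radius_ap)
        trab2d = _in_ellipse(X, Y, vx, vy, v.radius_lat - v.shell, v.radius_ap - v.shell)
        outside = ell & ~block2d
        if outside.any():
            hit = sorted({Tissue(t).name for t in np.unique(lbl2d[outside])})
            raise GeometryError(
                f"vertebra {v.label} extends outside the paravertebral compartment "
                f"into {hit}"
            )
        kz = np.nonzero(np.abs(zs - vz) <= v.height / 2.0)[0]
        if kz.size == 0:
            continue
        k0, k1 = int(kz[0]), int(kz[-1]) + 1
        sub = labels[:, :, k0:k1]                      # view
        dz = zs[k0:k1] - vz
        ep_z = np.abs(dz) > v.height / 2.0 - v.endplate
        sub[ell[:, :, None] & ep_z[None, None, :]] = Tissue.ENDPLATE
        in_z = ~ep_z
        sub[(ell & ~trab2d)[:, :, None] & in_z[None, None, :]] = Tissue.CORTICAL
        sub[trab2d[:, :, None] & in_z[None, None, :]] = Tissue.TRABECULAR
        plex = (
            (((X - vx) ** 2)[:, :, None] + (dz**2)[None, None, :] <= v.plexus_radius**2)
            & (Y >= vy + v.plexus_y_start)[:, :, None]
            & ell[:, :, None]
        )
        sub[plex] = Tissue.PLEXUS

    # ---- HU rendering -----------------------------------------------------
    lut = np.zeros(len(Tissue), dtype=np.float32)
    lut[Tissue.BACKGROUND] = -1000.0
    lut[Tissue.SAT] = body.adipose_hu
    lut[Tissue.VAT] = body.adipose_hu
    lut[Tissue.MUSCLE] = body.muscle_hu
    lut[Tissue.ORGAN] = body.organ_hu
    lut[Tissue.CUTIS] = body.cutis_hu
    bone_hu = phantom.density_to_hu(geometry.cortical_density)
    lut[Tissue.CORTICAL] = bone_hu
    lut[Tissue.ENDPLATE] = bone_hu
    lut[Tissue.PLEXUS] = geometry.plexus_hu
    lut[Tissue.PHANTOM_PHASE_1] = phantom.nominal_hu[0]
    lut[Tissue.PHANTOM_PHASE_2] = phantom.nominal_hu[1]

    hu = lut[labels]
    for v in geometry.vertebrae:
        kz = np.nonzero(np.abs(zs - v.center[2]) <= v.height / 2.0)[0]
        if kz.size == 0:
            continue
        k0, k1 = int(kz[0]), int(kz[-1]) + 1
        m = labels[:, :, k0:k1] == Tissue.TRABECULAR
        hu[:, :, k0:k1][m] = phantom.density_to_hu(densities[v.label])

    if hu_offset != 0.0:
        anat = (
            (labels != Tissue.BACKGROUND)
            & (labels != Tissue.PHANTOM_PHASE_1)
            & (labels != Tissue.PHANTOM_PHASE_2)
        )
        hu[anat] += np.float32(hu_offset)

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        hu = hu + rng.standard_normal(hu.shape, dtype=np.float32) * np.float32(noise_sd)

    # ---- ground truth -----------------------------------------------------
    k_disc = _axial_index(geometry.l45_disc_z, sz)
    window = tuple(range(k_disc - 2, k_disc + 3))
    voxvol = sx * sy * sz
    if 0 <= window[0] and window[-1] < nz:
        win_lbl = labels[:, :, window[0] : window[-1] + 1]
        sat_cm3 = float(np.count_nonzero(win_lbl == Tissue.SAT)) * voxvol / 1000.0
        vat_cm3 = float(np.count_nonzero(win_lbl == Tissue.VAT)) * voxvol / 1000.0
    else:  # pragma: no cover - default geometry always contains the window
        sat_cm3 = vat_cm3 = float("nan")

    meta = {
        "spacing": (sx, sy, sz),
        "seed": int(seed),
        "hu_offset": float(hu_offset),
        "noise_sd": float(noise_sd),
        "l45_disc_z_mm": float(geometry.l45_disc_z),
        "levels": {
            v.label: {
                "center_mm": list(v.center),
                "height_mm": v.height,
                "radius_lat_mm": v.radius_lat,
                "radius_ap_mm": v.radius_ap,
                "shell_mm": v.shell,
                "endplate_mm": v.endplate,
                "plexus_radius_mm": v.plexus_radius,
                "plexus_y_start_mm": v.plexus_y_start,
            }
            for v in geometry.vertebrae
        },
        "body": asdict(body),
        "phantom": asdict(phantom),
    }
    volume = ScanVolume(data=hu, spacing=(sx, sy, sz), meta=meta)
    truth = GroundTruth(
        true_densities=dict(densities),
        label_mask=labels,
        sat_volume_cm3=sat_cm3,
        vat_volume_cm3=vat_cm3,
        window=window,  # type: ignore[arg-type]
        hu_offset=float(hu_offset),
        noise_sd=float(noise_sd),
        seed=int(seed),
        cal_slope=phantom.slope,
        cal_intercept=phantom.intercept,
    )
    return volume, truth
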
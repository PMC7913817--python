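"""Parameter objects for the synthetic CT and cohort generators.

The synthetic scan emulates a contrast-enhanced thoraco-abdominal MDCT of the
Th5-L5 spine: elliptic-cylinder vertebral bodies with cortical shells, flat
endplates and a posterior basivertebral venous channel, embedded in an
abdominal cross-section with cutis, subcutaneous fat ring, muscle wall,
visceral fat and contrast-filled bowel, plus a two-phase density reference
phantom in the table mat under the back.  Everything is parameterised in
millimetres and Hounsfield units so downstream geometry rules (two-thirds-of
-height ROIs, border-based fat segmentation) can be exercised against exact
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..errors import GeometryError, ParameterError
from ..volume import LEVELS


@dataclass(frozen=True)
class VertebraSpec:
    """Geometry of one vertebral body (elliptic cylinder, axis cranio-caudal).

    ``center`` is the body centre in mm ``(x, y, z)``; ``radius_lat`` and
    ``radius_ap`` are the lateral / antero-posterior semi-axes; the cortical
    ``shell`` wraps the lateral boundary and the ``endplate`` slabs cap the
    cylinder; the venous ``plexus_radius`` channel runs antero-posteriorly
    through the posterior half at mid-height.
    """

    label: str
    center: tuple[float, float, float]
    height: float
    radius_lat: float
    radius_ap: float
    shell: float = 2.5
    endplate: float = 2.0
    plexus_radius: float = 2.0
    #: where the venous channel starts along y, relative to the body centre
    #: (positive = posterior half only; negative pushes it into the anterior body)
    plexus_y_start: float = 2.0

    def validate(self) -> None:
        if self.height <= 0:
            raise GeometryError(f"{self.label}: non-positive height")
        if self.shell >= min(self.radius_lat, self.radius_ap):
            raise GeometryError(f"{self.label}: cortical shell exceeds body radius")
        if self.endplate * 2 >= self.height:
            raise GeometryError(f"{self.label}: endplates exceed vertebral height")

    @property
    def z_top(self) -> float:
        return self.center[2] - self.height / 2.0

    @property
    def z_bottom(self) -> float:
        return self.center[2] + self.height / 2.0


@dataclass(frozen=True)
class SpineGeometry:
    """Thirteen vertebral bodies Th5..L5 in anatomical (cranio-caudal) order."""

    vertebrae: tuple[VertebraSpec, ...]
    gap: float = 4.0
    cortical_density: float = 650.0   # mg/cm3 rendered into shell + endplates
    plexus_hu: float = 150.0          # contrast-filled venous channel

    def validate(self) -> None:
        labels = tuple(v.label for v in self.vertebrae)
        if labels != LEVELS:
            raise GeometryError(
                f"spine must contain exactly the 13 levels {LEVELS} in order, got {labels}"
            )
        for v in self.vertebrae:
            v.validate()
        for a, b in zip(self.vertebrae, self.vertebrae[1:]):
            if a.z_bottom >= b.z_top:
                raise GeometryError(
                    f"vertebral bodies overlap: {a.label} (bottom {a.z_bottom:.1f} mm) "
                    f"and {b.label} (top {b.z_top:.1f} mm)"
                )

    def __getitem__(self, label: str) -> VertebraSpec:
        for v in self.vertebrae:
            if v.label == label:
                return v
        raise KeyError(label)

    @property
    def l45_disc_z(self) -> float:
        """Axial position (mm) of the L4/5 intervertebral disc plane."""
        return 0.5 * (self["L4"].z_bottom + self["L5"].z_top)


@dataclass(frozen=True)
class BodyCompositionSpec:
    """Abdominal soft-tissue compartments as nested ellipses.

    From outside in: cutis shell, subcutaneous fat (SAT) ring, muscle wall
    annulus, visceral compartment holding contrast-filled bowel/organ tissue
    and visceral fat (VAT).  A paravertebral muscle block (ellipse around the
    spine) closes the inner border posteriorly.  Adipose HU must lie strictly
    below muscle HU (this separation is what threshold segmentation exploits).
    """

    center_xy: tuple[float, float] = (120.0, 87.0)
    outer_semiaxes: tuple[float, float] = (115.0, 82.0)
    cutis_thickness: float = 2.5
    sat_thickness: float = 17.0
    muscle_thickness: float = 9.0
    spine_offset_y: float = 35.0                   # spine centre rel. body centre
    paravertebral_semiaxes: tuple[float, float] = (32.0, 30.0)
    organ_offset_y: float = -20.0
    organ_semiaxes: tuple[float, float] = (45.0, 28.0)
    adipose_hu: float = -100.0
    muscle_hu: float = 50.0
    organ_hu: float = 150.0                        # oral-contrast-filled bowel
    cutis_hu: float = 30.0

    def validate(self) -> None:
        if self.adipose_hu >= self.muscle_hu:
            raise GeometryError("adipose HU must be strictly below muscle HU")
        a, b = self.outer_semiaxes
        shrink = self.cutis_thickness + self.sat_thickness + self.muscle_thickness
        if shrink >= min(a, b):
            raise GeometryError("cutis+SAT+muscle thickness exceeds body radius")

    @property
    def spine_center_xy(self) -> tuple[float, float]:
        return (self.center_xy[0], self.center_xy[1] + self.spine_offset_y)

    @property
    def inner_semiaxes(self) -> tuple[float, float]:
        """Semi-axes of the inner border (inside of the muscle wall)."""
        a, b = self.outer_semiaxes
        s = self.cutis_thickness + self.sat_thickness + self.muscle_thickness
        return (a - s, b - s)

    @property
    def sat_cross_section_mm2(self) -> float:
        """Analytic SAT ring area per slice (ignores the paravertebral block)."""
        a, b = self.outer_semiaxes
        a1, b1 = a - self.cutis_thickness, b - self.cutis_thickness
        a2, b2 = a1 - self.sat_thickness, b1 - self.sat_thickness
        return float(np.pi * (a1 * b1 - a2 * b2))

    @property
    def vat_cross_section_mm2(self) -> float:
        """Analytic visceral-fat area per slice (inner region minus organ,
        ignoring the paravertebral block overlap)."""
        ai, bi = self.inner_semiaxes
        ao, bo = self.organ_semiaxes
        return float(np.pi * (ai * bi - ao * bo))


@dataclass(frozen=True)
class PhantomSpec:
    """Two-phase density reference phantom in the table mat under the back.

    Each phase is a cylinder (axis cranio-caudal, full scan length) of known
    density rendered at its nominal HU.  The two (nominal HU, density) points
    define the scanner's HU-to-density line; synchronous calibration must
    recover exactly this line.
    """

    densities: tuple[float, float] = (0.0, 200.0)     # mg/cm3
    nominal_hu: tuple[float, float] = (0.0, 160.0)
    y_center: float = 178.0
    x_offsets: tuple[float, float] = (-30.0, 30.0)    # rel. body centre x
    radius: float = 7.0

    def validate(self) -> None:
        if self.densities[0] == self.densities[1]:
            raise GeometryError("phantom phase densities must differ")
        if self.nominal_hu[0] == self.nominal_hu[1]:
            raise GeometryError("phantom phase nominal HU must differ")
        if self.radius <= 0:
            raise GeometryError("phantom radius must be positive")

    @property
    def slope(self) -> float:
        """Generator-internal calibration slope, (mg/cm3)/HU."""
        d1, d2 = self.densities
        h1, h2 = self.nominal_hu
        return (d2 - d1) / (h2 - h1)

    @property
    def intercept(self) -> float:
        """Generator-internal calibration intercept, mg/cm3."""
        return self.densities[0] - self.slope * self.nominal_hu[0]

    def density_to_hu(self, density):
        """Invert the phantom-defined line: HU a tissue of ``density`` renders at."""
        return (np.asarray(density, dtype=float) - self.intercept) / self.slope


def identity_phantom() -> PhantomSpec:
    """Phantom whose nominal HU numerically equal its phase densities
    (identity calibration line)."""
    return PhantomSpec(densities=(0.0, 200.0), nominal_hu=(0.0, 200.0))


def default_spine_geometry() -> SpineGeometry:
    """Reference spine: heights grow 22 -> 28 mm from Th5 to L5; the
    antero-posterior radius is sized so the two-thirds-of-height ROI circle
    fits inside the anterior trabecular half with margin."""
    shell = 2.5
    cx, cy = BodyCompositionSpec().spine_center_xy
    verts = []
    z = 12.0
    for i, label in enumerate(LEVELS):
        h = 22.0 + 0.5 * i
        ry = shell + 0.75 * h
        rx = 18.0 + i / 3.0
        verts.append(
            VertebraSpec(
                label=label,
                center=(cx, cy, z + h / 2.0),
                height=h,
                radius_lat=rx,
                radius_ap=ry,
                shell=shell,
            )
        )
        z += h + 4.0
    return SpineGeometry(vertebrae=tuple(verts))


def scaled_spine_geometry(scale: float) -> SpineGeometry:
    """Uniformly scaled spine (useful for small fast fixtures)."""
    base = default_spine_geometry()
    verts = tuple(
        replace(
            v,
            center=tuple(c * scale for c in v.center),
            height=v.height * scale,
            radius_lat=v.radius_lat * scale,
            radius_ap=v.radius_ap * scale,
            shell=v.shell * scale,
            endplate=v.endplate * scale,
            plexus_radius=v.plexus_radius * scale,
            plexus_y_start=v.plexus_y_start * scale,
        )
        for v in base.vertebrae
    )
    return replace(base, vertebrae=verts, gap=base.gap * scale)


def scaled_body(scale: float) -> BodyCompositionSpec:
    """Uniformly scaled abdominal cross-section."""
    base = BodyCompositionSpec()
    return replace(
        base,
        center_xy=tuple(c * scale for c in base.center_xy),
        outer_semiaxes=tuple(c * scale for c in base.outer_semiaxes),
        cutis_thickness=base.cutis_thickness * scale,
        sat_thickness=base.sat_thickness * scale,
        muscle_thickness=base.muscle_thickness * scale,
        spine_offset_y=base.spine_offset_y * scale,
        paravertebral_semiaxes=tuple(c * scale for c in base.paravertebral_semiaxes),
        organ_offset_y=base.organ_offset_y * scale,
        organ_semiaxes=tuple(c * scale for c in base.organ_semiaxes),
    )


def scaled_phantom(scale: float) -> PhantomSpec:
    """Phantom repositioned for a uniformly scaled body (densities unchanged)."""
    base = PhantomSpec()
    return replace(
        base,
        y_center=base.y_center * scale,
        x_offsets=tuple(c * scale for c in base.x_offsets),
        radius=max(base.radius * scale, 4.0),
    )


def scaled_specs(scale: float) -> tuple["SpineGeometry", BodyCompositionSpec, PhantomSpec]:
    """Consistently scaled (geometry, body, phantom) triple for fast volumes."""
    if scale == 1.0:
        return default_spine_geometry(), BodyCompositionSpec(), PhantomSpec()
    return scaled_spine_geometry(scale), scaled_body(scale), scaled_phantom(scale)


# ---------------------------------------------------------------------------
# Cohort parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupStats:
    """Mean and SD of one variable in one group."""

    mean: float
    sd: float

    def validate(self, name: str) -> None:
        if self.sd <= 0:
            raise ParameterError(f"{name}: SD must be positive (got {self.sd})")


@dataclass(frozen=True)
class CohortParams:
    """Group-level parameters of the synthetic matched case-control cohort.

    ``bmd`` maps each vertebral level to ``(control, fracture)`` group stats
    (mg/cm3, Gaussian within group with exchangeable inter-level correlation
    ``rho``); ``vat`` and ``sat`` are cm3 volumes drawn from zero-truncated
    Gaussians (their SDs are of the same order as the means).  Age (years)
    and follow-up (months) are drawn per matched pair so pairs match on both.
    """

    bmd: dict[str, tuple[GroupStats, GroupStats]]
    vat: tuple[GroupStats, GroupStats]
    sat: tuple[GroupStats, GroupStats]
    n_per_group: int = 17
    rho: float = 0.7
    age: GroupStats = field(default_factory=lambda: GroupStats(66.3, 9.0))
    followup_months: GroupStats = field(default_factory=lambda: GroupStats(21.4, 11.5))

    def validate(self) -> None:
        if self.n_per_group <= 0:
            raise ParameterError(f"n_per_group must be positive (got {self.n_per_group})")
        if not 0.0 <= self.rho < 1.0:
            raise ParameterError(f"rho must be in [0, 1) (got {self.rho})")
        missing = [lv for lv in LEVELS if lv not in self.bmd]
        if missing:
            raise ParameterError(f"missing BMD parameters for levels: {missing}")
        for lv, (c, f) in self.bmd.items():
            c.validate(f"{lv} control")
            f.validate(f"{lv} fracture")
        for name, (c, f) in (("VAT", self.vat), ("SAT", self.sat)):
            c.validate(f"{name} control")
            f.validate(f"{name} fracture")
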
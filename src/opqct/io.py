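"""File I/O: NIfTI volumes with JSON sidecars, cohort CSVs, report files.

Volumes are written as NIfTI-1 (.nii.gz) with a diagonal affine carrying the
voxel spacing (right-handed, axes sagittal/coronal/axial as documented in
:mod:`opqct.volume`).  Scan metadata and ground truth travel in a JSON sidecar
next to the image; ground-truth label masks are a second NIfTI.  Cohorts are
RFC-4180 CSVs with the documented header; missing cells parse as missing,
never as zero.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError
from .synth.cohort import COHORT_COLUMNS
from .synth.scan import GroundTruth
from .volume import ScanVolume


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _labels_path(path: Path) -> Path:
    side = _sidecar(path)
    return side.with_name(side.stem + "_labels.nii.gz")


def save_scan(volume: ScanVolume, path: str | Path, truth: GroundTruth | None = None) -> Path:
    """Write a scan (and optionally its ground truth) to ``path``.

    Produces ``<stem>.nii.gz``, a ``<stem>.json`` sidecar echoing all
    generator settings, and (if truth is given) ``<stem>_labels.nii.gz``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*volume.spacing, 1.0])
    nib.save(nib.Nifti1Image(volume.data, affine), str(path))
    sidecar: dict = {"spacing": list(volume.spacing), "meta": volume.meta}
    if truth is not None:
        sidecar["ground_truth"] = {
            "true_densities": truth.true_densities,
            "sat_volume_cm3": truth.sat_volume_cm3,
            "vat_volume_cm3": truth.vat_volume_cm3,
            "window": list(truth.window),
            "hu_offset": truth.hu_offset,
            "noise_sd": truth.noise_sd,
            "seed": truth.seed,
            "cal_slope": truth.cal_slope,
            "cal_intercept": truth.cal_intercept,
        }
        nib.save(nib.Nifti1Image(truth.label_mask.astype(np.uint8), affine), str(_labels_path(path)))
    _sidecar(path).write_text(json.dumps(sidecar, indent=2))
    return path


def load_scan(path: str | Path) -> ScanVolume:
    """Read a scan written by :func:`save_scan` (spacing preserved exactly)."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    side = _sidecar(path)
    if side.exists():
        payload = json.loads(side.read_text())
        spacing = tuple(payload["spacing"])
        meta = payload.get("meta", {})
    else:
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        meta = {}
    return ScanVolume(data=data, spacing=spacing, meta=meta)


def load_truth_sidecar(path: str | Path) -> dict:
    """Ground-truth section of a scan sidecar (raises FormatError if absent)."""
    payload = json.loads(_sidecar(Path(path)).read_text())
    if "ground_truth" not in payload:
        raise FormatError("sidecar has no 'ground_truth' field")
    return payload["ground_truth"]


def save_cohort(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV; missing cells become NaN, never zero."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort CSV is missing required columns: {missing}")
    return df


def save_measurements(spine_measurement, path: str | Path) -> Path:
    """Per-scan BMD table: level, meanHU, BMD, voxel count, status."""
    rows = [
        {
            "level": m.level,
            "mean_hu": m.mean_hu,
            "bmd_mg_cm3": m.bmd,
            "voxel_count": m.voxel_count,
            "status": m.status,
            "roi_diameter_mm": m.roi.diameter_mm if m.roi else None,
            "roi_shrunk": m.roi.shrunk if m.roi else None,
        }
        for m in spine_measurement.measurements
    ]
    rows.append(
        {
            "level": "L1-L3",
            "mean_hu": None,
            "bmd_mg_cm3": spine_measurement.mean_l1_l3,
            "voxel_count": 0,
            "status": spine_measurement.l1_l3_flag,
            "roi_diameter_mm": None,
            "roi_shrunk": None,
        }
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def save_report(report, out_dir: str | Path) -> dict[str, Path]:
    """Write the statistical report as CSVs plus a human-readable text table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "group_summary": out / "group_summary.csv",
        "discrimination": out / "discrimination.csv",
        "correlations": out / "correlations.csv",
        "stepwise": out / "stepwise.csv",
        "report_txt": out / "report.txt",
    }
    report.group_summary.to_csv(paths["group_summary"], index=False)
    report.discrimination.to_csv(paths["discrimination"], index=False)
    report.correlations.to_csv(paths["correlations"])
    pd.DataFrame(
        [
            {
                "variable": e.variable,
                "entry_p": e.entry_p,
                "coef": e.coef,
                "odds_ratio_per_sd_decrease": e.odds_ratio,
                "ci_low": e.ci[0],
                "ci_high": e.ci[1],
                "wald_p": e.wald_p,
            }
            for e in report.stepwise.entered
        ]
    ).to_csv(paths["stepwise"], index=False)

    lines = ["Group summary (mean +/- SD, Wilcoxon signed-rank p)", "-" * 60]
    for _, r in report.group_summary.iterrows():
        lines.append(
            f"{r['variable']:>8}  control {r['control_mean']:8.1f} +/- {r['control_sd']:6.1f}"
            f"   fracture {r['fracture_mean']:8.1f} +/- {r['fracture_sd']:6.1f}"
            f"   p={r['wilcoxon_p']:.3f}"
        )
    lines += ["", "Discrimination (OR per SD decrease, AUC +/- SE, p vs 0.5)", "-" * 60]
    for _, r in report.discrimination.iterrows():
        lines.append(
            f"{r['variable']:>8}  OR {r['or_text']:>6}   AUC {r['auc']:.3f} "
            f"+/- {r['auc_se']:.3f}   p={r['auc_p']:.3f}"
        )
    lines += ["", "Stepwise logistic model (entry p < %.2f)" % report.stepwise.p_enter, "-" * 60]
    if report.stepwise.entered:
        for e in report.stepwise.entered:
            lines.append(
                f"{e.variable:>8}  OR {e.odds_ratio:.2f} per SD decrease "
                f"(95% CI {e.ci[0]:.2f}-{e.ci[1]:.2f}), Wald p={e.wald_p:.4f}"
            )
    else:
        lines.append("(no predictor entered)")
    paths["report_txt"].write_text("\n".join(lines) + "\n")
    return paths
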
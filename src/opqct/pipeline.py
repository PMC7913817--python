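"""End-to-end orchestration: simulate, calibrate, measure, segment, analyze.

A run is fully described by a :class:`RunConfig` (loadable from YAML or JSON);
every defaulted field is echoed into the run manifest together with a config
hash, the seed and package versions, so a manifest suffices to reproduce any
run.  Identical config + seed produces byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import calibrate_scan
from .bmd import measure_spine
from .errors import OpqctError, PipelineStageError
from .fat import ADIPOSE_HU_RANGE, measure_fat
from .io import save_cohort, save_measurements, save_report, save_scan
from .reference import reference_cohort_params
from .stats import build_report
from .synth.scan import DEFAULT_NOISE_SD, DEFAULT_SPACING, generate_scan
from .synth.specs import PhantomSpec, scaled_specs
from .synth.cohort import generate_cohort
from .volume import LEVELS

logger = logging.getLogger("opqct")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (all fields have defaults)."""

    seed: int = 0
    out_dir: str = "opqct_run"
    n_scans: int = 1
    noise_sd: float = DEFAULT_NOISE_SD
    hu_offset: float = 35.0                  # contrast-enhancement HU drift
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    scale: float = 1.0                       # uniform anatomy scale (fast demos)
    phantom: dict | None = None              # overrides for PhantomSpec fields
    prevalent_fractures: tuple[str, ...] = ()
    adipose_hu_range: tuple[float, float] = ADIPOSE_HU_RANGE
    n_per_group: int = 17
    rho: float = 0.7
    p_enter: float = 0.05
    verbosity: str = "info"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise PipelineStageError("config", f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**payload)
        for name in ("spacing", "prevalent_fractures", "adipose_hu_range"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _phantom_from_config(config: RunConfig) -> PhantomSpec:
    geometry, body, phantom = scaled_specs(config.scale)
    if config.phantom is not None:
        if not isinstance(config.phantom, dict):
            raise PipelineStageError(
                "simulate-scan", f"phantom spec must be a mapping, got {type(config.phantom).__name__}"
            )
        try:
            overrides = {
                k: tuple(v) if isinstance(v, list) else v for k, v in config.phantom.items()
            }
            phantom = dataclasses.replace(phantom, **overrides)
        except TypeError as exc:
            raise PipelineStageError("simulate-scan", f"invalid phantom spec: {exc}") from exc
    return phantom


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> calibrate -> measure -> segment -> analyze.

    Returns the run manifest (also written to ``<out_dir>/manifest.json``).
    Any stage failure propagates as :class:`PipelineStageError` naming the
    stage.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    geometry, body, _ = scaled_specs(config.scale)
    phantom = _phantom_from_config(config)

    artifacts: list[str] = []
    scan_rows = []
    for i in range(config.n_scans):
        scan_id = f"scan{i + 1:03d}"
        stage = "simulate-scan"
        try:
            densities = {
                lv: max(float(rng.normal(m, 15.0)), 30.0)
                for lv, m in _reference_density_means().items()
            }
            volume, truth = generate_scan(
                geometry, body, phantom, densities,
                hu_offset=config.hu_offset, noise_sd=config.noise_sd,
                seed=int(rng.integers(2**31 - 1)), spacing=config.spacing,
            )
            scan_path = save_scan(volume, out / f"{scan_id}.nii.gz", truth)
            artifacts.append(str(scan_path))
        except OpqctError as exc:
            raise PipelineStageError(stage, f"{scan_id}: {exc}") from exc

        stage = "calibrate"
        try:
            model = calibrate_scan(volume, phantom, scan_id=scan_id)
            model_path = out / f"{scan_id}_calibration.json"
            model.to_json(model_path)
            artifacts.append(str(model_path))
        except OpqctError as exc:
            raise PipelineStageError(stage, f"{scan_id}: {exc}") from exc

        stage = "measure-bmd"
        try:
            sm = measure_spine(volume, model, set(config.prevalent_fractures))
            bmd_path = save_measurements(sm, out / f"{scan_id}_bmd.csv")
            artifacts.append(str(bmd_path))
        except OpqctError as exc:
            raise PipelineStageError(stage, f"{scan_id}: {exc}") from exc

        stage = "segment-fat"
        try:
            fat = measure_fat(volume, adipose_range=config.adipose_hu_range)
        except OpqctError as exc:
            raise PipelineStageError(stage, f"{scan_id}: {exc}") from exc

        measured = {m.level: m.bmd for m in sm.measurements if m.bmd is not None}
        scan_rows.append(
            {
                "scan_id": scan_id,
                **{f"bmd_{lv.lower()}": measured.get(lv) for lv in LEVELS},
                "bmd_l1_l3": sm.mean_l1_l3,
                "sat_cm3": fat.sat_cm3,
                "vat_cm3": fat.vat_cm3,
                "vat_sat_ratio": fat.vat_sat_ratio,
                "true_sat_cm3": truth.sat_volume_cm3,
                "true_vat_cm3": truth.vat_volume_cm3,
            }
        )
    if scan_rows:
        scans_path = out / "scan_measurements.csv"
        pd.DataFrame(scan_rows).to_csv(scans_path, index=False)
        artifacts.append(str(scans_path))

    stage = "simulate-cohort"
    try:
        params = reference_cohort_params(n_per_group=config.n_per_group, rho=config.rho)
        cohort = generate_cohort(params, seed=config.seed)
        cohort_path = save_cohort(cohort, out / "cohort.csv")
        artifacts.append(str(cohort_path))
    except OpqctError as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    stage = "analyze"
    try:
        report = build_report(cohort, p_enter=config.p_enter)
        report_paths = save_report(report, out / "report")
        artifacts.extend(str(p) for p in report_paths.values())
    except OpqctError as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    manifest = {
        "package": "opqct",
        "version": __version__,
        "config": config.as_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "versions": _library_versions(),
        "artifacts": sorted(artifacts),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return manifest


def _reference_density_means() -> dict[str, float]:
    from .reference import REFERENCE_BMD

    return {lv: REFERENCE_BMD[lv][0] for lv in LEVELS}


def _library_versions() -> dict[str, str]:
    import nibabel
    import scipy
    import skimage
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-image": skimage.__version__,
        "nibabel": nibabel.__version__,
        "statsmodels": statsmodels.__version__,
    }
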
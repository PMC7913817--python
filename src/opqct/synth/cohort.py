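"""Scalar matched case-control cohort generator.

Subjects are drawn per matched pair: age and follow-up duration are shared
within a pair (plus a small matching jitter), mirroring an age-, sex- and
follow-up-matched design.  Per-level trabecular BMD is multivariate Gaussian
within each group with an exchangeable inter-level correlation; SAT and VAT
volumes are zero-truncated Gaussians (their SDs are of the same order as the
means, so an untruncated Gaussian would produce negative volumes).  The
per-subject VAT/SAT ratio and the QCT-standard mean over L1-L3 are computed
from the simulated values, never drawn separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from ..errors import ParameterError
from ..volume import LEVELS
from .specs import CohortParams, GroupStats

#: Column order of the cohort table (the CSV header contract).
COHORT_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "pair_id",
    "group",
    "age",
    "followup_months",
    *(f"bmd_{lv.lower()}" for lv in LEVELS),
    "bmd_l1_l3",
    "vat_cm3",
    "sat_cm3",
    "vat_sat_ratio",
)


def bmd_column(level: str) -> str:
    """CSV column name for one vertebral level."""
    return f"bmd_{level.lower()}"


def _truncated_normal(stats: GroupStats, n: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated Gaussian draws via the inverse-CDF method."""
    alpha = (0.0 - stats.mean) / stats.sd
    u = rng.uniform(sps.norm.cdf(alpha), 1.0, size=n)
    return stats.mean + stats.sd * sps.norm.ppf(u)


def truncated_normal_mean(stats: GroupStats) -> float:
    """Analytic mean of the zero-truncated Gaussian (test oracle)."""
    alpha = (0.0 - stats.mean) / stats.sd
    lam = sps.norm.pdf(alpha) / sps.norm.sf(alpha)
    return stats.mean + stats.sd * lam


def _group_bmd(
    params: CohortParams, group: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    means = np.array([params.bmd[lv][group].mean for lv in LEVELS])
    sds = np.array([params.bmd[lv][group].sd for lv in LEVELS])
    k = len(LEVELS)
    corr = np.full((k, k), params.rho)
    np.fill_diagonal(corr, 1.0)
    z = rng.multivariate_normal(np.zeros(k), corr, size=n, method="cholesky")
    return means + z * sds


def generate_cohort(params: CohortParams, seed: int = 0) -> pd.DataFrame:
    """Generate one matched case-control cohort table.

    Returns a DataFrame with :data:`COHORT_COLUMNS`; pair ids form a perfect
    1:1 matching across groups (control subject ``C<i>`` matched to fracture
    subject ``F<i>`` by ``pair_id`` ``i``).  Seed-reproducible.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.n_per_group

    pair_age = rng.normal(params.age.mean, params.age.sd, size=n)
    pair_fu = np.maximum(
        rng.normal(params.followup_months.mean, params.followup_months.sd, size=n), 6.0
    )

    rows = []
    bmd = {0: _group_bmd(params, 0, n, rng), 1: _group_bmd(params, 1, n, rng)}
    vat = {g: _truncated_normal(params.vat[g], n, rng) for g in (0, 1)}
    sat = {g: _truncated_normal(params.sat[g], n, rng) for g in (0, 1)}
    jitter = {g: rng.normal(0.0, 1.0, size=n) for g in (0, 1)}

    for g, prefix in ((0, "C"), (1, "F")):
        for i in range(n):
            rec: dict[str, object] = {
                "subject_id": f"{prefix}{i + 1:03d}",
                "pair_id": i + 1,
                "group": g,
                "age": pair_age[i] + jitter[g][i],
                "followup_months": pair_fu[i],
            }
            levels = bmd[g][i]
            for j, lv in enumerate(LEVELS):
                rec[bmd_column(lv)] = levels[j]
            l13 = [levels[LEVELS.index(x)] for x in ("L1", "L2", "L3")]
            rec["bmd_l1_l3"] = float(np.mean(l13))
            v, s = float(vat[g][i]), float(sat[g][i])
            rec["vat_cm3"] = v
            rec["sat_cm3"] = s
            rec["vat_sat_ratio"] = v / s if s > 0 else np.nan
            rows.append(rec)

    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return df


def validate_cohort(df: pd.DataFrame) -> None:
    """Check the cohort-table invariants (columns, perfect 1:1 matching)."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"cohort table is missing columns: {missing}")
    ctrl = set(df.loc[df["group"] == 0, "pair_id"])
    frac = set(df.loc[df["group"] == 1, "pair_id"])
    if ctrl != frac or len(ctrl) != (df["group"] == 0).sum():
        raise ParameterError("pair ids do not form a perfect 1:1 matching")
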
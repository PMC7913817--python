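"""Matched case-control statistics for fracture-risk discrimination.

The battery mirrors a matched case-control analysis at two-sided alpha 0.05
with no multiplicity correction: Wilcoxon signed-rank comparison on matched
pairs, Spearman correlations, nonparametric ROC analysis (Mann-Whitney AUC
with Hanley-McNeil standard error), univariate odds ratios per SD decrease
from logistic regression, and forward stepwise multivariate logistic
regression with score-test entry at p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import MatchingError, ParameterError
from .synth.cohort import bmd_column, validate_cohort
from .volume import LEVELS

LOWER = "lower_indicates_case"
HIGHER = "higher_indicates_case"

#: Report variables in output order: 13 levels, the QCT standard, fat measures.
REPORT_VARIABLES: tuple[str, ...] = (*LEVELS, "L1-L3", "VAT", "SAT", "VAT/SAT")

_VARIABLE_COLUMNS: dict[str, str] = {
    **{lv: bmd_column(lv) for lv in LEVELS},
    "L1-L3": "bmd_l1_l3",
    "VAT": "vat_cm3",
    "SAT": "sat_cm3",
    "VAT/SAT": "vat_sat_ratio",
}

#: BMD is protective (lower value indicates a case); adiposity measures are
#: oriented the other way. Orientation is always recorded in the output.
DEFAULT_ORIENTATIONS: dict[str, str] = {
    **{lv: LOWER for lv in LEVELS},
    "L1-L3": LOWER,
    "VAT": HIGHER,
    "SAT": HIGHER,
    "VAT/SAT": HIGHER,
}


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    w_plus: float
    w_minus: float
    p: float
    n_used: int
    n_zero_dropped: int
    method: str                  # "exact" | "normal" | "degenerate"

    @property
    def statistic(self) -> float:
        """Conventional test statistic: the smaller of the two rank sums."""
        return min(self.w_plus, self.w_minus)


#: exact null distribution by convolution up to this many nonzero pairs
EXACT_WILCOXON_N = 25


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p over all 2^n sign assignments (convolution over
    doubled mid-ranks, which are integers even under ties)."""
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= 2.0 ** len(r2)
    w2 = int(np.rint(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(diffs) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (documented behaviour).  The null
    distribution is exact (full enumeration via convolution) for up to 25
    nonzero pairs; beyond that a normal approximation with tie and continuity
    corrections is used.  All differences zero yields a degenerate, flagged
    result with p = 1.
    """
    d_all = np.atleast_1d(np.asarray(diffs, dtype=float))
    d_all = d_all[~np.isnan(d_all)]
    n_zero = int((d_all == 0).sum())
    d = d_all[d_all != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 0.0, 1.0, 0, n_zero, "degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    if n <= EXACT_WILCOXON_N:
        p = _exact_signed_rank_p(w_plus, ranks)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        tie_term = sum(t**3 - t for t in np.bincount(np.rint(2 * ranks).astype(int)) if t > 1)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
        method = "normal"
    return WilcoxonResult(w_plus, w_minus, p, int(n), n_zero, method)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    variables: tuple[str, str]
    r: float
    p: float
    n: int
    undefined: bool = False


def spearman(x, y, names: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Spearman rank correlation (Pearson of mid-ranks, t-approximation p).

    Requires at least three complete pairs; a constant input gives an
    undefined-flagged result (r and p are NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ParameterError("Spearman correlation needs at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(names, float("nan"), float("nan"), int(x.size), undefined=True)
    r, p = sps.spearmanr(x, y)
    return CorrelationResult(names, float(r), float(p), int(x.size))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    variable: str
    auc: float
    se: float                    # Hanley-McNeil SE at the observed AUC
    p: float                     # normal test of AUC vs 0.5 (null-variance SE)
    orientation: str
    n_controls: int
    n_cases: int


def _mann_whitney_auc(control: np.ndarray, case: np.ndarray) -> float:
    """AUC as the Mann-Whitney pair statistic: fraction of (case, control)
    pairs correctly ordered, ties counting one half."""
    combined = np.concatenate([case, control])
    ranks = sps.rankdata(combined)
    n1, n0 = case.size, control.size
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def hanley_mcneil_se(auc: float, n_cases: int, n_controls: int) -> float:
    """Standard error of a nonparametric AUC (Hanley & McNeil)."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_cases - 1) * (q1 - auc**2)
        + (n_controls - 1) * (q2 - auc**2)
    ) / (n_cases * n_controls)
    return float(np.sqrt(max(var, 0.0)))


def roc_auc(control_values, case_values, orientation: str = LOWER, variable: str = "") -> ROCResult:
    """Nonparametric ROC analysis of one candidate predictor.

    Under ``lower_indicates_case`` orientation the AUC is the probability that
    a random case has the *lower* value of a random case-control pair (ties
    one half).  The p-value tests AUC = 0.5 with the null-hypothesis variance
    ``(n0 + n1 + 1) / (12 n0 n1)``; the reported SE is Hanley-McNeil at the
    observed AUC.
    """
    control = np.asarray(control_values, dtype=float)
    case = np.asarray(case_values, dtype=float)
    control = control[~np.isnan(control)]
    case = case[~np.isnan(case)]
    if control.size == 0 or case.size == 0:
        raise ParameterError("both groups must be non-empty for ROC analysis")
    if orientation not in (LOWER, HIGHER):
        raise ParameterError(f"unknown orientation {orientation!r}")
    sgn = -1.0 if orientation == LOWER else 1.0
    auc = _mann_whitney_auc(sgn * control, sgn * case)
    n0, n1 = control.size, case.size
    se = hanley_mcneil_se(auc, n1, n0)
    se0 = np.sqrt((n0 + n1 + 1) / (12.0 * n0 * n1))
    p = float(2 * sps.norm.sf(abs(auc - 0.5) / se0))
    return ROCResult(variable, auc, se, p, orientation, n0, n1)


# ---------------------------------------------------------------------------
# Odds ratios per SD decrease
# ---------------------------------------------------------------------------

@dataclass
class OddsRatioResult:
    variable: str
    odds_ratio: float            # per SD decrease (or increase, per orientation)
    ci: tuple[float, float]
    p: float
    scaling_sd: float
    orientation: str
    separated: bool = False      # complete separation: CI is (0, inf)


def _oriented_z(values: np.ndarray, orientation: str, sd: float | None) -> tuple[np.ndarray, float]:
    mean = float(np.mean(values))
    scale = float(np.std(values, ddof=1)) if sd is None else float(sd)
    if scale <= 0:
        raise ParameterError("predictor SD must be positive")
    z = (mean - values) / scale if orientation == LOWER else (values - mean) / scale
    return z, scale


def or_per_sd(
    values, status, orientation: str = LOWER, sd: float | None = None, variable: str = ""
) -> OddsRatioResult:
    """Univariate logistic odds ratio per SD change of the predictor.

    The predictor is standardised with the pooled-sample SD (configurable) and
    sign-flipped under ``lower_indicates_case`` so the reported OR is per SD
    *decrease*.  Complete separation yields a flagged result with an infinite
    confidence interval.
    """
    values = np.asarray(values, dtype=float)
    status = np.asarray(status, dtype=float)
    keep = ~np.isnan(values)
    values, status = values[keep], status[keep]
    if len(np.unique(status)) < 2:
        raise ParameterError("both case and control status must be present")
    z, scale = _oriented_z(values, orientation, sd)
    X = sm.add_constant(z)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(status, X).fit(disp=0, maxiter=200)
        beta = float(res.params[1])
        se = float(res.bse[1])
        if not np.isfinite(se) or se > 50:
            raise RuntimeError("separation")
        p = float(res.pvalues[1])
        ci = (float(np.exp(beta - 1.959963984540054 * se)),
              float(np.exp(beta + 1.959963984540054 * se)))
        return OddsRatioResult(variable, float(np.exp(beta)), ci, p, scale, orientation)
    except Exception:
        return OddsRatioResult(
            variable, float("inf"), (0.0, float("inf")), float("nan"),
            scale, orientation, separated=True,
        )


# ---------------------------------------------------------------------------
# Forward stepwise logistic regression
# ---------------------------------------------------------------------------

@dataclass
class StepwiseEntry:
    variable: str
    entry_p: float               # score-test p at the entry step
    coef: float
    odds_ratio: float            # per SD decrease of the predictor
    ci: tuple[float, float]
    wald_p: float


@dataclass
class LogisticModelResult:
    entered: list[StepwiseEntry] = field(default_factory=list)
    p_enter: float = 0.05
    candidate_order: tuple[str, ...] = ()

    @property
    def variables(self) -> list[str]:
        return [e.variable for e in self.entered]


def _score_test_p(X: np.ndarray, y: np.ndarray, x_new: np.ndarray) -> float:
    """Rao score test for adding one column to a fitted logistic model."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    p = res.predict(X)
    w = p * (1 - p)
    u = float(x_new @ (y - p))
    i_oo = X.T @ (X * w[:, None])
    i_on = X.T @ (w * x_new)
    i_nn = float(x_new @ (w * x_new))
    var = i_nn - float(i_on @ np.linalg.solve(i_oo, i_on))
    if var <= 0:
        return 1.0
    return float(sps.chi2.sf(u * u / var, 1))


def stepwise_logistic(
    candidates: pd.DataFrame,
    status,
    p_enter: float = 0.05,
    orientations: dict[str, str] | None = None,
) -> LogisticModelResult:
    """Forward stepwise multivariate logistic regression.

    At each step the remaining candidate with the smallest score-test p enters
    if p < ``p_enter`` (ties broken by listed order); selection stops
    otherwise.  The final model is refit and reported with per-predictor Wald
    p-values and odds ratios per SD decrease.  Rows with any missing candidate
    are dropped (complete-case).  An empty model (no candidate passes at step
    one) is a valid result.
    """
    if candidates.shape[1] == 0:
        raise ParameterError("at least one candidate predictor is required")
    status = np.asarray(status, dtype=float)
    data = candidates.reset_index(drop=True)
    keep = ~data.isna().any(axis=1).to_numpy() & ~np.isnan(status)
    data = data.loc[keep]
    y = status[keep]
    orientations = orientations or {}

    z = {}
    for col in data.columns:
        z[col], _ = _oriented_z(
            data[col].to_numpy(dtype=float), orientations.get(col, LOWER), None
        )

    selected: list[str] = []
    entry_ps: dict[str, float] = {}
    remaining = list(data.columns)
    while remaining:
        X = np.column_stack([np.ones(len(y))] + [z[c] for c in selected])
        pvals = [_score_test_p(X, y, z[c]) for c in remaining]
        best = int(np.argmin(pvals))
        if pvals[best] >= p_enter:
            break
        name = remaining.pop(best)
        entry_ps[name] = float(pvals[best])
        selected.append(name)

    result = LogisticModelResult(p_enter=p_enter, candidate_order=tuple(candidates.columns))
    if not selected:
        return result
    X = sm.add_constant(np.column_stack([z[c] for c in selected]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    zcrit = 1.959963984540054
    for i, name in enumerate(selected, start=1):
        beta, se = float(res.params[i]), float(res.bse[i])
        result.entered.append(
            StepwiseEntry(
                variable=name,
                entry_p=entry_ps[name],
                coef=beta,
                odds_ratio=float(np.exp(beta)),
                ci=(float(np.exp(beta - zcrit * se)), float(np.exp(beta + zcrit * se))),
                wald_p=float(res.pvalues[i]),
            )
        )
    return result


# ---------------------------------------------------------------------------
# Cohort report (group summary + discrimination tables + correlations)
# ---------------------------------------------------------------------------

@dataclass
class CohortReport:
    group_summary: pd.DataFrame       # variable, group means/SDs, Wilcoxon stat, p
    discrimination: pd.DataFrame      # variable, OR per SD, CI, AUC, SE, p
    correlations: pd.DataFrame        # Spearman r matrix across variables
    correlation_p: pd.DataFrame
    stepwise: LogisticModelResult


def _paired_diffs(df: pd.DataFrame, column: str) -> np.ndarray:
    ctrl = df[df["group"] == 0].set_index("pair_id")[column]
    case = df[df["group"] == 1].set_index("pair_id")[column]
    if not ctrl.index.sort_values().equals(case.index.sort_values()):
        raise MatchingError("unmatched pair ids between groups")
    aligned = pd.DataFrame({"c": ctrl, "f": case}).dropna()
    return (aligned["f"] - aligned["c"]).to_numpy()


def build_report(
    cohort: pd.DataFrame,
    p_enter: float = 0.05,
    orientations: dict[str, str] | None = None,
) -> CohortReport:
    """Full statistical report for one matched case-control cohort.

    One group-summary row and one discrimination row per variable (13
    vertebral levels, mean L1-L3, VAT, SAT, VAT/SAT); Spearman correlation
    matrix across all variables; forward stepwise logistic model over all
    candidates.  Non-significant odds ratios render as "n.s.".
    """
    validate_cohort(cohort)
    orientations = {**DEFAULT_ORIENTATIONS, **(orientations or {})}

    summary_rows, discr_rows = [], []
    for var in REPORT_VARIABLES:
        col = _VARIABLE_COLUMNS[var]
        ctrl = cohort.loc[cohort["group"] == 0, col].dropna().to_numpy()
        case = cohort.loc[cohort["group"] == 1, col].dropna().to_numpy()
        wres = wilcoxon_signed_rank(_paired_diffs(cohort, col))
        summary_rows.append(
            {
                "variable": var,
                "control_mean": ctrl.mean() if ctrl.size else np.nan,
                "control_sd": ctrl.std(ddof=1) if ctrl.size > 1 else np.nan,
                "fracture_mean": case.mean() if case.size else np.nan,
                "fracture_sd": case.std(ddof=1) if case.size > 1 else np.nan,
                "wilcoxon_statistic": wres.statistic,
                "wilcoxon_p": wres.p,
                "degenerate": wres.method == "degenerate",
            }
        )
        orient = orientations[var]
        roc = roc_auc(ctrl, case, orientation=orient, variable=var)
        orr = or_per_sd(
            cohort[col].to_numpy(), cohort["group"].to_numpy(),
            orientation=orient, variable=var,
        )
        significant = np.isfinite(orr.p) and orr.p < 0.05 and not orr.separated
        discr_rows.append(
            {
                "variable": var,
                "odds_ratio": orr.odds_ratio,
                "or_ci_low": orr.ci[0],
                "or_ci_high": orr.ci[1],
                "or_p": orr.p,
                "or_text": f"{orr.odds_ratio:.2f}" if significant else "n.s.",
                "auc": roc.auc,
                "auc_se": roc.se,
                "auc_p": roc.p,
                "orientation": orient,
            }
        )

    variables = list(REPORT_VARIABLES)
    k = len(variables)
    rmat = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = spearman(
                cohort[_VARIABLE_COLUMNS[variables[i]]],
                cohort[_VARIABLE_COLUMNS[variables[j]]],
                names=(variables[i], variables[j]),
            )
            rmat[i, j] = rmat[j, i] = res.r
            pmat[i, j] = pmat[j, i] = res.p

    stepwise = stepwise_logistic(
        cohort[[_VARIABLE_COLUMNS[v] for v in variables]].rename(
            columns={_VARIABLE_COLUMNS[v]: v for v in variables}
        ),
        cohort["group"].to_numpy(),
        p_enter=p_enter,
        orientations=orientations,
    )
    return CohortReport(
        group_summary=pd.DataFrame(summary_rows),
        discrimination=pd.DataFrame(discr_rows),
        correlations=pd.DataFrame(rmat, index=variables, columns=variables),
        correlation_p=pd.DataFrame(pmat, index=variables, columns=variables),
        stepwise=stepwise,
    )
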
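"""Statistical battery against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from opqct.errors import MatchingError, ParameterError
from opqct.reference import reference_cohort_params
from opqct.stats import (
    HIGHER,
    LOWER,
    REPORT_VARIABLES,
    build_report,
    hanley_mcneil_se,
    or_per_sd,
    roc_auc,
    spearman,
    stepwise_logistic,
    wilcoxon_signed_rank,
)
from opqct.synth import generate_cohort


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_auc(control, case, orientation=LOWER):
    """Exhaustive pair counting: correctly ordered pairs, ties one half."""
    wins = 0.0
    for c in case:
        for k in control:
            if c == k:
                wins += 0.5
            elif (c < k) == (orientation == LOWER):
                wins += 1.0
    return wins / (len(case) * len(control))


def brute_force_wilcoxon_p(diffs):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    dist = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product((0, 1), repeat=n)]
    )
    p_le = np.mean(dist <= w_obs + 1e-9)
    p_ge = np.mean(dist >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def test_wilcoxon_enumeration_example():
    res = wilcoxon_signed_rank([1.0, -2.0, 3.0])
    assert res.w_minus == pytest.approx(2.0)
    assert res.p == pytest.approx(0.75)
    assert res.method == "exact"


def test_wilcoxon_exact_matches_sign_enumeration():
    rng = np.random.default_rng(11)
    for trial in range(60):
        n = int(rng.integers(1, 13))
        d = np.round(rng.normal(0, 2, size=n), 1)      # induces occasional ties
        d = np.where(d == 0, 0.5, d)
        got = wilcoxon_signed_rank(d)
        assert got.p == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12), (trial, d)


@given(st.lists(st.floats(-50, 50).filter(lambda v: abs(v) > 1e-6), min_size=1, max_size=20))
def test_wilcoxon_symmetric_under_negation(diffs):
    a = wilcoxon_signed_rank(diffs)
    b = wilcoxon_signed_rank([-d for d in diffs])
    assert a.p == pytest.approx(b.p, abs=1e-12)
    assert a.w_plus == pytest.approx(b.w_minus)


def test_wilcoxon_zeros_dropped_and_degenerate_flagged():
    res = wilcoxon_signed_rank([0.0, 0.0, 1.0, -2.0, 3.0])
    assert res.n_used == 3 and res.n_zero_dropped == 2
    degen = wilcoxon_signed_rank([0.0, 0.0, 0.0])
    assert degen.method == "degenerate" and degen.p == 1.0


def test_wilcoxon_type_one_error_is_calibrated():
    """At n=17 null pairs the exact test rejects at ~alpha=0.05."""
    rng = np.random.default_rng(99)
    rejections = sum(
        wilcoxon_signed_rank(rng.normal(0, 1, size=17)).p <= 0.05 for _ in range(2000)
    )
    assert 0.035 <= rejections / 2000 <= 0.065


def test_wilcoxon_normal_approximation_regime():
    rng = np.random.default_rng(5)
    d = rng.normal(0.8, 1.0, size=60)
    res = wilcoxon_signed_rank(d)
    assert res.method == "normal"
    ref = sps.wilcoxon(d, correction=True, mode="approx")
    assert res.p == pytest.approx(ref.pvalue, rel=1e-6)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_limits_and_hand_example():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    assert spearman(x, x).r == pytest.approx(1.0)
    assert spearman(x, [-v for v in x]).r == pytest.approx(-1.0)
    # d^2 = (1,1,1,1,0): r = 1 - 6*4/(5*24) = 0.8
    res = spearman(x, [2.0, 1.0, 4.0, 3.0, 5.0])
    assert res.r == pytest.approx(0.8)


def test_spearman_equals_rank_pearson():
    rng = np.random.default_rng(2)
    for _ in range(25):
        n = int(rng.integers(4, 30))
        x = np.round(rng.normal(size=n), 1)
        y = np.round(rng.normal(size=n) + 0.5 * x, 1)
        got = spearman(x, y).r
        expected = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
        assert got == pytest.approx(expected, abs=1e-12)


@given(
    st.lists(
        st.tuples(st.integers(-100, 100), st.integers(-100, 100)),
        min_size=4, max_size=30,
    )
)
def test_spearman_invariant_under_monotone_transform(pairs):
    x = np.array([float(p[0]) for p in pairs])
    y = np.array([float(p[1]) for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return
    base = spearman(x, y).r
    assert spearman(np.exp(x / 50.0), y).r == pytest.approx(base, abs=1e-9)
    assert spearman(x, 3.0 * y + 7.0).r == pytest.approx(base, abs=1e-9)


def test_spearman_constant_input_flagged_and_short_input_rejected():
    res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
    assert res.undefined and np.isnan(res.r)
    with pytest.raises(ParameterError, match="3"):
        spearman([1.0, 2.0], [3.0, 4.0])


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def test_auc_hand_example_and_complement():
    controls = [160.0, 150.0, 140.0]
    cases = [130.0, 145.0, 120.0]
    res = roc_auc(controls, cases, orientation=LOWER)
    assert res.auc == pytest.approx(8.0 / 9.0)
    flipped = roc_auc(cases, controls, orientation=LOWER)
    assert flipped.auc == pytest.approx(1.0 / 9.0)
    assert res.auc + roc_auc(controls, cases, orientation=HIGHER).auc == pytest.approx(1.0)


def test_auc_perfect_separation():
    controls = list(np.linspace(150.0, 170.0, 10))
    cases = list(np.linspace(100.0, 120.0, 10))
    res = roc_auc(controls, cases, orientation=LOWER)
    assert res.auc == 1.0
    assert res.se == 0.0
    assert res.p < 0.001


def test_auc_equals_brute_force_on_random_small_inputs():
    rng = np.random.default_rng(7)
    for trial in range(400):
        n0 = int(rng.integers(1, 9))
        n1 = int(rng.integers(1, 9))
        ctrl = rng.integers(0, 6, size=n0).astype(float)   # many ties
        case = rng.integers(0, 6, size=n1).astype(float)
        orient = LOWER if trial % 2 == 0 else HIGHER
        got = roc_auc(ctrl, case, orientation=orient).auc
        assert got == pytest.approx(brute_force_auc(ctrl, case, orient), abs=1e-12)


def test_hanley_mcneil_se_closed_form():
    # AUC=0.5 reduces to the null variance sqrt((n0+n1+1)/(12 n0 n1))
    assert hanley_mcneil_se(0.5, 17, 17) == pytest.approx(
        np.sqrt((0.5 * 0.5 + 16 * (1 / 3 - 0.25) * 2) / (17 * 17))
    )
    assert hanley_mcneil_se(1.0, 10, 10) == 0.0


def test_auc_empty_group_rejected():
    with pytest.raises(ParameterError, match="non-empty"):
        roc_auc([], [1.0])


# ---------------------------------------------------------------------------
# odds ratios per SD
# ---------------------------------------------------------------------------

def test_or_null_predictor_near_one():
    rng = np.random.default_rng(21)
    x = rng.normal(size=4000)
    y = rng.integers(0, 2, size=4000)
    res = or_per_sd(x, y)
    assert res.odds_ratio == pytest.approx(1.0, abs=0.15)
    assert res.ci[0] < 1.0 < res.ci[1]


def test_or_recovers_simulated_per_sd_effect():
    """True per-SD log-odds of 1 recovered within (2.3, 3.2) in >=90% of seeds."""
    hits = 0
    n_seeds = 120
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        x = rng.normal(size=2000)
        p = 1.0 / (1.0 + np.exp(-(-0.5 - 1.0 * x)))   # lower x -> higher risk
        y = rng.random(2000) < p
        res = or_per_sd(x, y.astype(float), orientation=LOWER)
        if 2.3 <= res.odds_ratio <= 3.2:
            hits += 1
    assert hits >= int(0.90 * n_seeds)


def test_or_sign_contract_under_reparameterization():
    rng = np.random.default_rng(3)
    x = rng.normal(size=500)
    y = (rng.random(500) < 1 / (1 + np.exp(x))).astype(float)
    a = or_per_sd(x, y, orientation=LOWER)
    b = or_per_sd(-x, y, orientation=HIGHER)
    assert a.odds_ratio == pytest.approx(b.odds_ratio, rel=1e-6)


def test_or_complete_separation_flagged():
    x = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    y = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    res = or_per_sd(x, y, orientation=LOWER)
    assert res.separated
    assert res.ci == (0.0, float("inf"))


# ---------------------------------------------------------------------------
# stepwise logistic regression
# ---------------------------------------------------------------------------

def _sim_candidates(seed, n=1000, signal=True):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    noise = rng.normal(size=n)
    logit = -0.3 - (1.2 * x1 if signal else 0.0)
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
    return pd.DataFrame({"signal": x1, "noise": noise}), y


def test_single_strong_candidate_enters():
    X, y = _sim_candidates(0)
    res = stepwise_logistic(X[["signal"]], y)
    assert res.variables == ["signal"]
    assert res.entered[0].entry_p < 0.05


def test_noise_candidate_enters_at_type_one_rate():
    entered = 0
    n_seeds = 150
    for seed in range(n_seeds):
        X, y = _sim_candidates(seed, n=600, signal=False)
        res = stepwise_logistic(X[["noise"]], y)
        entered += bool(res.variables)
    assert entered <= int(0.10 * n_seeds)


def test_collinear_candidates_usually_enter_once():
    """With two near-duplicate predictors carrying the same signal, the second
    adds no information once the first is in, so it enters only at the
    type-one rate of the score test."""
    singles = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(300 + seed)
        n = 1500
        x1 = rng.normal(size=n)
        x2 = 0.995 * x1 + np.sqrt(1 - 0.995**2) * rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(0.8 * x1))).astype(float)
        res = stepwise_logistic(pd.DataFrame({"a": x1, "b": x2}), y)
        assert len(res.variables) >= 1 and res.variables[0] in ("a", "b")
        singles += len(res.variables) == 1
    assert singles >= int(0.8 * n_seeds)


def test_stepwise_containment_and_entry_threshold():
    X, y = _sim_candidates(4)
    res = stepwise_logistic(X, y, p_enter=0.05)
    assert set(res.variables) <= set(X.columns)
    for e in res.entered:
        assert e.entry_p < 0.05


def test_empty_model_is_valid_result():
    rng = np.random.default_rng(8)
    X = pd.DataFrame({"x": rng.normal(size=200)})
    y = rng.integers(0, 2, size=200).astype(float)
    res = stepwise_logistic(X, y)
    assert isinstance(res.variables, list)   # may legitimately be empty
    assert res.p_enter == 0.05


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

def test_report_covers_all_seventeen_variables():
    cohort = generate_cohort(reference_cohort_params(), seed=12)
    report = build_report(cohort)
    assert list(report.group_summary["variable"]) == list(REPORT_VARIABLES)
    assert len(report.discrimination) == 17
    assert report.correlations.shape == (17, 17)
    assert np.allclose(np.diag(report.correlations), 1.0)
    assert set(report.stepwise.variables) <= set(REPORT_VARIABLES)
    ns_rows = report.discrimination[report.discrimination["or_p"] >= 0.05]
    assert (ns_rows["or_text"] == "n.s.").all()


def test_identical_groups_degenerate_report():
    """Duplicating the controls as cases: all paired differences are zero and
    every AUC is exactly one half."""
    cohort = generate_cohort(reference_cohort_params(), seed=3)
    ctrl = cohort[cohort["group"] == 0]
    fake_cases = ctrl.copy()
    fake_cases["group"] = 1
    fake_cases["subject_id"] = "F" + fake_cases["pair_id"].astype(str)
    dup = pd.concat([ctrl, fake_cases], ignore_index=True)
    report = build_report(dup)
    assert (report.group_summary["wilcoxon_p"] == 1.0).all()
    assert report.group_summary["degenerate"].all()
    assert np.allclose(report.discrimination["auc"], 0.5)


def test_unmatched_pairs_raise_matching_error():
    cohort = generate_cohort(reference_cohort_params(), seed=1)
    broken = cohort.copy()
    broken.loc[broken.index[0], "pair_id"] = 999
    with pytest.raises((MatchingError, ParameterError)):
        build_report(broken)


def test_large_cohort_reproduces_group_means():
    cohort = generate_cohort(reference_cohort_params(n_per_group=20000), seed=6)
    report = build_report(cohort)
    th7 = report.group_summary.set_index("variable").loc["Th7"]
    assert th7["control_mean"] == pytest.approx(166.3, rel=0.01)
    assert th7["fracture_mean"] == pytest.approx(128.4, rel=0.01)
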
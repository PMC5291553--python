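"""Statistics: frozen worked values and brute-force oracle equivalence."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from ivimnac import (
    ValidationError,
    clopper_pearson,
    cohort_wide,
    compare_groups,
    diagnostic_metrics,
    estimate_auc_correlation,
    hanley_mcneil_test,
    mann_whitney,
    roc_analysis,
    roc_auc,
    route_test,
    run_full_analysis,
    simulate_cohort,
    spearman_shrinkage,
    youden_cutoff,
)


# --- independent oracles -----------------------------------------------------

def auc_pair_counting(scores, labels):
    """Double loop over (case, control) pairs; ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def mw_enumeration_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    U is computed by pair counting (not midranks) so the code path is
    independent of the implementation's.
    """
    pooled = list(a) + list(b)
    n1 = len(a)
    mu = n1 * len(b) / 2.0

    def u_of(group):
        rest = pooled.copy()
        for x in group:
            rest.remove(x)
        return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in group for y in rest)

    u_obs = u_of(list(a))
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        group = [pooled[i] for i in comb]
        total += 1
        if abs(u_of(group) - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return u_obs, hits / total


def youden_brute_force(scores, labels, orientation):
    """Scan every threshold on a fine grid around the data; max J."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    grid = np.unique(np.concatenate([scores, scores - 1e-6, scores + 1e-6]))
    best = -np.inf
    for c in grid:
        pred = scores >= c if orientation == "ge" else scores <= c
        j = (pred & labels).sum() / labels.sum() + (~pred & ~labels).sum() / (~labels).sum() - 1
        best = max(best, j)
    return best


# --- routing and group comparison --------------------------------------------

def test_route_test_normal_vs_heavy_tailed(rng):
    a = rng.normal(size=300)
    b = rng.normal(size=300)
    assert route_test(a, b) == "student_t"
    heavy = rng.lognormal(mean=0.0, sigma=1.0, size=200)
    assert route_test(rng.normal(size=200), heavy) == "mann_whitney"


def test_route_test_preconditions():
    with pytest.raises(ValidationError):
        route_test([1.0, 2.0], [1.0, 2.0, 3.0, 4.0])
    with pytest.warns(UserWarning):
        assert route_test([1.0] * 10, [1.0, 2.0, 3.0, 2.5, 1.5]) == "mann_whitney"


def test_student_t_hand_value(rng):
    # pooled-variance t: diff / (sp * sqrt(1/3 + 1/3)) with sp = 1
    t, _ = sps.ttest_ind([1, 2, 3], [101, 102, 103], equal_var=True)
    assert abs(t) == pytest.approx(100.0 * math.sqrt(1.5), rel=1e-12)
    gc = compare_groups(rng.normal(size=50), rng.normal(loc=5.0, size=50), "x")
    assert gc.test_used == "student_t" and gc.p_value < 1e-4


def test_mann_whitney_exact_matches_enumeration():
    u, p = mann_whitney([1, 2, 3], [2, 3, 4])
    u_oracle, p_oracle = mw_enumeration_p([1, 2, 3], [2, 3, 4])
    assert u == pytest.approx(u_oracle)
    assert p == pytest.approx(p_oracle)


@pytest.mark.parametrize("trial", range(20))
def test_mann_whitney_exact_random_small_samples(trial):
    rng = np.random.default_rng(1000 + trial)
    n1, n2 = rng.integers(3, 8, size=2)
    a = np.round(rng.normal(size=n1), 1)
    b = np.round(rng.normal(loc=rng.uniform(-1, 1), size=n2), 1)
    u, p = mann_whitney(a, b)
    u_oracle, p_oracle = mw_enumeration_p(list(a), list(b))
    assert u == pytest.approx(u_oracle)
    assert p == pytest.approx(p_oracle)


def test_identical_groups_p_one():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    _, p = mann_whitney(x, x)
    assert p == pytest.approx(1.0)


# --- ROC / Youden / diagnostic metrics ---------------------------------------

def test_auc_worked_examples():
    auc, _, _ = roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
    assert auc == 1.0
    auc, _, orient = roc_auc([1, 2, 3, 2, 3, 4], [0, 0, 0, 1, 1, 1])
    assert auc == pytest.approx(7.0 / 9.0) and orient == "ge"
    # label swap mirrors the AUC before orientation
    auc_sw, _, orient_sw = roc_auc([1, 2, 3, 2, 3, 4], [1, 1, 1, 0, 0, 0])
    assert auc_sw == pytest.approx(7.0 / 9.0) and orient_sw == "le"
    with pytest.raises(ValidationError):
        roc_auc([1, 2], [1, 1])


@pytest.mark.parametrize("trial", range(0, 1000, 100))
def test_auc_matches_pair_counting_oracle(trial):
    rng = np.random.default_rng(trial)
    for k in range(100):
        n = int(rng.integers(4, 12))
        labels = np.zeros(n, dtype=bool)
        labels[: int(rng.integers(1, n))] = True
        rng.shuffle(labels)
        if labels.all() or not labels.any():
            continue
        scores = np.round(rng.normal(size=n), 1)
        auc, _, _ = roc_auc(scores, labels)
        oracle = auc_pair_counting(scores, labels)
        assert auc == pytest.approx(max(oracle, 1 - oracle))


def test_youden_worked_examples():
    cutoff, sens, spec = youden_cutoff([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
    assert cutoff == pytest.approx(3.5) and sens == 1.0 and spec == 1.0
    # fully overlapping identical sets: best J is 0, sens + spec = 1
    _, sens, spec = youden_cutoff([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1], orientation="ge")
    assert sens + spec == pytest.approx(1.0)


def test_youden_never_beaten_by_brute_force(rng):
    for _ in range(200):
        n = int(rng.integers(4, 15))
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            continue
        scores = np.round(rng.normal(size=n), 1)
        for orientation in ("ge", "le"):
            c, sens, spec = youden_cutoff(scores, labels, orientation=orientation)
            assert sens + spec - 1 >= youden_brute_force(scores, labels, orientation) - 1e-12


def test_clopper_pearson_printed_bounds():
    lo, hi = clopper_pearson(9, 9)
    assert 100 * lo == pytest.approx(66.4, abs=0.05)  # 0.025**(1/9)
    assert lo == pytest.approx(0.025 ** (1.0 / 9.0), rel=1e-12)
    assert hi == 1.0
    lo, hi = clopper_pearson(14, 19)
    assert 100 * lo == pytest.approx(48.8, abs=0.05)
    assert 100 * hi == pytest.approx(90.9, abs=0.05)
    lo, hi = clopper_pearson(0, 1)
    assert lo == 0.0 and 100 * hi == pytest.approx(97.5, abs=0.01)


def test_diagnostic_metrics_contain_point_and_flag_zero_denominator():
    m = diagnostic_metrics(tp=9, fp=5, tn=14, fn=0)
    assert m["sens"][0] == 100.0 and m["sens"][1] == pytest.approx(66.4, abs=0.05)
    assert m["spec"][0] == pytest.approx(100 * 14 / 19)
    for point, lo, hi in m.values():
        assert 0.0 <= lo <= point <= hi <= 100.0
    with pytest.warns(UserWarning):
        m = diagnostic_metrics(tp=0, fp=0, tn=3, fn=2)
        assert math.isnan(m["ppv"][0])


def test_hanley_mcneil_worked_values():
    from ivimnac.stats import _auc_se_hanley

    z, p = hanley_mcneil_test(0.8, 0.8, 10, 10, r=0.3)
    assert z == 0.0 and p == 1.0
    # A = 0.5, n = 5/5: SE = sqrt(0.9167/25) ~ 0.1915
    assert _auc_se_hanley(0.5, 5, 5) == pytest.approx(math.sqrt(0.9167 / 25.0), rel=1e-3)
    # with r = 0 the denominator is the independence form sqrt(SE1^2 + SE2^2)
    z, _ = hanley_mcneil_test(0.6, 0.5, 5, 5, r=0.0)
    se1, se2 = _auc_se_hanley(0.6, 5, 5), _auc_se_hanley(0.5, 5, 5)
    assert abs(z) == pytest.approx(0.1 / math.sqrt(se1**2 + se2**2), rel=1e-12)
    with pytest.raises(ValidationError):
        hanley_mcneil_test(0.3, 0.6, 5, 5)  # unoriented AUC
    with pytest.raises(ValidationError):
        hanley_mcneil_test(0.6, 0.5, 5, 5, r=1.0)  # perfectly correlated scores


def test_estimate_auc_correlation_bounds(rng):
    labels = np.array([True] * 10 + [False] * 10)
    s1 = rng.normal(size=20)
    assert estimate_auc_correlation(s1, s1 + rng.normal(scale=0.1, size=20), labels) > 0.5
    assert 0.0 <= estimate_auc_correlation(s1, rng.normal(size=20), labels) <= 0.99


def test_spearman_worked_values():
    rho, _ = spearman_shrinkage([1, 2, 3, 4], [10, 20, 30, 40])
    assert rho == pytest.approx(1.0)
    rho, _ = spearman_shrinkage([1, 2, 3, 4], [40, 30, 20, 10])
    assert rho == pytest.approx(-1.0)
    # hand ranking: d = (0, 1, -1, ... ) -> 1 - 6*4/(4*15) = 0.6
    rho, _ = spearman_shrinkage([1, 2, 3, 4], [2, 1, 4, 3])
    assert rho == pytest.approx(0.6)
    with pytest.raises(ValidationError):
        spearman_shrinkage([1, 2, 3], [1, 2, 3])


def test_estimated_auc_matches_analytic_for_normal_groups():
    # two normal groups: analytic AUC = Phi(delta / sqrt(s1^2 + s2^2))
    rng = np.random.default_rng(8)
    delta, s1, s2, n = 1.0, 1.0, 1.0, 4000
    scores = np.concatenate([rng.normal(delta, s1, n), rng.normal(0.0, s2, n)])
    labels = np.array([True] * n + [False] * n)
    auc, _, _ = roc_auc(scores, labels)
    assert auc == pytest.approx(sps.norm.cdf(delta / math.sqrt(2.0)), abs=0.01)


# --- cohort pipeline ----------------------------------------------------------

@pytest.fixture(scope="module")
def default_report():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_full_analysis(simulate_cohort())


def test_full_analysis_structure(default_report):
    rep = default_report
    assert rep["metadata"]["n_patients"] == 28
    assert rep["metadata"]["multiple_testing_correction"] == "none"
    assert set(rep["group_comparisons"]) >= {"delta_D", "delta_f", "f_pre", "D_mid"}
    roc = rep["roc"]["delta_D"]
    assert roc["auc_ci"][0] <= roc["auc"] <= roc["auc_ci"][1]
    for key in ("sens", "spec", "ppv", "npv"):
        point, lo, hi = rep["roc"]["delta_D"][key]
        assert 0.0 <= lo <= point <= hi <= 100.0


def test_full_analysis_deterministic():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = run_full_analysis(simulate_cohort())
        b = run_full_analysis(simulate_cohort())
    assert a == b


def test_full_analysis_single_class_errors():
    df = simulate_cohort()
    df["pcr"] = True
    with pytest.raises(ValidationError):
        run_full_analysis(df)


def test_pre_only_cohort_skips_delta_blocks():
    df = simulate_cohort()
    df = df[df["timepoint"] == "pre"].reset_index(drop=True)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = run_full_analysis(df)
    assert "delta_D" not in rep["group_comparisons"]
    assert rep["auc_comparisons"] == {} and rep["spearman"] == {}
    assert "f_pre" in rep["roc"]


def test_cohort_wide_requires_schema():
    import pandas as pd

    with pytest.raises(ValidationError):
        cohort_wide(pd.DataFrame({"id": [1], "D": [1.0]}))
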
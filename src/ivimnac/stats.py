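"""Response-prediction statistics for a two-group imaging cohort.

Implements the statistical pipeline of an early treatment-response study:

* normality-routed group comparison — Lilliefors-corrected one-sample
  Kolmogorov-Smirnov per group; Student t when both groups pass, exact
  Mann-Whitney U otherwise;
* ROC analysis with the Mann-Whitney pair-counting AUC estimator (ties
  count one half), Hanley-McNeil standard-error confidence intervals, and
  Youden-optimal operating cutoffs;
* diagnostic sensitivity/specificity/PPV/NPV with exact Clopper-Pearson
  confidence intervals;
* the Hanley-McNeil z test for the difference of two (correlated) AUCs;
* Spearman correlation of parameters with mass shrinkage.

Throughout, pCR (pathologic complete response) is the positive class,
tests are two-sided at alpha = 0.05 and no multiple-testing correction is
applied (flagged in the report metadata).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import asdict, dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .model import ValidationError

__all__ = [
    "GroupComparison",
    "ROCResult",
    "route_test",
    "compare_groups",
    "mann_whitney",
    "roc_auc",
    "youden_cutoff",
    "diagnostic_metrics",
    "clopper_pearson",
    "hanley_mcneil_test",
    "estimate_auc_correlation",
    "spearman_shrinkage",
    "cohort_wide",
    "run_full_analysis",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05
#: exact Mann-Whitney enumeration is used while C(n1+n2, n1) stays below this
EXACT_MW_LIMIT = 20_000


# ---------------------------------------------------------------------------
# group comparison

@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test_used: str              # "student_t" | "mann_whitney"
    statistic: float
    p_value: float
    summary_a: str              # mean+-SD or median (IQR), per routing
    summary_b: str
    n_a: int
    n_b: int


def _is_normalish(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:
        warnings.warn("constant sample: routing nonparametric", stacklevel=3)
        return False
    if len(x) < 4:
        warnings.warn("group too small for the KS normality test: routing nonparametric",
                      stacklevel=3)
        return False
    _, p = lilliefors(x, dist="norm")
    return p > alpha


def route_test(sample_a, sample_b, alpha: float = ALPHA) -> str:
    """Choose the group-comparison test from per-group normality.

    Lilliefors-corrected Kolmogorov-Smirnov (mean and SD estimated from
    the sample) on each group; both consistent with normality routes to
    the Student t test, anything else to Mann-Whitney.  Constant or
    too-small samples route nonparametric with a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("need n >= 3 per group")
    if _is_normalish(a, alpha) and _is_normalish(b, alpha):
        return "student_t"
    return "mann_whitney"


def _midrank_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of sample a, from pooled midranks."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    return float(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2.0)


def mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    For small problems (C(n1+n2, n1) <= 20 000) the p value is exact by
    full enumeration of group assignments:
    p = P(|U' - n1*n2/2| >= |u - n1*n2/2|) under the permutation null.
    Larger problems fall back to the tie-corrected normal approximation.
    Returns (U of sample_a, p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = len(a), len(b)
    u = _midrank_u(a, b)
    if math.comb(n1 + n2, n1) <= EXACT_MW_LIMIT:
        ranks = sps.rankdata(np.concatenate([a, b]))
        mu = n1 * n2 / 2.0
        offset = n1 * (n1 + 1) / 2.0
        hits = total = 0
        for idx in combinations(range(n1 + n2), n1):
            u_perm = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u_perm - mu) >= abs(u - mu) - 1e-9:
                hits += 1
        return u, hits / total
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


def _summary(x: np.ndarray, style: str) -> str:
    if style == "student_t":
        return f"{x.mean():.3g} +/- {x.std(ddof=1):.3g}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.3g} ({q1:.3g}-{q3:.3g})"


def compare_groups(sample_a, sample_b, variable: str = "", alpha: float = ALPHA) -> GroupComparison:
    """Normality-routed two-sided comparison of one variable across groups.

    Student t (pooled variance) when both groups pass the Lilliefors KS
    check, exact Mann-Whitney otherwise.  Summaries follow the routing:
    mean +/- SD for t, median (IQR) for the rank test.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    test = route_test(a, b, alpha=alpha)
    if test == "student_t":
        stat, p = sps.ttest_ind(a, b, equal_var=True)
    else:
        stat, p = mann_whitney(a, b)
    return GroupComparison(
        variable=variable,
        test_used=test,
        statistic=float(stat),
        p_value=float(p),
        summary_a=_summary(a, test),
        summary_b=_summary(b, test),
        n_a=len(a),
        n_b=len(b),
    )


# ---------------------------------------------------------------------------
# ROC / diagnostic performance

@dataclass(frozen=True)
class ROCResult:
    """AUC with CI, Youden-optimal cutoff and diagnostic metrics.

    ``orientation`` is 'ge' when high scores indicate the positive class
    and 'le' when low scores do; the AUC is reported after orientation,
    hence always >= 0.5.  Metric points and CI bounds are percentages.
    """

    auc: float
    auc_ci: tuple[float, float]
    orientation: str
    cutoff: float
    youden_j: float
    sens: tuple[float, float, float]
    spec: tuple[float, float, float]
    ppv: tuple[float, float, float]
    npv: tuple[float, float, float]
    n_pos: int
    n_neg: int


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = labels.astype(bool)
    if pos.all() or not pos.any():
        raise ValidationError("both classes must be present")
    return pos, ~pos


def _auc_se_hanley(a: float, n_pos: int, n_neg: int) -> float:
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    return math.sqrt(max(var, 0.0))


def roc_auc(scores, labels, alpha: float = ALPHA) -> tuple[float, tuple[float, float], str]:
    """AUC by pair counting (ties one half) with a Hanley-McNeil CI.

    Auto-orients so the AUC is >= 0.5 and returns
    ``(auc, (lo, hi), orientation)`` where orientation 'ge' means high
    scores predict the positive class.  The CI is the normal interval on
    the Hanley-McNeil standard error, truncated to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = _check_two_classes(labels)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    ranks = sps.rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    orientation = "ge"
    if auc < 0.5:
        auc = 1.0 - auc
        orientation = "le"
        logger.info("roc_auc: orientation flipped, low scores indicate the positive class")
    se = _auc_se_hanley(auc, n_pos, n_neg)
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    ci = (max(auc - z * se, 0.0), min(auc + z * se, 1.0))
    return float(auc), ci, orientation


def youden_cutoff(scores, labels, orientation: str | None = None) -> tuple[float, float, float]:
    """Youden-optimal operating point: ``(cutoff, sens, spec)``.

    Candidate thresholds are the midpoints between adjacent distinct
    sorted scores; J = sens + spec - 1 is maximized, ties broken by higher
    sensitivity then smaller |cutoff|.  ``orientation`` as in
    :func:`roc_auc`; inferred from the data when omitted.  Ties with the
    cutoff classify positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = _check_two_classes(labels)
    if orientation is None:
        _, _, orientation = roc_auc(scores, labels)
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if len(distinct) > 1 else distinct
    # corner thresholds (everything / nothing positive) are legal operating
    # points too; without them a forced orientation could do worse than J=0
    candidates = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])
    best = None
    for c in candidates:
        pred = scores >= c if orientation == "ge" else scores <= c
        sens = float((pred & pos).sum() / pos.sum())
        spec = float((~pred & neg).sum() / neg.sum())
        j = sens + spec - 1.0
        key = (round(j, 12), round(sens, 12), -abs(c))
        if best is None or key > best[0]:
            best = (key, float(c), sens, spec)
    _, cutoff, sens, spec = best
    return cutoff, sens, spec


def clopper_pearson(k: int, n: int, alpha: float = ALPHA) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval, as fractions."""
    if n <= 0:
        raise ValidationError("n must be positive")
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


def diagnostic_metrics(
    tp: int, fp: int, tn: int, fn: int, alpha: float = ALPHA
) -> dict[str, tuple[float, float, float]]:
    """Sens/spec/PPV/NPV as ``(point, lo, hi)`` percentages.

    Confidence intervals are exact Clopper-Pearson.  A metric with a zero
    denominator comes back as NaNs with a warning.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValidationError("counts must be non-negative")
    out: dict[str, tuple[float, float, float]] = {}
    for name, k, n in (
        ("sens", tp, tp + fn),
        ("spec", tn, tn + fp),
        ("ppv", tp, tp + fp),
        ("npv", tn, tn + fn),
    ):
        if n == 0:
            warnings.warn(f"diagnostic_metrics: {name} undefined (zero denominator)",
                          stacklevel=2)
            out[name] = (float("nan"),) * 3
            continue
        lo, hi = clopper_pearson(k, n, alpha=alpha)
        out[name] = (100.0 * k / n, 100.0 * lo, 100.0 * hi)
    return out


def roc_analysis(scores, labels, alpha: float = ALPHA) -> ROCResult:
    """Full single-marker ROC work-up: AUC + CI, Youden cutoff, metrics."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = _check_two_classes(labels)
    auc, ci, orientation = roc_auc(scores, labels, alpha=alpha)
    cutoff, _, _ = youden_cutoff(scores, labels, orientation=orientation)
    pred = scores >= cutoff if orientation == "ge" else scores <= cutoff
    tp = int((pred & pos).sum())
    fp = int((pred & neg).sum())
    tn = int((~pred & neg).sum())
    fn = int((~pred & pos).sum())
    m = diagnostic_metrics(tp, fp, tn, fn, alpha=alpha)
    sens, spec = m["sens"], m["spec"]
    return ROCResult(
        auc=auc,
        auc_ci=ci,
        orientation=orientation,
        cutoff=float(cutoff),
        youden_j=sens[0] / 100.0 + spec[0] / 100.0 - 1.0,
        sens=sens,
        spec=spec,
        ppv=m["ppv"],
        npv=m["npv"],
        n_pos=int(pos.sum()),
        n_neg=int(neg.sum()),
    )


def hanley_mcneil_test(
    auc1: float, auc2: float, n_pos: int, n_neg: int, r: float = 0.0
) -> tuple[float, float]:
    """Hanley-McNeil z test for the difference between two AUCs.

    ``r`` is the correlation between the two markers' AUC estimates
    induced by scoring the same cases (0 for independent samples; see
    :func:`estimate_auc_correlation`).  Each AUC's variance uses the
    Hanley-McNeil SE with Q1 = A/(2-A), Q2 = 2A^2/(1+A);
    z = (A1 - A2) / sqrt(SE1^2 + SE2^2 - 2 r SE1 SE2), two-sided normal p.
    """
    for a in (auc1, auc2):
        if not 0.5 <= a <= 1.0:
            raise ValidationError("AUCs must be oriented into [0.5, 1]")
    if not 0.0 <= r < 1.0:
        raise ValidationError("r must be in [0, 1)")
    se1 = _auc_se_hanley(auc1, n_pos, n_neg)
    se2 = _auc_se_hanley(auc2, n_pos, n_neg)
    var = se1 * se1 + se2 * se2 - 2.0 * r * se1 * se2
    if var <= 0:
        raise ValidationError("non-positive variance for the AUC difference")
    z = (auc1 - auc2) / math.sqrt(var)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return float(z), p


def estimate_auc_correlation(scores1, scores2, labels) -> float:
    """Between-marker correlation feeding the paired AUC comparison.

    Averages the Pearson correlations of the two score vectors within the
    positive and within the negative class — a practical stand-in for the
    published lookup table mapping the within-class correlations and mean
    AUC to r, to which it is close over most of the table.  Clipped to
    [0, 0.99]; non-finite within-class correlations (constant scores) are
    skipped.
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    pos, neg = _check_two_classes(np.asarray(labels))
    rs = []
    for sel in (pos, neg):
        if sel.sum() >= 3 and np.ptp(s1[sel]) > 0 and np.ptp(s2[sel]) > 0:
            rs.append(sps.pearsonr(s1[sel], s2[sel]).statistic)
    if not rs:
        return 0.0
    return float(np.clip(np.mean(rs), 0.0, 0.99))


def spearman_shrinkage(x, shrink_pct) -> tuple[float, float]:
    """Midrank Spearman correlation of a parameter with mass shrinkage.

    Two-sided p from the t approximation.  Needs at least 4 complete
    pairs; a constant variable yields NaNs with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(shrink_pct, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 4:
        raise ValidationError("need >= 4 paired observations")
    if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        warnings.warn("spearman_shrinkage: constant input, correlation undefined",
                      stacklevel=2)
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x[ok], y[ok])
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# cohort-level pipeline

#: wide-table score columns per (variable, when)
_SCORE_COLUMNS = {
    ("D", "pre"): "D_pre", ("D", "mid"): "D_mid", ("D", "delta"): "delta_D",
    ("Dstar", "pre"): "Dstar_pre", ("Dstar", "mid"): "Dstar_mid",
    ("Dstar", "delta"): "delta_Dstar",
    ("f", "pre"): "f_pre", ("f", "mid"): "f_mid", ("f", "delta"): "delta_f",
    ("MD", "pre"): "MD_pre", ("MD", "mid"): "MD_mid", ("MD", "delta"): "shrink_MD_pct",
    ("V", "pre"): "V_pre", ("V", "mid"): "V_mid", ("V", "delta"): "shrink_V_pct",
}


def cohort_wide(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long CohortTable to one row per patient, with deltas.

    Delta columns follow the pre-minus-mid convention on the reporting
    scale (delta_f in percentage points); shrink_* are percent of the
    pre value.  Patients without a mid row keep NaN deltas.
    """
    required = {"id", "timepoint", "pcr"}
    if not required.issubset(cohort.columns):
        raise ValidationError(f"cohort table needs columns {sorted(required)}")
    value_cols = ["D", "Dstar", "f", "MD_mm", "V_mm3"]
    wide = cohort.pivot(index="id", columns="timepoint", values=value_cols)
    out = pd.DataFrame(index=wide.index)
    rename = {"D": "D", "Dstar": "Dstar", "f": "f", "MD_mm": "MD", "V_mm3": "V"}
    for col, short in rename.items():
        out[f"{short}_pre"] = wide[(col, "pre")]
        out[f"{short}_mid"] = wide[(col, "mid")] if (col, "mid") in wide else np.nan
    out["delta_D"] = out["D_pre"] - out["D_mid"]
    out["delta_Dstar"] = out["Dstar_pre"] - out["Dstar_mid"]
    out["delta_f"] = out["f_pre"] - out["f_mid"]
    out["shrink_MD_pct"] = 100.0 * (out["MD_pre"] - out["MD_mid"]) / out["MD_pre"]
    out["shrink_V_pct"] = 100.0 * (out["V_pre"] - out["V_mid"]) / out["V_pre"]
    out["pcr"] = cohort.groupby("id")["pcr"].first().astype(bool)
    return out


def run_full_analysis(cohort: pd.DataFrame, alpha: float = ALPHA) -> dict:
    """End-to-end response-prediction report for a cohort table.

    Emits group comparisons (pre, mid, delta for D, D*, f, MD, V), a ROC
    table per marker, pairwise Hanley-McNeil comparisons among the delta
    markers, and Spearman correlations of D and f (pre/mid/delta) with
    diameter and volume shrinkage.  Missing mid data skips the mid/delta
    blocks with a log notice.  Deterministic: same table, same report.
    """
    wide = cohort_wide(cohort)
    labels = wide["pcr"].to_numpy()
    if labels.all() or not labels.any():
        raise ValidationError("cohort has a single outcome class; ROC analysis undefined")
    has_mid = wide["D_mid"].notna().any()
    if not has_mid:
        logger.warning("no mid-treatment data: delta and mid analyses skipped")
    whens = ("pre", "mid", "delta") if has_mid else ("pre",)

    report: dict = {
        "metadata": {
            "alpha": alpha,
            "positive_class": "pCR",
            "two_sided": True,
            "multiple_testing_correction": "none",
            "n_patients": int(len(wide)),
            "n_pcr": int(labels.sum()),
            "n_nonpcr": int((~labels).sum()),
        },
        "group_comparisons": {},
        "roc": {},
        "auc_comparisons": {},
        "spearman": {},
    }

    for var in ("D", "Dstar", "f", "MD", "V"):
        for when in whens:
            vals = wide[_SCORE_COLUMNS[(var, when)]].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            a = vals[ok & labels]
            b = vals[ok & ~labels]
            key = _SCORE_COLUMNS[(var, when)]
            try:
                report["group_comparisons"][key] = asdict(
                    compare_groups(a, b, variable=key, alpha=alpha)
                )
            except ValidationError as exc:
                logger.warning("group comparison %s skipped: %s", key, exc)
                continue
            roc = roc_analysis(vals[ok], labels[ok], alpha=alpha)
            report["roc"][key] = asdict(roc)

    if has_mid:
        delta_keys = ["delta_D", "delta_Dstar", "delta_f", "shrink_MD_pct", "shrink_V_pct"]
        for k1, k2 in combinations(delta_keys, 2):
            v1, v2 = wide[k1].to_numpy(float), wide[k2].to_numpy(float)
            ok = np.isfinite(v1) & np.isfinite(v2)
            auc1 = report["roc"][k1]["auc"]
            auc2 = report["roc"][k2]["auc"]
            r = estimate_auc_correlation(v1[ok], v2[ok], labels[ok])
            z, p = hanley_mcneil_test(
                auc1, auc2, int(labels[ok].sum()), int((~labels[ok]).sum()), r=r
            )
            report["auc_comparisons"][f"{k1}_vs_{k2}"] = {
                "auc1": auc1, "auc2": auc2, "r": r, "z": z, "p_value": p,
            }

        for var in ("D", "f"):
            for when in whens:
                col = _SCORE_COLUMNS[(var, when)]
                for shrink in ("shrink_MD_pct", "shrink_V_pct"):
                    rho, p = spearman_shrinkage(wide[col], wide[shrink])
                    report["spearman"][f"{col}_vs_{shrink}"] = {"rho": rho, "p_value": p}

    return report
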
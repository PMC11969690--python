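"""Cohort statistics: normality-gated comparisons, correlations, ROC.

The statistical layer mirrors a conventional SPSS-style clinical workflow:

* Shapiro–Wilk normality gate; two-group comparison by unpaired Student's t
  when both groups pass (summarised mean ± SD), otherwise Mann–Whitney U
  (summarised median with 25th/75th percentiles);
* Pearson chi-square for categorical rates;
* Spearman rank correlation, pairwise-complete, no multiplicity adjustment;
* empirical ROC with trapezoidal AUC, stratified-bootstrap CI and a
  Youden-J operating point.

Percentiles use the weighted-average-at-(n+1)p definition (SPSS HAVERAGE),
which reproduces the printed quartiles of the packaged patient table; a
nearest-rank alternative is available per call.  Missing data are handled by
pairwise deletion throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_NORMALITY = 0.05

COHORT_COLUMNS = [
    "patient_id", "family_id", "sex", "age", "onset_age", "alpha_gal",
    "lyso_gb3", "mssi", "hypertension", "visual_impairment", "mri_age",
    "arwmc", "fazekas", "epvs", "mars", "lacuna", "svds", "gca",
]

ORDINAL_MAXIMA = {
    "arwmc": 30, "fazekas": 3, "epvs": 4, "mars": 10,
    "lacuna": 5, "svds": 4, "gca": 15,
}


def percentile(values, p: float, method: str = "weighted") -> float:
    """Percentile with the SPSS-style weighted-average definition by default.

    ``weighted`` interpolates at position (n+1)·p ('weibull'); ``nearest``
    uses the nearest-rank order statistic.
    """
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    numpy_method = {"weighted": "weibull", "nearest": "closest_observation"}[method]
    return float(np.percentile(arr, p, method=numpy_method))


def load_cohort_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load and validate a patient table ("NA" marks missing values).

    With no path, the packaged 27-patient Fabry cohort is returned
    (19 male / 8 female, 14 families).
    """
    if path is None:
        path = files("retmorph.data").joinpath("fabry_table2.csv")
    df = pd.read_csv(path, na_values=["NA"])
    if df.empty:
        raise ValueError("cohort table is empty")
    missing_cols = set(COHORT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"cohort table missing columns: {sorted(missing_cols)}")
    if not df["sex"].isin(["M", "F"]).all():
        raise ValueError("sex must be 'M' or 'F' for every record")
    if (df["age"].dropna() <= 0).any():
        raise ValueError("ages must be positive")
    for col, hi in ORDINAL_MAXIMA.items():
        vals = df[col].dropna()
        if ((vals < 0) | (vals > hi)).any():
            raise ValueError(f"{col} outside its ordinal range [0, {hi}]")
    return df


@dataclass
class NormalityResult:
    statistic: float | None
    p_value: float | None
    is_normal: bool
    flagged: bool = False  # degenerate input forced the nonparametric path


def normality_gate(values) -> NormalityResult:
    """Shapiro–Wilk test; degenerate inputs force the nonparametric path."""
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(arr) < 3 or np.ptp(arr) == 0:
        return NormalityResult(None, None, is_normal=False, flagged=True)
    w, p = sps.shapiro(arr)
    return NormalityResult(float(w), float(p), is_normal=p >= ALPHA_NORMALITY)


@dataclass
class GroupComparison:
    parameter: str
    test_used: str  # t | mann_whitney | chi_square
    p_value: float
    n_a: int
    n_b: int
    summary_a: str
    summary_b: str
    statistic: float | None = None


def _summaries(a: np.ndarray, b: np.ndarray, parametric: bool, pct_method: str):
    if parametric:
        return (
            f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
            f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
        )
    fmt = lambda x: (
        f"{percentile(x, 50, pct_method):.2f} "
        f"({percentile(x, 25, pct_method):.2f}, {percentile(x, 75, pct_method):.2f})"
    )
    return fmt(a), fmt(b)


def compare_groups(
    values_a,
    values_b,
    parameter: str = "",
    percentile_method: str = "weighted",
    test: str = "auto",
    paired: bool = False,
) -> GroupComparison:
    """Normality-gated two-group comparison.

    Both groups normal (Shapiro–Wilk p >= 0.05) -> two-sided unpaired
    Student's t with mean ± SD summaries; otherwise two-sided Mann–Whitney U
    (exact when min(n) <= 8 and tie-free, else the tie-corrected normal
    approximation) with median (P25, P75) summaries.  ``test`` may force
    either path ("t" / "mann_whitney") instead of gating on normality.
    """
    if paired:
        raise NotImplementedError("only unpaired comparisons are provided")
    a = np.asarray(pd.Series(values_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(values_b).dropna(), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    if test == "auto":
        normal = normality_gate(a).is_normal and normality_gate(b).is_normal
    elif test in ("t", "mann_whitney"):
        normal = test == "t"
    else:
        raise ValueError("test must be 'auto', 't' or 'mann_whitney'")
    if normal:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        sa, sb = _summaries(a, b, True, percentile_method)
        return GroupComparison(parameter, "t", float(p), len(a), len(b), sa, sb, float(stat))
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    sa, sb = _summaries(a, b, False, percentile_method)
    return GroupComparison(parameter, "mann_whitney", float(p), len(a), len(b), sa, sb, float(stat))


def compare_rates(flags_a, flags_b, parameter: str = "") -> GroupComparison:
    """Pearson chi-square (no continuity correction) on two binary samples."""
    a = pd.Series(flags_a).dropna().astype(bool)
    b = pd.Series(flags_b).dropna().astype(bool)
    table = np.array([[a.sum(), (~a).sum()], [b.sum(), (~b).sum()]])
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    fmt = lambda s: f"{int(s.sum())} ({100 * s.mean():.2f}%)"
    return GroupComparison(parameter, "chi_square", float(p), len(a), len(b), fmt(a), fmt(b), float(chi2))


def gender_subgroup_report(cohort: pd.DataFrame, percentile_method: str = "weighted") -> pd.DataFrame:
    """Male-vs-female comparison of demographics, labs and imaging scores."""
    males = cohort[cohort["sex"] == "M"]
    females = cohort[cohort["sex"] == "F"]
    continuous = [
        "age", "onset_age", "alpha_gal", "lyso_gb3", "mssi", "mri_age",
        "arwmc", "fazekas", "epvs", "mars", "lacuna", "svds", "gca",
    ]
    rows = []
    for param in continuous:
        a, b = males[param].dropna(), females[param].dropna()
        if len(a) < 2 or len(b) < 2:
            continue
        rows.append(compare_groups(a, b, param, percentile_method))
    for param in ("hypertension", "visual_impairment"):
        a = males[param].dropna() == "Yes"
        b = females[param].dropna() == "Yes"
        rows.append(compare_rates(a, b, param))
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "males": [r.summary_a for r in rows],
            "females": [r.summary_b for r in rows],
            "test": [r.test_used for r in rows],
            "p_value": [r.p_value for r in rows],
            "n_male": [r.n_a for r in rows],
            "n_female": [r.n_b for r in rows],
        }
    )


def spearman_matrix(
    rmp_table: pd.DataFrame,
    clinical_table: pd.DataFrame,
    key: str = "patient_id",
) -> pd.DataFrame:
    """Pairwise-complete Spearman correlations, long format.

    Every numeric column of ``rmp_table`` is correlated against every
    numeric column of ``clinical_table`` (tables joined on ``key``); cells
    with fewer than 3 complete pairs are omitted.  Two-sided p values use
    the t approximation; no multiple-testing adjustment is applied.
    """
    merged = rmp_table.merge(clinical_table, on=key, how="inner", suffixes=("", "_clin"))
    rmp_cols = [c for c in rmp_table.columns if c != key and pd.api.types.is_numeric_dtype(rmp_table[c])]
    clin_cols = [
        c if c in merged.columns else c + "_clin"
        for c in clinical_table.columns
        if c != key and pd.api.types.is_numeric_dtype(clinical_table[c])
    ]
    rows = []
    for rc in rmp_cols:
        for cc in clin_cols:
            sub = merged[[rc, cc]].dropna()
            if len(sub) < 3:
                continue
            rho, p = sps.spearmanr(sub[rc], sub[cc])
            rows.append(
                {"rmp": rc, "clinical": cc.removesuffix("_clin"),
                 "spearman_r": float(rho), "p_value": float(p), "n": len(sub)}
            )
    return pd.DataFrame(rows)


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    threshold: float


def roc_analysis(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """Empirical ROC: trapezoidal AUC, bootstrap CI, Youden operating point.

    The 95% CI comes from a stratified bootstrap (positives and negatives
    resampled separately); the operating point maximises J = sens + spec − 1.
    """
    from sklearn.metrics import roc_curve

    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.argmax(j))
    rng = np.random.default_rng(seed)
    pos, neg = s[y], s[~y]
    boots = []
    for _ in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        bs = np.concatenate([bp, bn])
        by = np.concatenate([np.ones(len(bp), bool), np.zeros(len(bn), bool)])
        f, t, _ = roc_curve(by, bs)
        boots.append(np.trapezoid(t, f))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RocResult(auc, float(lo), float(hi), float(tpr[best]), float(1 - fpr[best]), float(thr[best]))


def mssi_severity_roc(scores, mssi, cutoff: float = 20.0, **kwargs) -> RocResult:
    """ROC of a vascular score against moderate-to-severe disease (MSSI >= cutoff)."""
    df = pd.DataFrame({"s": scores, "m": mssi}).dropna()
    return roc_analysis(df["s"], df["m"] >= cutoff, **kwargs)


def cohort_summary(cohort: pd.DataFrame, percentile_method: str = "weighted") -> pd.DataFrame:
    """Descriptive table: labs as mean ± SD, imaging scores as median (P25, P75)."""
    if cohort.empty:
        return pd.DataFrame(columns=["parameter", "summary", "n", "n_missing"])
    rows = []
    for col in ("age", "onset_age", "alpha_gal", "lyso_gb3", "mssi", "mri_age"):
        if col not in cohort:
            continue
        vals = cohort[col].dropna()
        if len(vals) == 0:
            continue
        rows.append(
            {"parameter": col, "summary": f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}",
             "mean": float(vals.mean()), "median": percentile(vals, 50, percentile_method),
             "n": len(vals), "n_missing": int(cohort[col].isna().sum())}
        )
    for col in ORDINAL_MAXIMA:
        if col not in cohort:
            continue
        vals = cohort[col].dropna()
        if len(vals) == 0:
            continue
        med = percentile(vals, 50, percentile_method)
        p25 = percentile(vals, 25, percentile_method)
        p75 = percentile(vals, 75, percentile_method)
        rows.append(
            {"parameter": col, "summary": f"{med:g} ({p25:g}, {p75:g})",
             "mean": float(vals.mean()), "median": med,
             "n": len(vals), "n_missing": int(cohort[col].isna().sum())}
        )
    return pd.DataFrame(rows)


def correlation_heatmap(corr_long: pd.DataFrame, path: str | Path) -> None:
    """Optional matrix heatmap of a long-format correlation table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = corr_long.pivot(index="clinical", columns="rmp", values="spearman_r")
    fig, ax = plt.subplots(figsize=(0.4 * len(pivot.columns) + 2, 0.4 * len(pivot) + 2))
    im = ax.imshow(pivot.values, cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=90)
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    fig.colorbar(im, ax=ax, label="Spearman r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
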
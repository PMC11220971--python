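"""Subgroup characterization: group comparisons, regional tau, progression.

Continuous cognitive-reserve factors are compared across latent subgroups
with Kruskal-Wallis omnibus tests and Dunn's post hoc pairwise z-tests,
Hochberg-corrected within each variable's pairwise family; categorical
factors use Pearson's chi-squared (Fisher's exact when expected counts are
small).  Regional tau-PET SUVR is regressed on subgroup per ROI with
Benjamini-Hochberg FDR control across regions, and time to clinical
progression is compared with Kaplan-Meier curves and a log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests


def example_roi_table() -> pd.DataFrame:
    """Bundled example: per-ROI tau-SUVR regression estimates and raw p-values
    for the 33 bilateral FreeSurfer cortical regions, as published for a
    preclinical-AD subgroup analysis.  Used to demonstrate FDR adjustment."""
    with resources.files("crtraj.data").joinpath("roi_tau_regression.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# rank-based omnibus and post hoc tests
# ---------------------------------------------------------------------------


def kruskal_wallis(values, groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-squared p on k-1 df."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.all(values == values[0]):
        return 0.0, len(levels) - 1, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), len(levels) - 1, float(p)


def dunn_posthoc(values, groups) -> pd.DataFrame:
    """Dunn's pairwise z-tests on mean ranks with tie-corrected pooled variance.

    Returns one row per unordered group pair with the z statistic and
    two-sided raw p-value (adjustment is applied separately).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    n = len(values)
    ranks = stats.rankdata(values)
    # tie correction to the rank variance
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for a, b in combinations(levels, 2):
        ra, rb = ranks[groups == a], ranks[groups == b]
        se = np.sqrt(var_base * (1.0 / len(ra) + 1.0 / len(rb)))
        z = 0.0 if se == 0 else (ra.mean() - rb.mean()) / se
        p = 1.0 if se == 0 else 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, float(z), float(p)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])


def hochberg_adjust(pvalues) -> np.ndarray:
    """Hochberg step-up adjusted p-values, capped at 1, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="simes-hochberg")[1]


def bh_fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR-adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GroupComparisonResult:
    """Omnibus + adjusted pairwise comparison of one variable across subgroups."""

    variable: str
    test: str
    statistic: float
    df: int
    p: float
    pairwise: pd.DataFrame | None = None
    direction: str = ""


def compare_across_groups(values, groups, variable: str = "") -> GroupComparisonResult:
    """Kruskal-Wallis omnibus with Hochberg-corrected Dunn post hoc tests."""
    h, df, p = kruskal_wallis(values, groups)
    pw = dunn_posthoc(values, groups)
    pw["p_adjusted"] = hochberg_adjust(pw["p_raw"].to_numpy())
    pw["method"] = "dunn+hochberg"
    means = pd.Series(np.asarray(values, dtype=float)).groupby(np.asarray(groups)).median()
    direction = " > ".join(str(g) for g in means.sort_values(ascending=False).index)
    return GroupComparisonResult(variable, "kruskal-wallis", h, df, p, pw, direction)


# ---------------------------------------------------------------------------
# categorical tests
# ---------------------------------------------------------------------------


def categorical_tests(table, seed: int = 0, n_mc: int = 20000) -> tuple[str, float]:
    """Pearson chi-squared by default; Fisher's exact when any expected count < 5.

    2x2 tables use the exact hypergeometric test; larger sparse tables fall
    back to a seeded Monte-Carlo permutation p-value of the chi-squared
    statistic.  Returns ``(test_name, p)``.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.size == 0:
        raise ValueError("need a 2-d contingency table")
    if tab.sum() == 0:
        raise ValueError("empty contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(tab, correction=False)
    if np.all(expected >= 5):
        return "chi-squared", float(p)
    if tab.shape == (2, 2):
        _, p = stats.fisher_exact(tab)
        return "fisher-exact", float(p)
    # r x c exact is combinatorial; use a seeded Monte-Carlo permutation test
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(tab.shape[0]), tab.sum(axis=1).astype(int))
    cols = np.repeat(np.arange(tab.shape[1]), tab.sum(axis=0).astype(int))
    count = 0
    for _ in range(n_mc):
        perm = rng.permutation(cols)
        sim = np.zeros_like(tab)
        np.add.at(sim, (rows, perm), 1.0)
        c2 = ((sim - expected) ** 2 / expected).sum()
        count += c2 >= chi2 - 1e-12
    return "fisher-mc", float((count + 1) / (n_mc + 1))


# ---------------------------------------------------------------------------
# regional tau analysis
# ---------------------------------------------------------------------------


@dataclass
class ROIResult:
    roi: str
    estimate: float
    p_raw: float
    p_fdr: float = np.nan


def roi_tau_analysis(roi_table: pd.DataFrame, labels, contrast: str = "Resilient",
                     factor_coding: bool = False) -> pd.DataFrame:
    """Per-ROI linear regression of tau SUVR on subgroup, BH-FDR corrected.

    Default coding is a single membership indicator for ``contrast`` (one
    estimate per ROI); ``factor_coding=True`` instead codes subgroup as a
    factor and reports the largest-magnitude level contrast.  Missing ROI
    columns are skipped with a warning and the FDR family shrinks
    accordingly.
    """
    labels = np.asarray(labels)
    if factor_coding:
        X = pd.get_dummies(pd.Series(labels), drop_first=True).astype(float)
    else:
        X = pd.DataFrame({"contrast": (labels == contrast).astype(float)})
    X = sm.add_constant(X)
    rows = []
    for roi in roi_table.columns:
        yv = roi_table[roi].to_numpy(dtype=float)
        if np.all(yv == yv[0]):
            rows.append(ROIResult(roi, 0.0, 1.0))
            continue
        res = sm.OLS(yv, X.to_numpy()).fit()
        if factor_coding:
            j = int(np.argmax(np.abs(res.params[1:]))) + 1
        else:
            j = 1
        rows.append(ROIResult(roi, float(res.params[j]), float(res.pvalues[j])))
    out = pd.DataFrame([(r.roi, r.estimate, r.p_raw) for r in rows],
                       columns=["roi", "estimate", "p_raw"])
    out["p_fdr"] = bh_fdr_adjust(out["p_raw"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# survival and trajectory confirmation
# ---------------------------------------------------------------------------


@dataclass
class SurvivalComparison:
    curves: dict
    chi2: float
    df: int
    p: float
    progressed_pct: pd.Series


def km_logrank(time, event, group) -> SurvivalComparison:
    """Kaplan-Meier curves per subgroup with a k-group log-rank test.

    Also reports the crude percentage progressed per group.  Raises if no
    events occurred (the log-rank statistic is undefined).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    if not event.any():
        raise ValueError("no events observed: log-rank statistic undefined")
    curves = {}
    for g in pd.unique(group):
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(time[group == g], event[group == g])
        curves[g] = kmf
    res = multivariate_logrank_test(time, group, event)
    pct = pd.Series(event, dtype=float).groupby(pd.Series(group)).mean() * 100.0
    return SurvivalComparison(curves, float(res.test_statistic),
                              int(res.degrees_of_freedom), float(res.p_value), pct)


def trajectory_contrast(cohort, labels_by_subject: pd.Series,
                        reference: str | None = None) -> pd.DataFrame:
    """Confirmatory linear mixed model: subgroup differences in intercept/slope.

    Fits an ordinary linear mixed model (random intercept + slope) with
    subgroup dummies and subgroup-by-time interactions as fixed effects and
    reports Wald z-tests on each contrast.  ``reference`` picks the
    baseline subgroup (default: the largest).
    """
    vis = cohort.visits.copy()
    lab = labels_by_subject.reindex(vis["subject_id"]).to_numpy()
    vis["label"] = lab
    if reference is None:
        reference = labels_by_subject.value_counts().idxmax()
    levels = [reference] + [l for l in pd.unique(labels_by_subject) if l != reference]
    X = pd.DataFrame({"intercept": np.ones(len(vis)), "time": vis["time"].to_numpy()})
    for l in levels[1:]:
        d = (vis["label"] == l).astype(float).to_numpy()
        X[f"{l}"] = d
        X[f"{l}:time"] = d * vis["time"].to_numpy()
    md = sm.MixedLM(vis["outcome"].to_numpy(), X.to_numpy(), groups=vis["subject_id"].to_numpy(),
                    exog_re=X[["intercept", "time"]].to_numpy())
    with np.errstate(all="ignore"):
        res = md.fit(reml=False, method="lbfgs", maxiter=200, disp=False)
    rows = []
    for j, name in enumerate(X.columns):
        rows.append((name, float(res.params[j]), float(res.bse[j]),
                     float(res.params[j] / res.bse[j]) if res.bse[j] > 0 else np.nan,
                     float(res.pvalues[j])))
    return pd.DataFrame(rows, columns=["term", "estimate", "se", "z", "p"])


def final_visit_comparison(cohort, labels_by_subject: pd.Series) -> GroupComparisonResult:
    """Compare each subject's last observed outcome across subgroups
    (Kruskal-Wallis + Dunn/Hochberg); a regression-to-the-mean check."""
    last = cohort.visits.groupby("subject_id", sort=False).last()["outcome"]
    labels = labels_by_subject.reindex(last.index)
    return compare_across_groups(last.to_numpy(), labels.to_numpy(), "final_visit_outcome")


# ---------------------------------------------------------------------------
# summary table assembly
# ---------------------------------------------------------------------------


def characteristics_table(baseline: pd.DataFrame, labels_by_subject: pd.Series,
                          continuous=(), categorical=(), seed: int = 0) -> pd.DataFrame:
    """Per-subgroup mean (SD) / n (%) summaries with omnibus p-values.

    Continuous variables get Kruskal-Wallis p-values, categorical ones
    chi-squared/Fisher — the style of a cohort-characteristics table.
    """
    lab = labels_by_subject.reindex(baseline.index)
    groups = pd.unique(lab.dropna())
    rows = []
    for var in continuous:
        vals = baseline[var].astype(float)
        ok = vals.notna() & lab.notna()
        try:
            _, _, p = kruskal_wallis(vals[ok].to_numpy(), lab[ok].to_numpy())
        except ValueError:
            p = np.nan
        row = {"variable": var, "type": "continuous", "p": p}
        for g in groups:
            sub = vals[ok & (lab == g)]
            row[str(g)] = f"{sub.mean():.2f} ({sub.std(ddof=1):.2f})"
        rows.append(row)
    for var in categorical:
        vals = baseline[var]
        ok = vals.notna() & lab.notna()
        tab = pd.crosstab(vals[ok], lab[ok])
        try:
            _, p = categorical_tests(tab.to_numpy(), seed=seed)
        except ValueError:
            p = np.nan
        row = {"variable": var, "type": "categorical", "p": p}
        for g in groups:
            if g in tab.columns:
                top = tab[g].idxmax()
                row[str(g)] = f"{top}: {tab[g].max()} ({100 * tab[g].max() / tab[g].sum():.0f}%)"
        rows.append(row)
    return pd.DataFrame(rows)
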
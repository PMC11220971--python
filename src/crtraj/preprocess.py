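"""Raw tabular inputs -> analysis cohort.

Covers inclusion filtering (baseline anchored to the first tau-PET scan,
>= 2 cognitive timepoints, complete covariates), head-size adjustment of
hippocampal volume, the PACC-5 z-score composite, the cross-sectional
cognitive-reserve residual, published positivity thresholds, and the
cognitive-reserve factor scores (activity averages, occupational
complexity, neighborhood-deprivation tertiles, CDR progression events).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import LongitudinalCohort

#: Published amyloid-positivity threshold (DVR, strict >).
ABETA_POSITIVITY_THRESHOLD = 1.185
#: Published hippocampal-atrophy threshold (mm^3, strict <).
HC_ATROPHY_THRESHOLD = 6723.0
#: Inclusion window between cognitive baseline and first tau scan (days, inclusive).
DEFAULT_WINDOW_DAYS = 365


def adjust_hippocampal_volume(raw_hv, etiv, b: float | None = None,
                              mean_etiv: float | None = None):
    """Head-size-corrected hippocampal volume by the regression method.

    ``adjusted = raw - b * (eTIV - mean eTIV)`` where ``b`` is the OLS slope
    of raw volume on eTIV, estimated within the cohort being processed
    unless supplied (reference-stat injection for replicating external
    conventions).  Returns ``(adjusted, b, mean_etiv)``.
    """
    raw_hv = np.asarray(raw_hv, dtype=float)
    etiv = np.asarray(etiv, dtype=float)
    ok = np.isfinite(raw_hv) & np.isfinite(etiv)
    if ok.sum() < len(raw_hv):
        warnings.warn(f"{len(raw_hv) - ok.sum()} subjects excluded pairwise from HV adjustment")
    if ok.sum() < 3 and b is None:
        raise ValueError("need >= 3 complete (raw_hv, eTIV) pairs to estimate the slope")
    if mean_etiv is None:
        mean_etiv = float(np.mean(etiv[ok]))
    if b is None:
        e = etiv[ok]
        if np.var(e) == 0:
            raise ValueError("zero eTIV variance: adjustment slope undefined")
        b = float(np.cov(e, raw_hv[ok], ddof=0)[0, 1] / np.var(e))
    adjusted = raw_hv - b * (etiv - mean_etiv)
    return adjusted, float(b), float(mean_etiv)


def compute_pacc5(component_scores: pd.DataFrame,
                  reference_means=None, reference_sds=None,
                  lower_is_better=(), min_components: int | None = None) -> pd.Series:
    """Cognitive composite: mean of component z-scores against cohort baseline.

    Each of the five component tests is z-scored against the supplied
    reference means/SDs (defaulting to the scores' own column statistics);
    components flagged ``lower_is_better`` (e.g. a timed trail-making score)
    are sign-flipped so higher always means better cognition.  The composite
    is the mean of available z-scores, requiring at least ``min_components``
    non-missing components (default: all).
    """
    comp = component_scores.astype(float)
    cols = list(comp.columns)
    if min_components is None:
        min_components = len(cols)
    elif min_components < len(cols):
        warnings.warn(f"composite allows as few as {min_components}/{len(cols)} components")
    means = pd.Series(reference_means) if reference_means is not None else comp.mean()
    sds = pd.Series(reference_sds) if reference_sds is not None else comp.std(ddof=1)
    if (sds[cols] <= 0).any():
        bad = [c for c in cols if sds[c] <= 0]
        raise ValueError(f"zero reference SD for components: {bad}")
    z = (comp - means[cols]) / sds[cols]
    for c in lower_is_better:
        z[c] = -z[c]
    n_ok = z.notna().sum(axis=1)
    out = z.mean(axis=1)
    out[n_ok < min_components] = np.nan
    if (n_ok == 0).any():
        raise ValueError("some rows have all components missing")
    return out


def apply_inclusion_criteria(visit_table: pd.DataFrame, baseline_table: pd.DataFrame,
                             window_days: int = DEFAULT_WINDOW_DAYS,
                             covariate_columns=("baseline_age", "sex", "abeta", "tau_ec", "adj_hv"),
                             ) -> tuple[LongitudinalCohort, pd.DataFrame]:
    """Build the analysis cohort and an exclusion log.

    ``visit_table`` needs ``subject_id``, ``visit_date`` (ISO-8601) and
    ``outcome``; ``baseline_table`` needs ``subject_id``, ``scan_date`` and
    the model covariates.  The analysis baseline is the earliest cognitive
    visit within ``window_days`` of the tau scan; earlier (retrospective)
    visits are dropped, duplicated timestamps deduplicated keeping the
    first, and subjects retained only with >= 2 remaining visits and
    complete covariates.  Times are years from each subject's baseline.
    """
    vis = visit_table.copy()
    base = baseline_table.copy()
    if base.index.name != "subject_id":
        base = base.set_index("subject_id")
    vis["visit_date"] = pd.to_datetime(vis["visit_date"], format="ISO8601")
    scan = pd.to_datetime(base["scan_date"], format="ISO8601")

    kept_rows, log = [], []
    for sid, grp in vis.groupby("subject_id", sort=False):
        if sid not in base.index:
            log.append((sid, "no baseline record"))
            continue
        grp = grp.sort_values("visit_date")
        dup = grp["visit_date"].duplicated()
        if dup.any():
            warnings.warn(f"subject {sid!r}: {int(dup.sum())} duplicated visit timestamps dropped")
            grp = grp[~dup]
        gap = (grp["visit_date"] - scan[sid]).dt.days.abs()
        in_window = grp[gap <= window_days]
        if in_window.empty:
            log.append((sid, "no cognitive visit within the scan window"))
            continue
        t0 = in_window["visit_date"].iloc[0]
        retained = grp[grp["visit_date"] >= t0]
        if len(retained) < 2:
            log.append((sid, "insufficient timepoints"))
            continue
        covs = base.loc[sid, list(covariate_columns)]
        if covs.isna().any():
            missing = [c for c in covariate_columns if pd.isna(base.loc[sid, c])]
            log.append((sid, f"missing covariates: {missing}"))
            continue
        t = (retained["visit_date"] - t0).dt.days.to_numpy(dtype=float) / 365.25
        for tt, yy in zip(t, retained["outcome"].to_numpy(dtype=float)):
            kept_rows.append((sid, tt, yy))
        log.append((sid, "retained"))

    visits = pd.DataFrame(kept_rows, columns=["subject_id", "time", "outcome"])
    kept_ids = visits["subject_id"].unique() if len(visits) else []
    cohort = LongitudinalCohort(visits, base.loc[kept_ids],
                                covariate_columns=tuple(covariate_columns))
    log_df = pd.DataFrame(log, columns=["subject_id", "reason"])
    return cohort, log_df


def cr_residual(baseline_table: pd.DataFrame, outcome_column: str = "pacc5",
                predictors=("baseline_age", "sex", "abeta", "tau_ec", "adj_hv")) -> pd.Series:
    """Cross-sectional cognitive-reserve residual.

    Standardized residual (observed minus predicted, divided by the
    residual SD on n - p - 1 degrees of freedom) from an OLS regression of
    baseline cognition on age, sex, amyloid, entorhinal tau and adjusted
    hippocampal volume.  Higher values reflect higher cognitive resilience.
    """
    y = baseline_table[outcome_column].astype(float)
    X = sm.add_constant(baseline_table[list(predictors)].astype(float))
    if len(y) <= X.shape[1]:
        raise ValueError("too few subjects for the residual regression")
    res = sm.OLS(y, X).fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design in residual regression")
    resid = res.resid
    s = np.sqrt(resid @ resid / (len(y) - X.shape[1]))
    if s <= 1e-10 * max(float(np.std(y)), 1e-300):
        raise ValueError("degenerate residual standardization: outcome is exactly linear in predictors")
    return resid / s


def threshold_flags(abeta, adj_hv,
                    abeta_threshold: float = ABETA_POSITIVITY_THRESHOLD,
                    atrophy_threshold: float = HC_ATROPHY_THRESHOLD):
    """Published positivity flags: amyloid positive iff ``abeta > 1.185``,
    hippocampal atrophy iff ``adj_hv < 6723`` (boundaries negative, strict)."""
    abeta = np.asarray(abeta, dtype=float)
    adj_hv = np.asarray(adj_hv, dtype=float)
    return abeta > abeta_threshold, adj_hv < atrophy_threshold


def activity_scores(item_responses: pd.DataFrame, past_prefix: str = "past_act_",
                    current_prefix: str = "curr_act_", min_answered: float = 0.8):
    """Past (25-item) and current (11-item) cognitive-activity averages.

    Items are on a 1-5 frequency scale; a score is the mean of answered
    items when at least ``min_answered`` of them are present, else missing.
    Returns ``(past, current)`` Series.
    """
    def score(prefix, n_items):
        cols = [c for c in item_responses.columns if c.startswith(prefix)]
        if len(cols) != n_items:
            warnings.warn(f"expected {n_items} items with prefix {prefix!r}, found {len(cols)}")
        block = item_responses[cols].astype(float)
        valid = block.notna().sum(axis=1) / len(cols)
        out = block.mean(axis=1)
        out[valid < min_answered] = np.nan
        return out

    return score(past_prefix, 25), score(current_prefix, 11)


_DOT_SCALES = {"data": 6, "people": 8, "things": 7}


def occupational_complexity(data, people, things) -> np.ndarray:
    """Summed reversed Dictionary-of-Occupational-Titles ratings, 0-21.

    Raw DOT ratings run 0-6 (data), 0-8 (people), 0-7 (things) with lower =
    more complex; each is reversed so higher means greater complexity, then
    summed (0 = minimal, 21 = maximal complexity).
    """
    out = np.zeros(len(np.atleast_1d(data)), dtype=float)
    for name, arr in zip(_DOT_SCALES, (data, people, things)):
        arr = np.asarray(arr, dtype=float)
        hi = _DOT_SCALES[name]
        if np.nanmin(arr) < 0 or np.nanmax(arr) > hi:
            raise ValueError(f"DOT {name} ratings must lie in [0, {hi}]")
        out = out + (hi - arr)
    return out


def adi_tertiles(national_adi, reference=None) -> pd.Categorical:
    """Neighborhood-deprivation tertiles from a reference ADI distribution.

    Cut points are the 33.3rd/66.7th percentiles of ``reference`` (defaults
    to the values being categorized, mirroring the wider-cohort convention);
    labels: Lowest / Intermediate / Highest deprivation.
    """
    vals = np.asarray(national_adi, dtype=float)
    ref = np.asarray(reference, dtype=float) if reference is not None else vals
    ref = ref[np.isfinite(ref)]
    c1, c2 = np.quantile(ref, [1 / 3, 2 / 3])
    labels = ["Lowest", "Intermediate", "Highest"]
    if c1 == c2:
        warnings.warn("degenerate ADI reference distribution: single category")
        cats = np.where(np.isfinite(vals), "Lowest", None)
        return pd.Categorical(cats, categories=labels, ordered=True)
    cats = np.select([vals <= c1, vals <= c2], labels[:2], default=labels[2])
    cats = np.where(np.isfinite(vals), cats, None)
    return pd.Categorical(cats, categories=labels, ordered=True)


@dataclass
class ProgressionEvent:
    time: float
    event: bool


def progression_events(cdr_table: pd.DataFrame) -> pd.DataFrame:
    """Time to clinical progression from per-subject CDR series.

    The event is the first of two consecutive visits with a nonzero global
    CDR (0.5, 1 or 2) — timed at the first visit of the pair — or a final
    visit with a nonzero score; non-progressors are censored at their last
    CDR assessment.  Subjects with empty series are dropped (logged).
    Returns a frame indexed by subject with ``time_to_event`` (same units
    as the input times) and ``event``.
    """
    rows = []
    for sid, grp in cdr_table.groupby("subject_id", sort=False):
        grp = grp.sort_values("time")
        t = grp["time"].to_numpy(dtype=float)
        s = grp["cdr_global"].to_numpy(dtype=float)
        if len(t) == 0:
            continue
        bad = set(np.unique(s)) - {0.0, 0.5, 1.0, 2.0}
        if bad:
            raise ValueError(f"subject {sid!r}: CDR scores outside {{0, 0.5, 1, 2}}: {sorted(bad)}")
        event_time = None
        for j in range(len(s) - 1):
            if s[j] > 0 and s[j + 1] > 0:
                event_time = t[j]
                break
        if event_time is None and s[-1] > 0:
            event_time = t[-1]
        if event_time is not None:
            rows.append((sid, event_time, True))
        else:
            rows.append((sid, t[-1], False))
    if not rows:
        warnings.warn("no usable CDR series; survival analysis will be empty")
    return pd.DataFrame(rows, columns=["subject_id", "time_to_event", "event"]).set_index("subject_id")
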
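"""Candidate enumeration, grid-search estimation and favored-model selection.

The class-enumeration procedure: one-class models are fitted for each link
family to obtain initial values; every candidate (link family x number of
classes) is then estimated with a short-run grid search — several random
departures from the one-class solution, each optimized for a burn-in number
of iterations, the best interim solution being polished to full convergence.
Candidates that converged and whose smallest modal class holds at least 5%
of the sample are admissible; among those, the favored model is the lowest
sample-size-adjusted BIC with relative entropy above 0.5.  The full ranking
is retained so trajectory plausibility can be reviewed by a human — that
third criterion is advisory, not automated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cohort import LongitudinalCohort
from .lcmm import (
    FitControl,
    FittedModel,
    LikelihoodEngine,
    ModelSpec,
    ParameterVector,
    default_init,
    fit,
)
from .links import build_link

DEFAULT_FAMILIES = ("linear", "beta", "splines_equidistant", "splines_quantile")
DEFAULT_CLASS_RANGE = (2, 3, 4, 5, 6, 7)
DEFAULT_N_KNOTS = 5


@dataclass
class CandidateGrid:
    """The candidate model grid plus the per-family one-class initializer specs."""

    specs: list[ModelSpec]
    one_class_specs: dict[str, ModelSpec]

    def __len__(self) -> int:
        return len(self.specs)


@dataclass
class SelectionReport:
    """Per-candidate fit summaries and the favored-model decision trail."""

    table: pd.DataFrame
    favored_index: int | None
    notes: list[str] = field(default_factory=list)

    @property
    def favored_row(self):
        return None if self.favored_index is None else self.table.loc[self.favored_index]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def enumerate_candidates(outcomes, families=DEFAULT_FAMILIES,
                         class_range=DEFAULT_CLASS_RANGE,
                         n_knots: int = DEFAULT_N_KNOTS,
                         **spec_kwargs) -> CandidateGrid:
    """Cartesian product of link families and class counts, deterministic order.

    Under the defaults (4 families x classes 2-7) this yields 24 candidate
    specifications, plus one 1-class initializer spec per family.
    """
    if not families or not class_range:
        raise ValueError("families and class_range must be non-empty")
    outcomes = np.asarray(outcomes, dtype=float)

    def make(family, g):
        nk = n_knots if family.startswith("splines") else 0
        return ModelSpec(g, build_link(family, nk, outcomes), **spec_kwargs)

    specs = [make(fam, g) for fam, g in product(families, class_range)]
    one_class = {fam: make(fam, 1) for fam in families}
    return CandidateGrid(specs, one_class)


def init_from_one_class(fitted_1class: FittedModel, n_classes: int,
                        seed: int = 0, jitter_scale: float | None = None) -> ParameterVector:
    """Seed a G-class start from one-class estimates.

    Shared effects, random-effect covariance, residual SD and link
    parameters are copied; class-specific intercept/slope are the one-class
    values perturbed with Gaussian jitter scaled to the latent-outcome SD
    (default 0.5 x the marginal latent SD); membership logits start at 0.
    ``n_classes=1`` or ``jitter_scale=0`` returns the degenerate copy.
    """
    if not fitted_1class.converged:
        raise ValueError("one-class initializer did not converge")
    src = fitted_1class.params
    spec = fitted_1class.spec
    if n_classes == 1:
        return src.copy()
    rng = np.random.default_rng(seed)
    q = spec.n_class_coef
    latent_sd = np.sqrt(np.trace(src.B) + src.sigma_eps**2)
    scale = 0.5 * latent_sd if jitter_scale is None else jitter_scale
    delta = np.tile(src.delta[0], (n_classes, 1)) + rng.normal(0.0, scale, size=(n_classes, q))
    if scale == 0:
        delta = np.tile(src.delta[0], (n_classes, 1))
    if spec.link.estimated and "intercept" in spec.class_design:
        j = spec.class_design.index("intercept")
        delta[0, j] = 0.0
    omega = np.ones(n_classes - 1) if spec.class_variance_scaling else None
    return ParameterVector(np.zeros(n_classes - 1), src.beta.copy(), delta,
                           src.b_chol.copy(), src.sigma_eps, src.eta.copy(), omega)


def _kmeans_departure(cohort: LongitudinalCohort, spec: ModelSpec,
                      one_class_fit: FittedModel, seed: int) -> ParameterVector:
    """Structured departure: cluster per-subject OLS (intercept, slope) of the
    one-class latent outcome and seed class coefficients at the cluster centers."""
    from sklearn.cluster import KMeans

    from .links import link_transform

    G = spec.n_classes
    src = one_class_fit.params
    link = spec.link.with_eta(src.eta)
    feats = []
    for sid, grp in cohort.visits.groupby("subject_id", sort=False):
        t = grp["time"].to_numpy(dtype=float)
        h, _ = link_transform(grp["outcome"].to_numpy(dtype=float), link)
        A = np.column_stack([np.ones_like(t), t])
        coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        feats.append(coef)
    feats = np.asarray(feats)
    km = KMeans(n_clusters=G, n_init=5, random_state=seed % (2**31)).fit(feats)
    order = np.argsort(-np.bincount(km.labels_, minlength=G))  # big classes first
    centers = km.cluster_centers_[order]
    counts = np.maximum(np.bincount(km.labels_, minlength=G)[order], 1)
    props = counts / counts.sum()

    delta = np.tile(src.delta[0], (G, 1)).astype(float)
    for j, col in enumerate(spec.class_design):
        if col == "intercept":
            delta[:, j] = centers[:, 0]
        elif col == "time":
            delta[:, j] = centers[:, 1]
    if spec.link.estimated and "intercept" in spec.class_design:
        j = spec.class_design.index("intercept")
        delta[:, j] -= delta[0, j]
    xi = np.log(props[:-1]) - np.log(props[-1])
    omega = np.ones(G - 1) if spec.class_variance_scaling else None
    return ParameterVector(xi, src.beta.copy(), delta, src.b_chol.copy(),
                           src.sigma_eps, src.eta.copy(), omega)


def grid_search_fit(cohort: LongitudinalCohort, spec: ModelSpec,
                    n_departures: int = 15, burn_iters: int = 30,
                    seed: int = 0, control: FitControl | None = None,
                    one_class_fit: FittedModel | None = None,
                    scale_covariates: bool = True) -> FittedModel:
    """Short-run grid search: random departures, burn-in fits, polish the best.

    ``n_departures`` perturbed starts (derived deterministically from
    ``seed``) are each optimized for at most ``burn_iters`` iterations; the
    departure with the highest interim log-likelihood is then optimized to
    full convergence.  Departure seeds are recorded on the returned model.
    """
    control = control or FitControl()
    if one_class_fit is None:
        spec1 = ModelSpec(1, spec.link, spec.shared_design, spec.class_design,
                          spec.random_design, spec.class_variance_scaling)
        one_class_fit = fit(cohort, spec1, control=control, scale_covariates=scale_covariates)
        if not one_class_fit.converged:
            raise RuntimeError(f"one-class model for link {spec.link.family!r} did not converge")
    if spec.n_classes == 1:
        return one_class_fit

    burn = FitControl(max_iter=burn_iters, tol_param=control.tol_param,
                      tol_loglik=control.tol_loglik, tol_grad=control.tol_grad)
    rng = np.random.default_rng(seed)
    departure_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_departures)]
    best = None
    for k, dep_seed in enumerate(departure_seeds):
        if k == 0:
            # structured departure: trajectory-feature clustering
            try:
                init = _kmeans_departure(cohort, spec, one_class_fit, dep_seed)
            except Exception:
                init = init_from_one_class(one_class_fit, spec.n_classes, seed=dep_seed)
        else:
            init = init_from_one_class(one_class_fit, spec.n_classes, seed=dep_seed)
        try:
            interim = fit(cohort, spec, init=init, control=burn,
                          scale_covariates=scale_covariates)
        except Exception:
            continue
        if np.isfinite(interim.loglik) and (best is None or interim.loglik > best.loglik):
            best = interim
    if best is None:
        failed = one_class_fit
        failed = fit(cohort, spec, init=init_from_one_class(one_class_fit, spec.n_classes, seed=seed),
                     control=FitControl(max_iter=1), scale_covariates=scale_covariates)
        failed.converged = False
        failed.message = "all grid-search departures failed"
        return failed
    final = fit(cohort, spec, init=best.params, control=control,
                scale_covariates=scale_covariates)
    final.convergence["departure_seeds"] = departure_seeds
    return final


def filter_candidates(fits: list[FittedModel], min_prop: float = 0.05) -> list[FittedModel]:
    """Admissible candidates: converged and every modal class holds >= ``min_prop``."""
    return [f for f in fits if f.converged and f.min_class_proportion >= min_prop]


def select_favored(admissible: list[FittedModel],
                   entropy_gate: float = 0.5) -> tuple[FittedModel | None, SelectionReport]:
    """Rank admissible fits by SABIC (ascending); favor the best with entropy above the gate."""
    rows = []
    for k, f in enumerate(admissible):
        rows.append({
            "candidate": k,
            "link_family": f.spec.link.family,
            "n_classes": f.spec.n_classes,
            "converged": f.converged,
            "loglik": f.loglik,
            "npar": f.npar,
            "bic": f.bic,
            "sabic": f.sabic,
            "relative_entropy": f.relative_entropy,
            "min_class_proportion": f.min_class_proportion,
            "entropy_ok": (f.relative_entropy is not None and f.relative_entropy > entropy_gate),
        })
    table = pd.DataFrame(rows)
    notes = []
    if table.empty:
        notes.append("no admissible candidates")
        return None, SelectionReport(table, None, notes)
    ranked = table.sort_values("sabic", kind="mergesort").reset_index(drop=True)
    ranked["sabic_rank"] = np.arange(1, len(ranked) + 1)
    ok = ranked[ranked["entropy_ok"]]
    if ok.empty:
        notes.append("all candidates at or below the relative-entropy gate")
        return None, SelectionReport(ranked, None, notes)
    fav_row = ok.iloc[0]
    fav_idx = int(fav_row.name)
    notes.append(
        f"favored: {fav_row['link_family']} G={int(fav_row['n_classes'])} "
        f"(SABIC={fav_row['sabic']:.3f}, entropy={fav_row['relative_entropy']:.3f}); "
        "trajectory plausibility left to human review"
    )
    return admissible[int(fav_row["candidate"])], SelectionReport(ranked, fav_idx, notes)


def class_trajectory_summaries(fitted: FittedModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-class predicted latent intercept and slope at the covariate means.

    Covariates are centered internally at fit time, so the latent intercept
    at covariate means is the class intercept plus the (scaled) covariate
    contribution at zero.
    """
    spec = fitted.spec
    if "time" not in spec.class_design or "intercept" not in spec.class_design:
        raise ValueError("trajectory summaries need intercept and time in the class design")
    ji = spec.class_design.index("intercept")
    jt = spec.class_design.index("time")
    return fitted.params.delta[:, ji].copy(), fitted.params.delta[:, jt].copy()


def label_classes(fitted: FittedModel, decline_margin: float = 0.05) -> list[str]:
    """Name the classes by trajectory shape.

    For 3-class fits: the class whose slope is the most negative — by more
    than ``decline_margin`` (latent units/year) relative to the runner-up —
    is ``Declining``; of the remainder the higher-intercept class is
    ``Resilient``, the lower ``Normal``.  Slope is keyed before intercept,
    so a declining class may have the lowest baseline.  Other class counts
    (or ties within the margin) get generic ``C1..CG`` labels ordered by
    baseline level, with a warning for ties.
    """
    G = fitted.spec.n_classes
    intercepts, slopes = class_trajectory_summaries(fitted)

    def generic():
        order = np.argsort(np.argsort(intercepts))
        return [f"C{r + 1}" for r in order]

    if G != 3:
        return generic()
    order = np.argsort(slopes)
    steepest, runner_up = order[0], order[1]
    if slopes[runner_up] - slopes[steepest] <= decline_margin:
        warnings.warn("class slopes tie within the decline margin; using generic labels")
        return generic()
    labels = [""] * 3
    labels[steepest] = "Declining"
    rest = [g for g in range(3) if g != steepest]
    hi, lo = (rest[0], rest[1]) if intercepts[rest[0]] >= intercepts[rest[1]] else (rest[1], rest[0])
    labels[hi] = "Resilient"
    labels[lo] = "Normal"
    return labels


def class_proportion_report(assignments, n: int | None = None, decimals: int = 2) -> list[float]:
    """Modal-class percentages, rounded to at most ``decimals`` decimals.

    ``assignments`` is either per-class counts (when ``n`` is given and the
    values sum to it) or a per-subject modal-assignment vector.
    """
    arr = np.asarray(assignments)
    if n is not None and arr.ndim == 1 and arr.sum() == n and (len(arr) < n or n == len(arr) == 1):
        counts = arr.astype(int)
    else:
        _, counts = np.unique(arr, return_counts=True)
        n = len(arr)
    return [float(round(100.0 * c / n, decimals)) for c in counts]


def partition_equivalent(a, b, tol_ari: float = 1.0 - 1e-12) -> bool:
    """Two modal partitions are the same solution when ARI >= tol (label-permutation safe)."""
    return adjusted_rand_score(a, b) >= tol_ari


def replicate_modal_fit(cohort: LongitudinalCohort, spec: ModelSpec,
                        n_repeats: int = 10, seeds=None,
                        n_departures: int = 15, burn_iters: int = 30,
                        control: FitControl | None = None,
                        tol_ari: float = 1.0 - 1e-12) -> tuple[FittedModel, pd.DataFrame]:
    """Repeat the grid search and return the most frequent solution.

    Solutions are grouped by modal-partition equivalence up to label
    permutation (pairwise adjusted Rand = 1); the most frequent group's
    best-log-likelihood member is returned together with a frequency table.
    Frequency ties go to the group with the higher log-likelihood (noted).
    """
    if seeds is None:
        seeds = list(range(n_repeats))
    fits, group_of = [], []
    groups: list[list[int]] = []
    for s in seeds:
        f = grid_search_fit(cohort, spec, n_departures=n_departures,
                            burn_iters=burn_iters, seed=int(s), control=control)
        fits.append(f)
        placed = False
        for gi, members in enumerate(groups):
            if partition_equivalent(f.modal_class, fits[members[0]].modal_class, tol_ari):
                members.append(len(fits) - 1)
                group_of.append(gi)
                placed = True
                break
        if not placed:
            groups.append([len(fits) - 1])
            group_of.append(len(groups) - 1)
    freq = [len(m) for m in groups]
    best_ll = [max(fits[i].loglik for i in m) for m in groups]
    order = sorted(range(len(groups)), key=lambda g: (-freq[g], -best_ll[g]))
    winner = order[0]
    tie = len(order) > 1 and freq[order[1]] == freq[winner]
    member = max(groups[winner], key=lambda i: fits[i].loglik)
    report = pd.DataFrame({
        "group": np.arange(len(groups)),
        "frequency": freq,
        "best_loglik": best_ll,
        "selected": [g == winner for g in range(len(groups))],
    })
    report.attrs["tie_broken_by_loglik"] = bool(tie)
    report.attrs["seeds"] = [int(s) for s in seeds]
    return fits[member], report


def sensitivity_suite(cohort: LongitudinalCohort, favored: FittedModel,
                      seed: int = 0, n_departures: int = 5, burn_iters: int = 20,
                      control: FitControl | None = None,
                      alt_tau_column: str = "tau_it",
                      nonpvc_tau_column: str = "tau_ec_nonpvc") -> pd.DataFrame:
    """Refit the favored configuration under the standard sensitivity variants.

    Variants: (1) without covariates; (2) alternative tau region in place of
    entorhinal tau; (3) non-partial-volume-corrected tau; (4) restricted to
    subjects with >= 3 cognitive timepoints.  Each row reports SABIC,
    entropy, minimum class proportion and modal-assignment agreement
    (adjusted Rand) with the favored model; variants whose column is absent
    are skipped with a logged reason.
    """
    spec = favored.spec
    rows = [{
        "variant": "favored", "sabic": favored.sabic, "relative_entropy": favored.relative_entropy,
        "min_class_proportion": favored.min_class_proportion, "ari_vs_favored": 1.0,
        "converged": favored.converged, "note": "",
    }]

    def run(name, variant_cohort, variant_spec, note=""):
        try:
            f = grid_search_fit(variant_cohort, variant_spec, n_departures=n_departures,
                                burn_iters=burn_iters, seed=seed, control=control)
        except Exception as exc:  # pragma: no cover - defensive
            rows.append({"variant": name, "sabic": np.nan, "relative_entropy": np.nan,
                         "min_class_proportion": np.nan, "ari_vs_favored": np.nan,
                         "converged": False, "note": f"failed: {exc}"})
            return
        common = np.intersect1d(f.subject_ids, favored.subject_ids)
        amask = pd.Series(f.modal_class, index=f.subject_ids).loc[common]
        bmask = pd.Series(favored.modal_class, index=favored.subject_ids).loc[common]
        rows.append({"variant": name, "sabic": f.sabic, "relative_entropy": f.relative_entropy,
                     "min_class_proportion": f.min_class_proportion,
                     "ari_vs_favored": adjusted_rand_score(amask, bmask),
                     "converged": f.converged, "note": note})

    run("no_covariates", cohort,
        ModelSpec(spec.n_classes, spec.link, (), spec.class_design,
                  spec.random_design, spec.class_variance_scaling))

    for name, col in (("alt_tau", alt_tau_column), ("nonpvc_tau", nonpvc_tau_column)):
        if col not in cohort.baseline.columns:
            rows.append({"variant": name, "sabic": np.nan, "relative_entropy": np.nan,
                         "min_class_proportion": np.nan, "ari_vs_favored": np.nan,
                         "converged": False, "note": f"column {col!r} missing; skipped"})
            continue
        shared = tuple(col if c == "tau_ec" else c for c in spec.shared_design)
        run(name, cohort, ModelSpec(spec.n_classes, spec.link, shared, spec.class_design,
                                    spec.random_design, spec.class_variance_scaling))

    counts = cohort.visits.groupby("subject_id", sort=False).size()
    keep = counts[counts >= 3].index
    sub = cohort.subset(keep)
    run("min_3_timepoints", sub, spec, note=f"{len(keep)}/{cohort.n_subjects} subjects")

    return pd.DataFrame(rows)


def run_selection(cohort: LongitudinalCohort,
                  families=DEFAULT_FAMILIES, class_range=DEFAULT_CLASS_RANGE,
                  n_knots: int = DEFAULT_N_KNOTS, n_departures: int = 15,
                  burn_iters: int = 30, seed: int = 0, min_prop: float = 0.05,
                  entropy_gate: float = 0.5, control: FitControl | None = None,
                  **spec_kwargs) -> tuple[FittedModel | None, SelectionReport, list[FittedModel]]:
    """Full enumeration -> grid search -> filter -> rank pipeline.

    Returns the favored model (or None), the report over *all* fitted
    candidates (admissible or not), and the fitted candidates themselves.
    """
    grid = enumerate_candidates(cohort.outcomes(), families, class_range, n_knots, **spec_kwargs)
    one_class_fits = {}
    for fam, spec1 in grid.one_class_specs.items():
        try:
            one_class_fits[fam] = fit(cohort, spec1, control=control)
        except Exception:
            one_class_fits[fam] = None
    fits = []
    for k, spec in enumerate(grid.specs):
        fam = spec.link.family
        base = one_class_fits.get(fam)
        if base is None or not base.converged:
            continue
        fits.append(grid_search_fit(cohort, spec, n_departures=n_departures,
                                    burn_iters=burn_iters, seed=seed + k,
                                    control=control, one_class_fit=base))
    admissible = filter_candidates(fits, min_prop=min_prop)
    favored, report = select_favored(admissible, entropy_gate=entropy_gate)
    # decision trail over the full grid
    full = pd.DataFrame([{
        "link_family": f.spec.link.family, "n_classes": f.spec.n_classes,
        "converged": f.converged, "loglik": f.loglik, "npar": f.npar,
        "sabic": f.sabic, "bic": f.bic, "relative_entropy": f.relative_entropy,
        "min_class_proportion": f.min_class_proportion,
        "admissible": f in admissible,
    } for f in fits])
    report.notes.insert(0, f"{len(fits)} candidates fitted, {len(admissible)} admissible")
    report.table.attrs["full_grid"] = full
    return favored, report, fits
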
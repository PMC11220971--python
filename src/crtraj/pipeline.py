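"""Configuration, I/O dialects and end-to-end pipeline assembly.

The pipeline runs preprocess -> model selection (or fixed-spec replication
for transfer cohorts) -> class labeling -> subgroup characterization, and
writes a reproducible output bundle: analysis-cohort CSV, selection report,
per-subject assignments, characteristics and ROI-style tables, a survival
summary, and a JSON run manifest echoing seeds, configuration and software
versions.  All randomness is keyed to the configured seed, so a rerun with
the same configuration reproduces byte-identical result CSVs (timestamps
live only in the manifest).
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .characterize import (
    characteristics_table,
    compare_across_groups,
    final_visit_comparison,
    km_logrank,
)
from .cohort import LongitudinalCohort
from .lcmm import FitControl, FittedModel, ModelSpec, fit
from .links import build_link
from .preprocess import (
    ABETA_POSITIVITY_THRESHOLD,
    DEFAULT_WINDOW_DAYS,
    HC_ATROPHY_THRESHOLD,
    activity_scores,
    adjust_hippocampal_volume,
    apply_inclusion_criteria,
    cr_residual,
    progression_events,
    threshold_flags,
)
from .selection import (
    DEFAULT_CLASS_RANGE,
    DEFAULT_FAMILIES,
    DEFAULT_N_KNOTS,
    grid_search_fit,
    label_classes,
    replicate_modal_fit,
    run_selection,
)
from .simulate import SyntheticConfig, generate_cohort, generate_cr_factors, generate_progression

_CSV_FLOAT = "%.10g"


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the published constants as defaults."""

    output_dir: str = "crtraj_output"
    seed: int = 0

    # input mode: synthetic generation or CSV paths
    synthetic: bool = True
    synthetic_overrides: dict = field(default_factory=dict)
    visits_path: str | None = None
    baseline_path: str | None = None
    cr_factors_path: str | None = None
    cdr_path: str | None = None

    # candidate grid / estimation
    families: tuple = DEFAULT_FAMILIES
    class_range: tuple = DEFAULT_CLASS_RANGE
    n_knots: int = DEFAULT_N_KNOTS
    n_departures: int = 15
    burn_iters: int = 30
    max_iter: int = 500
    replication_repeats: int = 10
    fixed_spec: dict | None = None  # e.g. {"family": "linear", "n_classes": 3}

    # decision thresholds
    min_class_proportion: float = 0.05
    entropy_gate: float = 0.5
    abeta_threshold: float = ABETA_POSITIVITY_THRESHOLD
    atrophy_threshold: float = HC_ATROPHY_THRESHOLD
    window_days: int = DEFAULT_WINDOW_DAYS

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.families = tuple(cfg.families)
        cfg.class_range = tuple(cfg.class_range)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["families"] = list(self.families)
        d["class_range"] = list(self.class_range)
        return d


def read_cohort(visits_path, baseline_path,
                column_map: dict | None = None) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Read and validate the raw visit and baseline CSV tables.

    CSV dialect: comma-separated, header row required, '.' decimal, empty
    string or ``NA`` as missing, ISO-8601 dates.  ``column_map`` renames
    input columns to the canonical dictionary.  Returns the two tables and
    a validation report (row counts, per-column missingness, bad rows).
    """
    report = {}
    frames = []
    for name, path in (("visits", visits_path), ("baseline", baseline_path)):
        df = pd.read_csv(path, na_values=["", "NA"], keep_default_na=True)
        if df.empty:
            raise ValueError(f"{name} table {path!r} is empty")
        if column_map:
            df = df.rename(columns=column_map)
        report[name] = {"rows": len(df),
                        "missing_by_column": df.isna().sum().to_dict()}
        frames.append(df)
    visits, baseline = frames
    required = {"subject_id", "outcome"}
    missing = required - set(visits.columns)
    if missing:
        raise ValueError(f"visit table missing mandatory columns: {sorted(missing)}")
    bad = visits[pd.to_numeric(visits["outcome"], errors="coerce").isna() & visits["outcome"].notna()]
    if len(bad):
        report["visits"]["non_numeric_outcome_rows"] = bad.index.tolist()
        visits = visits.drop(bad.index)
        visits["outcome"] = visits["outcome"].astype(float)
    return visits, baseline, report


def _spec_from_config(cfg: PipelineConfig, cohort: LongitudinalCohort,
                      family: str, n_classes: int) -> ModelSpec:
    nk = cfg.n_knots if family.startswith("splines") else 0
    return ModelSpec(n_classes, build_link(family, nk, cohort.outcomes()))


def transfer_fit(cohort_b: LongitudinalCohort, favored_family: str, favored_classes: int,
                 repeats: int = 10, seed: int = 0, n_knots: int = DEFAULT_N_KNOTS,
                 n_departures: int = 15, burn_iters: int = 30,
                 control: FitControl | None = None) -> dict:
    """Apply a favored configuration (link family + class count) to a new cohort.

    Runs the repeated grid search (modal solution over ``repeats`` seeded
    replications, grouped up to label permutation) and fits the
    unconditioned (no-covariate) comparator; reports SABIC/entropy for both.
    """
    nk = n_knots if favored_family.startswith("splines") else 0
    link = build_link(favored_family, nk, cohort_b.outcomes())
    spec = ModelSpec(favored_classes, link)
    seeds = [seed + k for k in range(repeats)]
    modal, stability = replicate_modal_fit(cohort_b, spec, n_repeats=repeats, seeds=seeds,
                                           n_departures=n_departures, burn_iters=burn_iters,
                                           control=control)
    uncond_spec = ModelSpec(favored_classes, link, shared_design=())
    uncond = grid_search_fit(cohort_b, uncond_spec, n_departures=n_departures,
                             burn_iters=burn_iters, seed=seed, control=control)
    return {
        "model": modal,
        "stability": stability,
        "unconditioned": uncond,
        "comparison": pd.DataFrame([
            {"model": "conditioned", "sabic": modal.sabic,
             "relative_entropy": modal.relative_entropy,
             "min_class_proportion": modal.min_class_proportion},
            {"model": "unconditioned", "sabic": uncond.sabic,
             "relative_entropy": uncond.relative_entropy,
             "min_class_proportion": uncond.min_class_proportion},
        ]),
    }


def _write_csv(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, index=index, float_format=_CSV_FLOAT, lineterminator="\n")


def _load_inputs(cfg: PipelineConfig):
    """Stage 1: synthetic generation or CSV reading + preprocessing."""
    if cfg.synthetic:
        over = dict(cfg.synthetic_overrides)
        over.setdefault("seed", cfg.seed)
        sim_cfg = SyntheticConfig(**over)
        cohort, truth = generate_cohort(sim_cfg)
        cr = generate_cr_factors(truth, sim_cfg)
        cdr = generate_progression(truth, sim_cfg)
        return cohort, cr, cdr, {"mode": "synthetic", "n_subjects": cohort.n_subjects}

    visits, baseline, report = read_cohort(cfg.visits_path, cfg.baseline_path)
    if "adj_hv" not in baseline.columns and {"raw_hv", "etiv"} <= set(baseline.columns):
        baseline["adj_hv"], b, me = adjust_hippocampal_volume(baseline["raw_hv"], baseline["etiv"])
        report["hv_adjustment"] = {"b": b, "mean_etiv": me}
    if "visit_date" in visits.columns:
        cohort, excl = apply_inclusion_criteria(visits, baseline, window_days=cfg.window_days)
        report["exclusions"] = excl["reason"].value_counts().to_dict()
    else:
        base = baseline.set_index("subject_id") if baseline.index.name != "subject_id" else baseline
        cohort = LongitudinalCohort(visits, base)
    cr = pd.read_csv(cfg.cr_factors_path).set_index("subject_id") if cfg.cr_factors_path else None
    cdr = pd.read_csv(cfg.cdr_path) if cfg.cdr_path else None
    return cohort, cr, cdr, report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the output bundle; returns result objects."""
    cfg = config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    control = FitControl(max_iter=cfg.max_iter)
    results: dict = {}

    # ---- stage: inputs -------------------------------------------------
    cohort, cr, cdr, input_report = _load_inputs(cfg)
    results["cohort"] = cohort
    cohort_out = cohort.visits.merge(
        cohort.baseline.reset_index(), on="subject_id", how="left")
    _write_csv(cohort_out, out / "cohort.csv")

    # ---- stage: selection ---------------------------------------------
    if cfg.fixed_spec:
        spec = _spec_from_config(cfg, cohort, cfg.fixed_spec["family"], cfg.fixed_spec["n_classes"])
        favored, stability = replicate_modal_fit(
            cohort, spec, n_repeats=cfg.replication_repeats,
            seeds=[cfg.seed + k for k in range(cfg.replication_repeats)],
            n_departures=cfg.n_departures, burn_iters=cfg.burn_iters, control=control)
        _write_csv(stability, out / "replication_stability.csv")
        selection_table = pd.DataFrame([{
            "link_family": spec.link.family, "n_classes": spec.n_classes,
            "sabic": favored.sabic, "relative_entropy": favored.relative_entropy,
            "min_class_proportion": favored.min_class_proportion,
            "converged": favored.converged,
        }])
        notes = ["fixed-spec mode: enumeration skipped"]
    else:
        favored, report, fits = run_selection(
            cohort, families=cfg.families, class_range=cfg.class_range,
            n_knots=cfg.n_knots, n_departures=cfg.n_departures,
            burn_iters=cfg.burn_iters, seed=cfg.seed,
            min_prop=cfg.min_class_proportion, entropy_gate=cfg.entropy_gate,
            control=control)
        selection_table = report.table.attrs.get("full_grid", report.table)
        notes = report.notes
        if favored is None:
            _write_csv(selection_table, out / "selection_report.csv")
            raise RuntimeError("selection stage found no favored model; partial outputs kept")
    _write_csv(selection_table, out / "selection_report.csv")
    results["favored"] = favored

    # ---- stage: labeling -----------------------------------------------
    labels = label_classes(favored)
    label_by_subject = pd.Series(
        [labels[g - 1] for g in favored.modal_class], index=favored.subject_ids)
    assignments = favored.assignment_table()
    assignments["label"] = label_by_subject.to_numpy()
    _write_csv(assignments, out / "assignments.csv")
    results["labels"] = labels
    results["assignments"] = assignments

    # ---- stage: characterization ---------------------------------------
    base = cohort.baseline.copy()
    baseline_outcome = cohort.visits.groupby("subject_id", sort=False).first()["outcome"]
    base["pacc5_baseline"] = baseline_outcome
    base["cr_residual"] = cr_residual(base.assign(pacc5=baseline_outcome))
    pos, atro = threshold_flags(base["abeta"], base["adj_hv"],
                                cfg.abeta_threshold, cfg.atrophy_threshold)
    base["abeta_positive"], base["hc_atrophy"] = pos, atro
    continuous = ["baseline_age", "pacc5_baseline", "cr_residual", "abeta", "tau_ec", "adj_hv"]
    categorical = ["sex", "abeta_positive", "hc_atrophy"]
    if cr is not None:
        past, curr = activity_scores(cr)
        cr = cr.assign(past_activity=past, current_activity=curr)
        base = base.join(cr, how="left")
        continuous += [c for c in ("amnart_viq", "education_years", "past_activity",
                                   "current_activity", "cvd_risk") if c in base.columns]
        categorical += [c for c in ("apoe_e4",) if c in base.columns]
    chars = characteristics_table(base, label_by_subject, continuous, categorical, seed=cfg.seed)
    _write_csv(chars, out / "characteristics.csv")
    results["characteristics"] = chars

    pairwise_rows = []
    for var in continuous:
        ok = base[var].notna() & label_by_subject.reindex(base.index).notna()
        if ok.sum() < 3 or label_by_subject[ok].nunique() < 2:
            continue
        res = compare_across_groups(base.loc[ok, var].to_numpy(),
                                    label_by_subject[ok].to_numpy(), var)
        pw = res.pairwise.assign(variable=var, omnibus_p=res.p)
        pairwise_rows.append(pw)
    if pairwise_rows:
        _write_csv(pd.concat(pairwise_rows, ignore_index=True), out / "pairwise_comparisons.csv")

    final_cmp = final_visit_comparison(cohort, label_by_subject)
    _write_csv(final_cmp.pairwise.assign(omnibus_p=final_cmp.p), out / "final_visit_comparison.csv")

    if cdr is not None and len(cdr):
        events = progression_events(cdr)
        ev = events.join(label_by_subject.rename("label"), how="inner").dropna(subset=["label"])
        try:
            surv = km_logrank(ev["time_to_event"], ev["event"], ev["label"])
            surv_df = pd.DataFrame({
                "group": surv.progressed_pct.index,
                "progressed_pct": surv.progressed_pct.to_numpy(),
            })
            surv_df["logrank_chi2"] = surv.chi2
            surv_df["df"] = surv.df
            surv_df["p"] = surv.p
        except ValueError:
            surv_df = pd.DataFrame({"group": [], "progressed_pct": []})
        _write_csv(surv_df, out / "survival_summary.csv")
        results["survival"] = surv_df

    # ---- manifest -------------------------------------------------------
    manifest = {
        "config": cfg.to_dict(),
        "input_report": input_report,
        "selection_notes": notes,
        "labels": labels,
        "class_counts": favored.class_counts.tolist(),
        "software": {"crtraj": __version__, "python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["output_dir"] = out
    return results
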
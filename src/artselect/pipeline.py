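"""Deterministic end-to-end orchestration: cohort -> labels -> forest
screening -> guideline extraction -> evaluation.

The pipeline reproduces the full study design on any cohort with the
expected schema: calibrate deviation tolerances from weekly trend series,
label every objective under the four normal/violation formats, screen out
infeasible objectives, train the forest screening grid on the training
cohort, select the winning cell by the greedy stepwise procedure, distill
the winning forest into a conjunctive guideline rule, and score forest and
rule on the training and held-out validation cohorts.

Every source of randomness derives from one global seed through a counter
scheme (``stage_seed``), so two runs with the same configuration produce
bit-identical artifacts; the manifest records the configuration hash and a
digest of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import SchemaError
from .evaluation import (
    combined_referral_fraction,
    evaluate,
    evaluate_rule,
    train_validation_delta,
)
from .guideline_heuristic import drop_costly_category, extract_rule, remove_redundant_terms
from .labeling import (
    LabelScheme,
    ObjectiveSpec,
    TrendSeries,
    default_objective_specs,
    derive_deviation_tolerance,
    label_quartile,
    label_with_tolerance,
    projected_systematic_change,
    screen_objective_feasibility,
    violation_magnitude,
)
from .rf_screening import (
    FeatureBuilder,
    ScreeningCell,
    category_subsets,
    greedy_stepwise_select,
    screen_cell,
)
from .synthetic_cohort import (
    CohortConfig,
    PatientRecord,
    cohort_to_frame,
    default_cohort_config,
    generate_cohort,
    generate_trend_series,
    write_cohort_csv,
    write_mechanisms_json,
    write_trend_csv,
)
from sklearn.ensemble import RandomForestRegressor

# stage indices for the documented seed-derivation counter
STAGE_COHORT = 0
STAGE_TREND_PATIENTS = 1
STAGE_RF_INITS = 2
STAGE_IMPORTANCE = 3


def stage_seed(global_seed: int, stage: int, k: int = 1):
    """Derive stage seeds from the single global seed (all < 2**31)."""
    ss = np.random.SeedSequence([int(global_seed), int(stage)])
    vals = [int(v % (2 ** 31)) for v in ss.generate_state(k, dtype=np.uint64)]
    return vals[0] if k == 1 else vals


@dataclass
class PipelineConfig:
    """Everything needed for one deterministic pipeline run."""

    seed: int = 0
    n_patients: int = 250
    cohort_csv: str | None = None  # real-data path (schema of write_cohort_csv)
    trend_csv: str | None = None
    categories_json: str | None = None  # predictor -> category map for real data
    objectives: tuple[str, ...] | None = None  # None = all configured
    n_trend_patients: int = 10
    excluded_categories: dict = field(
        default_factory=lambda: {"weight_loss": ("Obs",)}
    )
    n_trees: int = 500
    cv_folds: int = 5
    n_inits: int = 5
    quartile_fraction: float = 0.25
    min_violations_fraction: float = 0.10
    alpha: float = 0.05
    delta_j: float = 0.02
    top_k: int = 8
    max_J_loss: float = 0.10
    output_dir: str = "artselect_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excluded_categories"] = {k: list(v) for k, v in d["excluded_categories"].items()}
        if d["objectives"] is not None:
            d["objectives"] = list(d["objectives"])
        return d


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def read_cohort(path) -> list[PatientRecord]:
    """Typed, validated records from a cohort CSV; row order is chronology."""
    frame = pd.read_csv(path)
    for col in ("patient_id", "role"):
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
    dup = frame["patient_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise SchemaError(f"duplicate patient_id {frame['patient_id'][row]!r} at row {row}")
    bad_role = ~frame["role"].isin(["training", "validation"])
    if bad_role.any():
        row = int(np.flatnonzero(bad_role)[0])
        raise SchemaError(f"invalid role {frame['role'][row]!r} at row {row}")
    planned_cols = [c for c in frame.columns if c.startswith("planned__")]
    delivered_cols = [c for c in frame.columns if c.startswith("delivered__")]
    p_objs = {c.removeprefix("planned__") for c in planned_cols}
    d_objs = {c.removeprefix("delivered__") for c in delivered_cols}
    if p_objs != d_objs:
        raise SchemaError(f"planned/delivered objective columns differ: {sorted(p_objs ^ d_objs)}")
    for col in planned_cols + delivered_cols:
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0])
            raise SchemaError(f"unparsable value in column {col!r} at row {row}")
        if (vals < 0).any():
            row = int(np.flatnonzero(vals < 0)[0])
            raise SchemaError(f"negative value in column {col!r} at row {row}")
    pred_cols = [
        c for c in frame.columns
        if c not in ("patient_id", "role") and not c.startswith(("planned__", "delivered__"))
    ]
    records = []
    for _, r in frame.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(r["patient_id"]),
                predictors={c: float(r[c]) for c in pred_cols},
                planned={o: float(r[f"planned__{o}"]) for o in sorted(p_objs)},
                delivered={o: float(r[f"delivered__{o}"]) for o in sorted(p_objs)},
                cohort_role=str(r["role"]),
            )
        )
    return records


def read_trend_csv(path) -> dict[str, list[TrendSeries]]:
    frame = pd.read_csv(path)
    needed = {"patient_id", "objective", "fraction", "value"}
    missing = needed - set(frame.columns)
    if missing:
        raise SchemaError(f"trend CSV missing columns {sorted(missing)}")
    out: dict[str, list[TrendSeries]] = {}
    for (pid, obj), grp in frame.groupby(["patient_id", "objective"], sort=True):
        grp = grp.sort_values("fraction")
        series = TrendSeries(
            patient_id=str(pid),
            objective=str(obj),
            points=tuple((int(f), float(v)) for f, v in zip(grp["fraction"], grp["value"])),
        )
        out.setdefault(str(obj), []).append(series)
    return out


# ---------------------------------------------------------------------------
# Stage helpers (also used by the CLI subcommands)
# ---------------------------------------------------------------------------

def magnitudes_for(
    records: list[PatientRecord], spec: ObjectiveSpec, paradigm: str
) -> dict[str, float]:
    return {
        r.patient_id: violation_magnitude(
            r.planned[spec.name], r.delivered[spec.name], spec, paradigm
        )
        for r in records
    }


def labels_for(
    records: list[PatientRecord],
    spec: ObjectiveSpec,
    scheme: LabelScheme,
) -> tuple[dict[str, float], dict[str, str]]:
    """(magnitudes, labels) under one format.

    Quartile labels are computed within the given record set, so training
    and validation cohorts are each cut at their own quartile.
    """
    mags = magnitudes_for(records, spec, scheme.paradigm)
    if scheme.tolerance_mode == "deviation":
        labels = {
            pid: label_with_tolerance(m, scheme.deviation_tolerance)
            for pid, m in mags.items()
        }
    else:
        labels = label_quartile(mags, scheme.quartile_fraction)
    return mags, labels


def four_schemes(deviation_tolerance: float, quartile_fraction: float = 0.25):
    """The four normal/violation formats of the study design."""
    return [
        LabelScheme("planning_criteria", "deviation", deviation_tolerance, quartile_fraction),
        LabelScheme("alara", "deviation", deviation_tolerance, quartile_fraction),
        LabelScheme("planning_criteria", "quartile", None, quartile_fraction),
        LabelScheme("alara", "quartile", None, quartile_fraction),
    ]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# The full run
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig,
    cohort_config: CohortConfig | None = None,
    objective_specs: dict[str, ObjectiveSpec] | None = None,
) -> Path:
    """Execute every stage and write all artifacts; returns the run directory.

    With no ``cohort_csv`` in the config, a synthetic cohort is generated
    from ``cohort_config`` (default: the standard simulated study at
    ``config.n_patients`` patients, seeded from the global seed).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs = objective_specs or default_objective_specs()
    manifest: dict = {
        "config": config.to_dict(),
        "package_version": __version__,
        "stages": [],
        "excluded_objectives": {},
    }

    # --- stage: cohort -----------------------------------------------------
    trend_by_obj: dict[str, list[TrendSeries]]
    if config.cohort_csv is None:
        cc = cohort_config or default_cohort_config(
            n_patients=config.n_patients, seed=stage_seed(config.seed, STAGE_COHORT)
        )
        records, mechanisms = generate_cohort(cc)
        write_cohort_csv(records, out / "cohort.csv")
        write_mechanisms_json(mechanisms, out / "planted_mechanisms.json")
        categories_of = {p.name: p.category for p in cc.predictor_specs}
        objective_names = [o.name for o in cc.objectives]
        # weekly trend sub-study: a random subset of training patients
        rng = np.random.default_rng(stage_seed(config.seed, STAGE_TREND_PATIENTS))
        training = [r for r in records if r.cohort_role == "training"]
        idx = rng.choice(len(training), size=min(config.n_trend_patients, len(training)),
                         replace=False)
        trend_patients = [training[i] for i in sorted(idx)]
        trend_by_obj = {
            obj: [generate_trend_series(cc, p, obj) for p in trend_patients]
            for obj in objective_names
        }
        write_trend_csv([s for ss in trend_by_obj.values() for s in ss], out / "trends.csv")
    else:
        records = read_cohort(config.cohort_csv)
        if config.trend_csv is None or config.categories_json is None:
            raise SchemaError("real-data runs need trend_csv and categories_json")
        trend_by_obj = read_trend_csv(config.trend_csv)
        categories_of = json.loads(Path(config.categories_json).read_text())
        objective_names = sorted(records[0].planned)
    manifest["stages"].append("cohort")

    if config.objectives is not None:
        objective_names = [o for o in objective_names if o in set(config.objectives)]

    frame = cohort_to_frame(records)
    train_mask = (frame["role"] == "training").to_numpy()
    train_records = [r for r in records if r.cohort_role == "training"]
    val_records = [r for r in records if r.cohort_role == "validation"]
    builder = FeatureBuilder(frame, categories_of, train_mask)

    # --- stage: tolerance calibration -------------------------------------
    tolerances: dict[str, float] = {}
    systematic: dict[str, list[float]] = {}
    for obj in objective_names:
        series = trend_by_obj.get(obj, [])
        tolerances[obj] = derive_deviation_tolerance(series)
        systematic[obj] = [projected_systematic_change(s) for s in series]
    _dump_json(tolerances, out / "deviation_tolerances.json")
    manifest["stages"].append("calibrate_tolerance")

    # --- stage: labeling + feasibility -------------------------------------
    label_rows = []
    feasibility: dict[str, dict] = {}
    min_violations = math.ceil(config.min_violations_fraction * len(train_records))
    per_obj_schemes: dict[str, list[LabelScheme]] = {}
    for obj in objective_names:
        spec = specs[obj]
        schemes = four_schemes(tolerances[obj], config.quartile_fraction)
        if spec.planning_criterion is None:
            # without a planning criterion the two paradigms coincide
            schemes = [s for s in schemes if s.paradigm == "alara"]
        per_obj_schemes[obj] = schemes
        for scheme in schemes:
            for subset, recs in (("training", train_records), ("validation", val_records)):
                if not recs:
                    continue
                mags, labels = labels_for(recs, spec, scheme)
                for pid in sorted(mags):
                    label_rows.append(
                        {
                            "patient_id": pid,
                            "objective": obj,
                            "paradigm": scheme.paradigm,
                            "tolerance_mode": scheme.tolerance_mode,
                            "magnitude": mags[pid],
                            "label": labels[pid],
                        }
                    )
        primary = schemes[0]
        _, train_labels = labels_for(train_records, spec, primary)
        feas = screen_objective_feasibility(
            train_labels, systematic[obj], tolerances[obj], min_violations
        )
        feasibility[obj] = {"feasible": feas.feasible, "reason": feas.reason, **feas.detail}
        if not feas.feasible:
            manifest["excluded_objectives"][obj] = feas.reason
    pd.DataFrame(label_rows).to_csv(out / "labels.csv", index=False, float_format="%.17g")
    _dump_json(feasibility, out / "feasibility.json")
    manifest["stages"].append("label")

    feasible_objectives = [o for o in objective_names if feasibility[o]["feasible"]]

    # --- stage: screening grid + greedy selection --------------------------
    init_seeds = tuple(stage_seed(config.seed, STAGE_RF_INITS, k=config.n_inits))
    grid_rows = []
    selections: dict[str, dict] = {}
    chosen: dict[str, dict] = {}
    rules: dict[str, object] = {}
    eval_reports: list[dict] = []
    train_frame = frame.loc[train_mask].reset_index(drop=True)
    val_frame = frame.loc[~train_mask].reset_index(drop=True)

    for obj in feasible_objectives:
        spec = specs[obj]
        subsets = category_subsets(exclude=config.excluded_categories.get(obj, ()))
        results = []
        for scheme in per_obj_schemes[obj]:
            mags, labels = labels_for(train_records, spec, scheme)
            pid_order = [r.patient_id for r in train_records]
            y = np.array([mags[p] for p in pid_order])
            lab = np.array([labels[p] for p in pid_order])
            if (lab == "violation").all() or (lab == "normal").all():
                continue  # single-class format cannot be screened
            for subset in subsets:
                cell = ScreeningCell(obj, subset, scheme, init_seeds, config.cv_folds)
                X = builder.matrix(subset).loc[train_mask].reset_index(drop=True)
                res = screen_cell(X, y, lab, cell, n_trees=config.n_trees)
                results.append(res)
                for m in res.per_init:
                    grid_rows.append(
                        {
                            "objective": obj,
                            "categories": "+".join(subset),
                            "paradigm": scheme.paradigm,
                            "tolerance_mode": scheme.tolerance_mode,
                            "seed": m.seed,
                            "auc": m.auc,
                            "youden_J": m.youden[3],
                            "sensitivity": m.youden[1],
                            "specificity": m.youden[2],
                            "threshold": m.youden[0],
                        }
                    )
        report = greedy_stepwise_select(results, alpha=config.alpha, delta_j=config.delta_j)
        selections[obj] = report.to_dict()
        win = report.chosen
        chosen[obj] = {
            "categories": list(win.cell.category_subset),
            "paradigm": win.cell.label_scheme.paradigm,
            "tolerance_mode": win.cell.label_scheme.tolerance_mode,
            "auc_mean": win.auc_mean,
            "auc_sd": win.auc_sd,
            "mean_J": win.mean_J,
            "threshold": win.mean_threshold,
        }

        # --- full-model evaluation ----------------------------------------
        scheme = win.cell.label_scheme
        mags_tr, labels_tr = labels_for(train_records, spec, scheme)
        pid_tr = [r.patient_id for r in train_records]
        y_tr = np.array([mags_tr[p] for p in pid_tr])
        lab_tr = np.array([labels_tr[p] for p in pid_tr]) == "violation"
        X_tr = builder.matrix(win.cell.category_subset).loc[train_mask].reset_index(drop=True)
        X_val = builder.matrix(win.cell.category_subset).loc[~train_mask].reset_index(drop=True)
        forests = [
            RandomForestRegressor(
                n_estimators=config.n_trees, random_state=s, n_jobs=1, max_features=1.0 / 3.0
            ).fit(np.asarray(X_tr, dtype=float), y_tr)
            for s in init_seeds
        ]
        threshold = win.mean_threshold
        score_tr = np.mean([f.predict(np.asarray(X_tr, float)) for f in forests], axis=0)
        full_train = evaluate(
            score_tr >= threshold, lab_tr, scores=score_tr,
            subject="full_model", dataset="training", objective=obj,
        )
        eval_reports.append(full_train.to_dict())
        full_val = None
        if val_records:
            mags_v, labels_v = labels_for(val_records, spec, scheme)
            pid_v = [r.patient_id for r in val_records]
            lab_v = np.array([labels_v[p] for p in pid_v]) == "violation"
            score_v = np.mean([f.predict(np.asarray(X_val, float)) for f in forests], axis=0)
            full_val = evaluate(
                score_v >= threshold, lab_v, scores=score_v,
                subject="full_model", dataset="validation", objective=obj,
            )
            eval_reports.append(full_val.to_dict())

        # --- heuristic distillation ---------------------------------------
        cv_resid_sd = float(
            np.mean([np.std(win.cv_predictions[s] - y_tr) for s in init_seeds])
        )
        rule = extract_rule(
            forests[0], X_tr, y_tr, lab_tr, threshold,
            categories_of=categories_of, top_k=config.top_k, band=cv_resid_sd,
            importance_seed=stage_seed(config.seed, STAGE_IMPORTANCE),
            objective=obj,
        )
        rule = remove_redundant_terms(rule, X_tr)
        for cat in ("Obs", "EMR"):
            rule = drop_costly_category(rule, X_tr, lab_tr, cat, config.max_J_loss)
        rule.performance["training"] = evaluate_rule(rule, X_tr, lab_tr, "training").to_dict()
        rules[obj] = rule
        rule_train = evaluate_rule(rule, X_tr, lab_tr, "training")
        eval_reports.append(rule_train.to_dict())
        if val_records:
            rule_val = evaluate_rule(rule, X_val, lab_v, "validation")
            rule.performance["validation"] = rule_val.to_dict()
            eval_reports.append(rule_val.to_dict())
        rule.to_json(out / f"rule_{obj}.json")
        (out / f"rule_{obj}.txt").write_text(rule.card() + "\n")

    pd.DataFrame(grid_rows).to_csv(out / "screening_grid.csv", index=False, float_format="%.17g")
    _dump_json(selections, out / "selection_report.json")
    _dump_json(chosen, out / "chosen_cells.json")
    manifest["stages"] += ["screen", "select", "extract_rule"]

    # --- stage: evaluation summary -----------------------------------------
    summary: dict = {"reports": eval_reports}
    if rules and len(val_frame):
        summary["combined_referral_fraction_validation"] = combined_referral_fraction(
            list(rules.values()), val_frame
        )
    deltas = []
    for obj in feasible_objectives:
        tr = [r for r in eval_reports
              if r["objective"] == obj and r["subject"] == "full_model" and r["dataset"] == "training"]
        va = [r for r in eval_reports
              if r["objective"] == obj and r["subject"] == "full_model" and r["dataset"] == "validation"]
        if tr and va and tr[0]["J"] is not None and va[0]["J"] is not None:
            deltas.append(tr[0]["J"] - va[0]["J"])
    if deltas:
        summary["mean_full_model_J_train_minus_val"] = float(np.mean(deltas))
    _dump_json(summary, out / "evaluation.json")
    pd.DataFrame(eval_reports).to_csv(out / "summary.csv", index=False, float_format="%.17g")
    manifest["stages"].append("evaluate")

    # --- manifest -----------------------------------------------------------
    manifest["artifacts"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    # the hash covers the semantic configuration and artifact digests, not
    # where the run happened to be written
    hashed = dict(manifest, config={k: v for k, v in manifest["config"].items()
                                    if k != "output_dir"})
    canonical = json.dumps(hashed, sort_keys=True)
    manifest["manifest_hash"] = hashlib.sha256(canonical.encode()).hexdigest()
    _dump_json(manifest, out / "manifest.json")
    return out
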
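"""Synthetic head-and-neck radiotherapy cohorts with planted violation mechanisms.

Real adaptive-radiotherapy (ART) selection studies work from per-patient
tables: chart data (EMR), planning-CT structure volumes (pCT), planned dose
metrics (RTx), and on-unit measurements (Obs), plus a planned and an
estimated-delivered value for each correction objective.  Institutional
cohorts of that kind are rarely shareable, so this module generates cohorts
with the same schema and a known ground truth: delivered values deviate from
planned values through a planted conjunctive threshold mechanism (the
analogue of an "If A AND B then violation likely" guideline) plus Gaussian
noise.  Every downstream stage — labeling, forest screening, rule
extraction — can then be tested for recovery of the planted structure.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

CATEGORIES = ("EMR", "pCT", "RTx", "Obs")

# stream tags so per-(patient, objective) trend draws are independent of the
# main cohort stream but reproducible from the single cohort seed
_TREND_TAG = 0x7E9D


@dataclass(frozen=True)
class PredictorSpec:
    """One predictor column: its category and marginal distribution.

    ``distribution`` is one of ``"truncnorm"`` (params: mean, sd, low, high),
    ``"categorical"`` (params: levels, probs; levels are integer codes), or
    ``"uniform"`` (params: low, high).
    """

    name: str
    category: str
    distribution: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigurationError(
                f"predictor {self.name!r}: unknown category {self.category!r}"
            )
        if self.distribution not in ("truncnorm", "categorical", "uniform"):
            raise ConfigurationError(
                f"predictor {self.name!r}: unknown distribution family "
                f"{self.distribution!r}"
            )


@dataclass(frozen=True)
class RuleTerm:
    """A single threshold condition ``predictor direction cutoff``."""

    predictor: str
    direction: str  # ">=" or "<="
    cutoff: float

    def __post_init__(self) -> None:
        if self.direction not in (">=", "<="):
            raise ConfigurationError(f"term direction must be >= or <=, got {self.direction!r}")

    def satisfied(self, value: float) -> bool:
        return value >= self.cutoff if self.direction == ">=" else value <= self.cutoff


@dataclass(frozen=True)
class PlantedMechanism:
    """Ground-truth conjunctive violation mechanism for one objective.

    When every term is satisfied the mean planned-to-delivered shift is
    ``effect_size`` (in the objective's units, adverse direction positive);
    otherwise it is ``baseline``.
    """

    terms: tuple[RuleTerm, ...]
    effect_size: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not self.effect_size > self.baseline:
            raise ConfigurationError("effect_size must exceed baseline")


@dataclass(frozen=True)
class ObjectiveSim:
    """Simulation wiring for one ART objective.

    ``planned_from`` names the predictor whose value doubles as the planned
    objective value (planned dose metrics are themselves RTx predictors, and
    initial BMI is the planned value of the weight-loss objective).
    ``adverse_sign`` is +1 when an increase is adverse, -1 for a decrease.
    """

    name: str
    planned_from: str
    adverse_sign: int = 1
    noise_sd: float = 1.5
    trend_noise_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.adverse_sign not in (+1, -1):
            raise ConfigurationError("adverse_sign must be +1 or -1")
        if self.noise_sd < 0 or self.trend_noise_sd < 0:
            raise ConfigurationError("noise SDs must be non-negative")


@dataclass
class PatientRecord:
    patient_id: str
    predictors: dict[str, float]
    planned: dict[str, float]
    delivered: dict[str, float]
    cohort_role: str  # "training" | "validation"


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 250
    predictor_specs: tuple[PredictorSpec, ...] = ()
    objectives: tuple[ObjectiveSim, ...] = ()
    planted_rules: dict = field(default_factory=dict)  # objective -> PlantedMechanism
    trend_fractions: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 33)
    training_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 8:
            raise ConfigurationError("n_patients must be >= 8")
        names = [p.name for p in self.predictor_specs]
        if len(names) != len(set(names)):
            raise ConfigurationError("predictor names must be unique")
        for obj in self.objectives:
            if obj.planned_from not in names:
                raise ConfigurationError(
                    f"objective {obj.name!r}: planned_from predictor "
                    f"{obj.planned_from!r} not in predictor_specs"
                )
        for obj_name, mech in self.planted_rules.items():
            if obj_name not in {o.name for o in self.objectives}:
                raise ConfigurationError(f"planted rule for unknown objective {obj_name!r}")
            for term in mech.terms:
                if term.predictor not in names:
                    raise ConfigurationError(
                        f"planted term references missing predictor {term.predictor!r}"
                    )
        if not 0 < self.training_fraction <= 1:
            raise ConfigurationError("training_fraction must be in (0, 1]")
        if list(self.trend_fractions) != sorted(set(self.trend_fractions)):
            raise ConfigurationError("trend_fractions must be strictly increasing")

    def objective(self, name: str) -> ObjectiveSim:
        for obj in self.objectives:
            if obj.name == name:
                return obj
        raise ConfigurationError(f"unknown objective {name!r}")


def _draw_predictor(spec: PredictorSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    p = spec.params
    if spec.distribution == "truncnorm":
        a = (p["low"] - p["mean"]) / p["sd"]
        b = (p["high"] - p["mean"]) / p["sd"]
        return stats.truncnorm.rvs(a, b, loc=p["mean"], scale=p["sd"], size=n, random_state=rng)
    if spec.distribution == "categorical":
        return rng.choice(np.asarray(p["levels"], dtype=float), size=n, p=p["probs"])
    return rng.uniform(p["low"], p["high"], size=n)


def rule_satisfied(mechanism: PlantedMechanism, predictors: dict[str, float]) -> bool:
    """Empty conjunctions are vacuously true."""
    return all(t.satisfied(predictors[t.predictor]) for t in mechanism.terms)


def oracle_labels(records: list[PatientRecord], mechanism: PlantedMechanism) -> dict[str, bool]:
    """Noise-free ground-truth labels: True iff every planted term holds."""
    return {r.patient_id: rule_satisfied(mechanism, r.predictors) for r in records}


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientRecord], dict[str, PlantedMechanism]]:
    """Draw a cohort: predictors, then planned/delivered values per objective.

    delivered = planned + sign * (baseline + (effect - baseline)*[rule holds]
    + N(0, noise_sd)), floored at zero.  Records keep draw order, which is the
    study chronology; the first ``training_fraction`` become the training
    cohort and the remainder the validation cohort.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    columns = {spec.name: _draw_predictor(spec, n, rng) for spec in config.predictor_specs}

    records: list[PatientRecord] = []
    width = max(4, len(str(n)))
    n_train = int(round(config.training_fraction * n))
    for i in range(n):
        preds = {name: float(col[i]) for name, col in columns.items()}
        records.append(
            PatientRecord(
                patient_id=f"P{i:0{width}d}",
                predictors=preds,
                planned={},
                delivered={},
                cohort_role="training" if i < n_train else "validation",
            )
        )

    for obj in config.objectives:
        mech = config.planted_rules.get(obj.name)
        noise = rng.normal(0.0, obj.noise_sd, size=n) if obj.noise_sd > 0 else np.zeros(n)
        for i, rec in enumerate(records):
            planned = rec.predictors[obj.planned_from]
            shift = 0.0
            if mech is not None:
                hit = rule_satisfied(mech, rec.predictors)
                shift = mech.baseline + (mech.effect_size - mech.baseline) * hit
            delivered = planned + obj.adverse_sign * (shift + noise[i])
            rec.planned[obj.name] = planned
            rec.delivered[obj.name] = max(0.0, float(delivered))

    return records, dict(config.planted_rules)


def _trend_rng(config: CohortConfig, patient_id: str, objective: str) -> np.random.Generator:
    entropy = [config.seed, _TREND_TAG, zlib.crc32(patient_id.encode()), zlib.crc32(objective.encode())]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def generate_trend_series(config: CohortConfig, patient: PatientRecord, objective: str):
    """Weekly objective values for one patient.

    The underlying trend is linear from the planned value to the delivered
    value over the treatment course: value(f) = planned + slope*f +
    N(0, trend_noise_sd), with slope = (delivered - planned)/f_last, so the
    final-fraction point equals the delivered value up to the same noise.
    Returns a :class:`artselect.labeling.TrendSeries`.
    """
    from .labeling import TrendSeries  # local import to avoid a cycle

    if not config.trend_fractions:
        raise ConfigurationError("trend_fractions must be non-empty")
    obj = config.objective(objective)
    rng = _trend_rng(config, patient.patient_id, objective)
    fractions = np.asarray(config.trend_fractions, dtype=float)
    planned = patient.planned[objective]
    delivered = patient.delivered[objective]
    slope = (delivered - planned) / fractions[-1]
    noise = (
        rng.normal(0.0, obj.trend_noise_sd, size=fractions.size)
        if obj.trend_noise_sd > 0
        else np.zeros(fractions.size)
    )
    values = planned + slope * fractions + noise
    points = tuple((int(f), float(v)) for f, v in zip(config.trend_fractions, values))
    return TrendSeries(patient_id=patient.patient_id, objective=objective, points=points)


# ---------------------------------------------------------------------------
# Default study conditions: a four-objective head-and-neck cohort
# ---------------------------------------------------------------------------

def default_predictor_specs() -> tuple[PredictorSpec, ...]:
    """Predictor menu patterned on routine head-and-neck ART data collection.

    Marginals are truncated normals (or integer-coded categoricals) centred
    on typical clinical values: cohort age ~59 +/- 10 y, BMI ~27.6 +/- 5.8
    kg/m^2, planned OAR doses placed below their planning objectives
    (brainstem D0.03cc <= 54 Gy, cord <= 48 Gy, parotid Dmean <= 26 Gy,
    constrictor Dmean <= 50 Gy).
    """
    tn = lambda mean, sd, low, high: {"mean": mean, "sd": sd, "low": low, "high": high}
    cat = lambda levels, probs: {"levels": levels, "probs": probs}
    return (
        # EMR: chart demographics, staging, systemic therapy
        PredictorSpec("age", "EMR", "truncnorm", tn(58.7, 10.1, 18, 90)),
        PredictorSpec("gender", "EMR", "categorical", cat([0, 1], [0.88, 0.12])),
        PredictorSpec(
            "cancer_site", "EMR", "categorical",
            cat([0, 1, 2, 3, 4, 5, 6], [0.088, 0.036, 0.080, 0.580, 0.028, 0.144, 0.044]),
        ),
        PredictorSpec(
            "chemo_agent", "EMR", "categorical",
            cat([0, 1, 2, 3, 4], [0.020, 0.080, 0.152, 0.704, 0.044]),
        ),
        PredictorSpec("ecog", "EMR", "categorical", cat([0, 1, 2, 3], [0.40, 0.40, 0.15, 0.05])),
        PredictorSpec("initial_bmi", "EMR", "truncnorm", tn(27.6, 5.8, 16, 50)),
        PredictorSpec("bilateral_treatment", "EMR", "categorical", cat([0, 1], [0.08, 0.92])),
        # pCT: structure volumes at planning (cc)
        PredictorSpec("high_dose_ctv_volume", "pCT", "truncnorm", tn(160, 90, 10, 600)),
        PredictorSpec("low_dose_ctv_volume", "pCT", "truncnorm", tn(210, 80, 30, 700)),
        PredictorSpec("ips_parotid_volume", "pCT", "truncnorm", tn(26, 8, 8, 60)),
        PredictorSpec("cont_parotid_volume", "pCT", "truncnorm", tn(26, 8, 8, 60)),
        PredictorSpec("brainstem_volume", "pCT", "truncnorm", tn(25, 4, 12, 40)),
        # RTx: planned dose metrics (Gy)
        PredictorSpec("planned_brainstem_d0_03cc", "RTx", "truncnorm", tn(28, 12, 5, 55)),
        PredictorSpec("planned_spinal_cord_d0_03cc", "RTx", "truncnorm", tn(40, 4, 20, 48.5)),
        PredictorSpec("planned_constrictor_dmean", "RTx", "truncnorm", tn(45, 5, 25, 52)),
        PredictorSpec("planned_ips_parotid_dmean", "RTx", "truncnorm", tn(32, 9, 10, 70)),
        PredictorSpec("planned_cont_parotid_dmean", "RTx", "truncnorm", tn(24, 4, 10, 40)),
        # Obs: on-unit change measurements relative to planning
        PredictorSpec("delta_neck_diameter", "Obs", "truncnorm", tn(3, 4, -10, 20)),
        PredictorSpec("delta_face_diameter", "Obs", "truncnorm", tn(2, 3, -8, 15)),
        PredictorSpec("delta_bmi", "Obs", "truncnorm", tn(-1.5, 1.3, -8, 3)),
    )


def default_cohort_config(n_patients: int = 250, seed: int = 0) -> CohortConfig:
    """Study conditions for the simulated four-objective ART cohort.

    Planted mechanisms conjoin two predictors at roughly their marginal
    medians, so ~25% of patients satisfy the full conjunction; effect sizes
    of 5-6 Gy against 1.2-1.5 Gy residual noise give violation prevalences in
    the 20-30% range once deviation tolerances are applied.  The weight-loss
    objective is a single-term mechanism on initial BMI with a decrease being
    adverse, and its screening excludes Obs predictors downstream.
    """
    specs = default_predictor_specs()
    objectives = (
        # the combined brainstem/cord objective tracks whichever structure is
        # planned closer to its limit — in this cohort the spinal cord
        # (plans ~40 Gy against a 45 Gy violation threshold)
        ObjectiveSim("brainstem_spinal_cord", "planned_spinal_cord_d0_03cc",
                     adverse_sign=+1, noise_sd=1.5, trend_noise_sd=0.8),
        ObjectiveSim("parotid_dmean", "planned_cont_parotid_dmean",
                     adverse_sign=+1, noise_sd=1.5, trend_noise_sd=0.9),
        ObjectiveSim("constrictor_dmean", "planned_constrictor_dmean",
                     adverse_sign=+1, noise_sd=1.2, trend_noise_sd=0.7),
        ObjectiveSim("weight_loss", "initial_bmi",
                     adverse_sign=-1, noise_sd=1.0, trend_noise_sd=0.7),
    )
    planted = {
        "brainstem_spinal_cord": PlantedMechanism(
            (RuleTerm("planned_brainstem_d0_03cc", ">=", 28.0),
             RuleTerm("planned_spinal_cord_d0_03cc", ">=", 40.0)),
            effect_size=6.0,
        ),
        "parotid_dmean": PlantedMechanism(
            (RuleTerm("planned_cont_parotid_dmean", ">=", 24.0),
             RuleTerm("planned_ips_parotid_dmean", ">=", 32.0)),
            effect_size=6.0,
        ),
        "constrictor_dmean": PlantedMechanism(
            (RuleTerm("planned_constrictor_dmean", ">=", 45.0),
             RuleTerm("delta_neck_diameter", ">=", 3.0)),
            effect_size=5.0,
        ),
        "weight_loss": PlantedMechanism(
            (RuleTerm("initial_bmi", ">=", 27.0),),
            effect_size=3.0,
            baseline=0.5,
        ),
    }
    return CohortConfig(
        n_patients=n_patients,
        predictor_specs=specs,
        objectives=objectives,
        planted_rules=planted,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """One row per patient: id, role, predictors, planned__*/delivered__*."""
    rows = []
    for rec in records:
        row: dict = {"patient_id": rec.patient_id, "role": rec.cohort_role}
        row.update(rec.predictors)
        for obj, v in rec.planned.items():
            row[f"planned__{obj}"] = v
        for obj, v in rec.delivered.items():
            row[f"delivered__{obj}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(records: list[PatientRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def write_trend_csv(series_list, path) -> None:
    rows = [
        {"patient_id": s.patient_id, "objective": s.objective, "fraction": f, "value": v}
        for s in series_list
        for f, v in s.points
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_mechanisms_json(mechanisms: dict[str, PlantedMechanism], path) -> None:
    payload = {
        obj: {
            "terms": [
                {"predictor": t.predictor, "direction": t.direction, "cutoff": t.cutoff}
                for t in mech.terms
            ],
            "effect_size": mech.effect_size,
            "baseline": mech.baseline,
        }
        for obj, mech in mechanisms.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def noise_free(config: CohortConfig) -> CohortConfig:
    """Copy of the config with all residual and trend noise switched off."""
    return replace(
        config,
        objectives=tuple(
            replace(o, noise_sd=0.0, trend_noise_sd=0.0) for o in config.objectives
        ),
    )
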
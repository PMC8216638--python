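"""Shared fixtures: a compact planted-mechanism study used across modules.

The planted cohort has two informative RTx predictors (planned brainstem and
spinal-cord near-maximum doses) driving a 6 Gy violation effect through the
conjunction brainstem >= 28 Gy AND cord >= 40 Gy (both near their marginal
medians, so roughly a quarter of patients satisfy it), against 1.5 Gy
residual noise.  The other categories carry pure noise, which lets tests
check recovery of both the informative category and the planted rule.
"""

from __future__ import annotations

import numpy as np
import pytest

from artselect.labeling import LabelScheme, ObjectiveSpec, violation_magnitude
from artselect.rf_screening import FeatureBuilder
from artselect.synthetic_cohort import (
    CohortConfig,
    ObjectiveSim,
    PlantedMechanism,
    PredictorSpec,
    RuleTerm,
    cohort_to_frame,
    generate_cohort,
)

PLANTED_CATEGORIES = {
    "age": "EMR",
    "initial_bmi": "EMR",
    "ctv_volume": "pCT",
    "parotid_volume": "pCT",
    "planned_brainstem": "RTx",
    "planned_cord": "RTx",
    "planned_parotid": "RTx",
    "delta_neck": "Obs",
}

BRAINSTEM_SPEC = ObjectiveSpec("brainstem", "D0.03cc", 54.0, "increase", "Gy")

# labels use a fixed deviation tolerance of half the planted effect, so label
# flips require a noise excursion beyond two residual SDs
PLANTED_TOLERANCE = 3.0
PLANTED_EFFECT = 6.0
PLANTED_CUTOFFS = {"planned_brainstem": 28.0, "planned_cord": 40.0}

INIT_SEEDS = (11, 22, 33, 44, 55)


def planted_config(seed: int, n: int = 250, noise: float = 1.5) -> CohortConfig:
    tn = lambda m, s, lo, hi: {"mean": m, "sd": s, "low": lo, "high": hi}
    specs = (
        PredictorSpec("age", "EMR", "truncnorm", tn(59, 10, 18, 90)),
        PredictorSpec("initial_bmi", "EMR", "truncnorm", tn(27.6, 5.8, 16, 50)),
        PredictorSpec("ctv_volume", "pCT", "truncnorm", tn(160, 90, 10, 600)),
        PredictorSpec("parotid_volume", "pCT", "truncnorm", tn(26, 8, 8, 60)),
        PredictorSpec("planned_brainstem", "RTx", "truncnorm", tn(28, 12, 5, 55)),
        PredictorSpec("planned_cord", "RTx", "truncnorm", tn(40, 4, 20, 48.5)),
        PredictorSpec("planned_parotid", "RTx", "truncnorm", tn(32, 9, 10, 70)),
        PredictorSpec("delta_neck", "Obs", "truncnorm", tn(3, 4, -10, 20)),
    )
    objective = ObjectiveSim("brainstem", "planned_brainstem", noise_sd=noise)
    mech = PlantedMechanism(
        (
            RuleTerm("planned_brainstem", ">=", PLANTED_CUTOFFS["planned_brainstem"]),
            RuleTerm("planned_cord", ">=", PLANTED_CUTOFFS["planned_cord"]),
        ),
        effect_size=PLANTED_EFFECT,
    )
    return CohortConfig(
        n_patients=n,
        predictor_specs=specs,
        objectives=(objective,),
        planted_rules={"brainstem": mech},
        seed=seed,
    )


def planted_study(seed: int, n: int = 250, noise: float = 1.5):
    """(records, frame, train_mask, builder, magnitudes, labels01) for one seed."""
    config = planted_config(seed, n=n, noise=noise)
    records, _ = generate_cohort(config)
    frame = cohort_to_frame(records)
    train_mask = (frame["role"] == "training").to_numpy()
    builder = FeatureBuilder(frame, PLANTED_CATEGORIES, train_mask)
    mags = np.array(
        [
            violation_magnitude(
                r.planned["brainstem"], r.delivered["brainstem"], BRAINSTEM_SPEC, "alara"
            )
            for r in records
        ]
    )
    labels = (mags >= PLANTED_TOLERANCE).astype(int)
    return records, frame, train_mask, builder, mags, labels


ALARA_DEVIATION = LabelScheme("alara", "deviation", PLANTED_TOLERANCE)


@pytest.fixture(scope="session")
def planted_study_seed0():
    return planted_study(0)


@pytest.fixture(scope="session")
def tiny_pipeline_runs(tmp_path_factory):
    """Two identical small pipeline runs, for determinism and artifact tests.

    Uses the weight-loss objective (Obs excluded, two label formats) to keep
    the screening grid small.
    """
    from artselect.pipeline import PipelineConfig, run_pipeline

    dirs = []
    for name in ("run_a", "run_b"):
        out = tmp_path_factory.mktemp("pipe") / name
        cfg = PipelineConfig(
            seed=7,
            n_patients=100,
            n_trees=15,
            objectives=("weight_loss",),
            output_dir=str(out),
        )
        dirs.append(run_pipeline(cfg))
    return dirs
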
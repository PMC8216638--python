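"""Normal-vs-violation labeling of delivered objective values.

An inter-fractional change that could raise the risk of an adverse effect is
a *violation* warranting an ART replan assessment; everything else is
*normal*.  Two reference paradigms are supported:

* **planning-criteria** — the delivered value is compared against the
  planning criterion when the plan met it, and against the planned value when
  the plan already exceeded it.  Both branches collapse to one formula with
  reference ``max(criterion, planned)``.
* **ALARA** ("as low as reasonably achievable") — the delivered value is
  compared against the planned value for every patient, flagging any adverse
  drift regardless of the criterion.

Each paradigm combines with one of two tolerance modes: a *deviation
tolerance* calibrated from longitudinal trend residuals (twice the
cross-patient SD of actual-minus-projected final values, separating random
from systematic change), or a *worst-quartile* cut that flags the fixed
fraction of patients with the largest violation magnitudes.

Decrease-type objectives (weight loss, target coverage) are sign-flipped
before labeling so the adverse direction is always positive; magnitudes are
signed and never clipped, preserving ordering information below tolerance
for the downstream regression models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, InsufficientDataError


@dataclass(frozen=True)
class ObjectiveSpec:
    """An ART objective's metric, planning criterion, and adverse direction.

    ``planning_criterion`` is present for dosimetric objectives (units Gy)
    and absent for volumetric/clinical ones, which have no predefined
    planning objective.
    """

    name: str
    metric: str  # e.g. "D0.03cc", "Dmean", "volume", "BMI"
    planning_criterion: float | None
    adverse_direction: str = "increase"  # "increase" | "decrease"
    units: str = "Gy"

    def __post_init__(self) -> None:
        if self.adverse_direction not in ("increase", "decrease"):
            raise ConfigurationError("adverse_direction must be 'increase' or 'decrease'")

    @property
    def is_dosimetric(self) -> bool:
        return self.units == "Gy"

    @property
    def sign(self) -> int:
        return +1 if self.adverse_direction == "increase" else -1


@dataclass(frozen=True)
class LabelScheme:
    """One of the four normal/violation formats.

    paradigm x tolerance_mode: {planning_criteria, alara} x
    {deviation, quartile}.  ``deviation_tolerance`` is required (and used)
    only in deviation mode; ``quartile_fraction`` only in quartile mode.
    """

    paradigm: str
    tolerance_mode: str
    deviation_tolerance: float | None = None
    quartile_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.paradigm not in ("planning_criteria", "alara"):
            raise ConfigurationError(f"unknown paradigm {self.paradigm!r}")
        if self.tolerance_mode not in ("deviation", "quartile"):
            raise ConfigurationError(f"unknown tolerance_mode {self.tolerance_mode!r}")
        if self.tolerance_mode == "deviation":
            if self.deviation_tolerance is None or self.deviation_tolerance < 0:
                raise ConfigurationError("deviation mode requires deviation_tolerance >= 0")
        if not 0 < self.quartile_fraction <= 1:
            raise ConfigurationError("quartile_fraction must be in (0, 1]")

    @property
    def key(self) -> str:
        return f"{self.paradigm}:{self.tolerance_mode}"


@dataclass(frozen=True)
class TrendSeries:
    """Weekly objective values for one patient, indexed by fraction number."""

    patient_id: str
    objective: str
    points: tuple  # of (fraction: int, value: float)

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ConfigurationError("a trend series needs at least 3 points")
        fracs = [f for f, _ in self.points]
        if fracs != sorted(set(fracs)):
            raise ConfigurationError("fractions must be strictly increasing")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for f, _ in self.points], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.points], dtype=float)


@dataclass(frozen=True)
class LabeledOutcome:
    patient_id: str
    objective: str
    magnitude: float  # signed, adverse direction positive
    label: str  # "normal" | "violation"


@dataclass(frozen=True)
class FeasibilityResult:
    feasible: bool
    reason: str | None = None  # "low_prevalence" | "random_dominates"
    detail: dict = field(default_factory=dict)


def fit_linear_trend(series: TrendSeries) -> tuple[float, float, float]:
    """OLS fit of value on fraction; returns (slope, intercept, projected_final).

    ``projected_final`` evaluates the fitted line at the last fraction
    present, the linearly projected counterpart of the last-acquired
    on-unit estimate.
    """
    x, y = series.fractions, series.values
    if np.ptp(x) == 0:
        raise DegenerateInputError("all fractions identical; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    projected_final = float(slope * x[-1] + intercept)
    return float(slope), float(intercept), projected_final


def derive_deviation_tolerance(series_set: list[TrendSeries]) -> float:
    """Random-error deviation tolerance from weekly trend residuals.

    For each patient the difference d = (actual final value) - (linearly
    projected final value) captures random, non-systematic variation.  The
    tolerance is twice the sample SD (n-1 denominator) of these differences
    across patients.
    """
    if len(series_set) < 2:
        raise InsufficientDataError("tolerance calibration needs >= 2 trend series")
    diffs = []
    for s in series_set:
        _, _, projected = fit_linear_trend(s)
        diffs.append(s.values[-1] - projected)
    return float(2.0 * np.std(diffs, ddof=1))


def violation_magnitude(
    planned: float, delivered: float, spec: ObjectiveSpec, paradigm: str
) -> float:
    """Signed excess of the delivered value over the paradigm's reference.

    Decrease-type objectives are sign-flipped first so adverse change is
    positive.  Under ALARA the reference is the planned value; under the
    planning-criteria paradigm it is max(criterion, planned) when a
    criterion exists — reproducing both the met-criterion and
    exceeded-criterion branches — and the planned value otherwise.
    """
    if not (math.isfinite(planned) and math.isfinite(delivered)):
        raise ConfigurationError("planned/delivered values must be finite")
    s = spec.sign
    p, d = s * planned, s * delivered
    if paradigm == "alara":
        return d - p
    if paradigm != "planning_criteria":
        raise ConfigurationError(f"unknown paradigm {paradigm!r}")
    if spec.planning_criterion is None:
        if spec.is_dosimetric:
            raise ConfigurationError(
                f"objective {spec.name!r}: planning-criteria paradigm requires a "
                "planning criterion for dosimetric objectives"
            )
        return d - p
    return d - max(s * spec.planning_criterion, p)


def label_with_tolerance(magnitude: float, tolerance: float) -> str:
    """Violation iff magnitude >= tolerance (boundary inclusive)."""
    if tolerance < 0:
        raise ConfigurationError("tolerance must be >= 0")
    return "violation" if magnitude >= tolerance else "normal"


def label_quartile(magnitudes: dict[str, float], fraction: float = 0.25) -> dict[str, str]:
    """Flag the ceil(fraction*n) patients with the largest magnitudes.

    Ties at the cut are broken by ascending patient_id, so the labeling is a
    deterministic function of the input.
    """
    if not magnitudes:
        raise InsufficientDataError("label_quartile requires at least one patient")
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must be in (0, 1]")
    n_flag = math.ceil(fraction * len(magnitudes))
    order = sorted(magnitudes, key=lambda pid: (-magnitudes[pid], pid))
    flagged = set(order[:n_flag])
    return {pid: ("violation" if pid in flagged else "normal") for pid in magnitudes}


def label_outcomes(
    planned: dict[str, float],
    delivered: dict[str, float],
    spec: ObjectiveSpec,
    scheme: LabelScheme,
) -> list[LabeledOutcome]:
    """Apply one label format to a whole cohort for one objective."""
    if set(planned) != set(delivered):
        raise ConfigurationError("planned and delivered patient sets differ")
    mags = {
        pid: violation_magnitude(planned[pid], delivered[pid], spec, scheme.paradigm)
        for pid in planned
    }
    if scheme.tolerance_mode == "deviation":
        labels = {
            pid: label_with_tolerance(m, scheme.deviation_tolerance) for pid, m in mags.items()
        }
    else:
        labels = label_quartile(mags, scheme.quartile_fraction)
    return [
        LabeledOutcome(pid, spec.name, mags[pid], labels[pid]) for pid in sorted(planned)
    ]


def projected_systematic_change(series: TrendSeries) -> float:
    """Fitted change over the observation window: slope * (f_last - f_first)."""
    slope, intercept, _ = fit_linear_trend(series)
    x = series.fractions
    return float(slope * (x[-1] - x[0]))


def screen_objective_feasibility(
    labels: dict[str, str],
    systematic_changes: list[float],
    deviation_tolerance: float,
    min_violations: int,
) -> FeasibilityResult:
    """Exclude objectives that cannot support predictive modelling.

    ``low_prevalence``: fewer than ``min_violations`` violations in the
    cohort (a dataset like 6 positives in 250 cannot anchor a classifier).
    ``random_dominates``: the cross-patient mean absolute projected
    systematic change falls below the random-error deviation tolerance, i.e.
    random interfractional changes dominate systematic effects.
    """
    if not labels:
        raise InsufficientDataError("feasibility screen requires labels")
    n_viol = sum(1 for v in labels.values() if v == "violation")
    if n_viol < min_violations:
        return FeasibilityResult(False, "low_prevalence", {"n_violations": n_viol})
    mean_sys = float(np.mean(np.abs(systematic_changes))) if len(systematic_changes) else 0.0
    if mean_sys < deviation_tolerance:
        return FeasibilityResult(
            False, "random_dominates",
            {"mean_systematic_change": mean_sys, "deviation_tolerance": deviation_tolerance},
        )
    return FeasibilityResult(True, None, {"n_violations": n_viol})


def default_objective_specs() -> dict[str, ObjectiveSpec]:
    """Planning criteria for the default simulated study objectives."""
    specs = [
        # combined objective follows the spinal cord (violation at >= 45 Gy);
        # the brainstem limit (54 Gy) is far from typical plans in this cohort
        ObjectiveSpec("brainstem_spinal_cord", "D0.03cc", 45.0, "increase", "Gy"),
        ObjectiveSpec("parotid_dmean", "Dmean", 26.0, "increase", "Gy"),
        ObjectiveSpec("constrictor_dmean", "Dmean", 50.0, "increase", "Gy"),
        ObjectiveSpec("weight_loss", "BMI", None, "decrease", "kg/m^2"),
    ]
    return {s.name: s for s in specs}
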
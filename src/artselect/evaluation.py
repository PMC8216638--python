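"""Scoring of full forests and simplified rules on training/validation data.

Metrics follow the screening convention: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), J = sensitivity + specificity - 1, and the replan
fraction (TP+FP)/n is the share of patients a subject refers for ART
assessment.  Metrics whose denominator is empty are reported as ``None``,
never coerced to 0, so degenerate validation splits stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ComparisonError
from .guideline_heuristic import GuidelineRule, apply_rule
from .rf_screening import auc as _auc
from .errors import UndefinedROCError


@dataclass
class EvalReport:
    subject: str  # "full_model" | "simple_rule"
    dataset: str  # "training" | "validation"
    objective: str = ""
    sensitivity: float | None = None
    specificity: float | None = None
    J: float | None = None
    auc: float | None = None
    replan_fraction: float = 0.0
    confusion: tuple[int, int, int, int] = (0, 0, 0, 0)  # TP, FP, TN, FN

    def to_dict(self) -> dict:
        tp, fp, tn, fn = self.confusion
        return {
            "subject": self.subject,
            "dataset": self.dataset,
            "objective": self.objective,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "J": self.J,
            "auc": self.auc,
            "replan_fraction": self.replan_fraction,
            "confusion": {"TP": tp, "FP": fp, "TN": tn, "FN": fn},
        }


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return (arr == "violation").astype(int)
    return arr.astype(int)


def evaluate(
    flags,
    labels,
    scores=None,
    subject: str = "simple_rule",
    dataset: str = "training",
    objective: str = "",
) -> EvalReport:
    """Confusion table and derived metrics for binary flags against labels.

    ``scores`` (continuous violation estimates) additionally yield an AUC
    when both classes are present.
    """
    y = _as_binary(labels)
    f = np.asarray(flags, dtype=bool)
    if len(y) == 0:
        raise ValueError("evaluate requires at least one patient")
    tp = int(np.sum(f & (y == 1)))
    fp = int(np.sum(f & (y == 0)))
    tn = int(np.sum(~f & (y == 0)))
    fn = int(np.sum(~f & (y == 1)))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    j = sens + spec - 1.0 if (sens is not None and spec is not None) else None
    auc_val = None
    if scores is not None:
        try:
            auc_val = _auc(scores, y)
        except UndefinedROCError:
            auc_val = None
    return EvalReport(
        subject=subject,
        dataset=dataset,
        objective=objective,
        sensitivity=sens,
        specificity=spec,
        J=j,
        auc=auc_val,
        replan_fraction=(tp + fp) / len(y),
        confusion=(tp, fp, tn, fn),
    )


def evaluate_rule(
    rule: GuidelineRule, X, labels, dataset: str = "training"
) -> EvalReport:
    return evaluate(
        apply_rule(rule, X), labels, subject="simple_rule", dataset=dataset,
        objective=rule.objective,
    )


def train_validation_delta(train: EvalReport, val: EvalReport) -> float:
    """Overfitting gap J_train - J_val for the same subject and objective."""
    if train.subject != val.subject or train.objective != val.objective:
        raise ComparisonError(
            f"mismatched reports: {train.subject}/{train.objective} vs "
            f"{val.subject}/{val.objective}"
        )
    if train.J is None or val.J is None:
        raise ComparisonError("J undefined on one of the reports")
    return float(train.J - val.J)


def combined_referral_fraction(rules: list[GuidelineRule], cohort) -> float:
    """Fraction of patients flagged by the union (OR) of the rules."""
    if not rules:
        raise ValueError("combined_referral_fraction requires >= 1 rule")
    union = np.zeros(len(cohort), dtype=bool)
    for rule in rules:
        union |= apply_rule(rule, cohort)
    return float(union.mean())
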
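"""Distillation of a random forest into a conjunctive patient-selection rule.

A trained forest predicts a continuous violation magnitude; the clinic wants
a wall-chart guideline of the form::

    If planned brainstem D0.03cc >= 16 Gy
    AND planned spinal cord D0.03cc >= 43 Gy
    then violation likely.

The heuristic proceeds in four steps:

1. Rank predictors by out-of-bag permutation importance (mean increase in
   per-tree MSE on out-of-bag samples after permuting the predictor).
2. Probe the decision boundary: holding the other predictors at the medians
   of boundary-region patients (forest output within a band of the
   violation-call threshold), sweep each high-importance predictor across
   its observed range and record where the forest output crosses the
   threshold.  The crossing value and direction seed one threshold term.
3. Jointly refine all cutoffs by coordinate ascent on the training-set
   Youden index of the conjunction.
4. Simplify: drop terms implied by the remaining conjunction on the
   training data, and optionally drop whole measurement categories
   (typically the on-unit Obs measurements) when the Youden cost is small —
   trading a little specificity for a large workflow gain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)

from .errors import RuleEvaluationError


@dataclass(frozen=True)
class GuidelineTerm:
    predictor: str
    direction: str  # ">=" | "<="
    cutoff: float
    category: str = ""

    def mask(self, values: np.ndarray) -> np.ndarray:
        return values >= self.cutoff if self.direction == ">=" else values <= self.cutoff


@dataclass
class GuidelineRule:
    """A conjunction of threshold terms with recorded performance.

    ``performance`` maps a dataset name ("training", "validation") to a dict
    with sensitivity/specificity/J; ``provenance`` lists the refinement steps
    applied, in order.
    """

    objective: str
    terms: list[GuidelineTerm] = field(default_factory=list)
    performance: dict = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def predictors(self) -> list[str]:
        return [t.predictor for t in self.terms]

    def to_dict(self) -> dict:
        return {
            "objective": self.objective,
            "terms": [
                {
                    "predictor": t.predictor,
                    "direction": t.direction,
                    "cutoff": t.cutoff,
                    "category": t.category,
                }
                for t in self.terms
            ],
            "performance": self.performance,
            "provenance": list(self.provenance),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "GuidelineRule":
        return cls(
            objective=d["objective"],
            terms=[
                GuidelineTerm(t["predictor"], t["direction"], float(t["cutoff"]), t.get("category", ""))
                for t in d["terms"]
            ],
            performance=dict(d.get("performance", {})),
            provenance=list(d.get("provenance", [])),
        )

    @classmethod
    def from_json(cls, text_or_path) -> "GuidelineRule":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)

    def card(self, decimals: int = 0) -> str:
        """Human-readable guideline card; cutoffs rounded to clinical precision.

        Rounding is presentational only — evaluation always uses the stored
        unrounded cutoffs.
        """
        if not self.terms:
            return f"[{self.objective}] No selection rule (flags no patients)."
        lines = []
        for i, t in enumerate(self.terms):
            prefix = "If " if i == 0 else "AND "
            lines.append(f"{prefix}{t.predictor} {t.direction} {round(t.cutoff, decimals):g}")
        lines.append("then violation likely.")
        return f"[{self.objective}]\n" + "\n".join(lines)


@dataclass(frozen=True)
class ImportanceRanking:
    """Predictors with permutation-importance scores, descending.

    Ties are broken by ascending predictor name so the ordering is total and
    reproducible.
    """

    entries: tuple  # of (predictor, score)

    def top(self, k: int) -> list[str]:
        return [name for name, _ in self.entries[:k]]


# ---------------------------------------------------------------------------
# Out-of-bag permutation importance
# ---------------------------------------------------------------------------

def _tree_oob_indices(tree, n_samples: int, n_samples_bootstrap: int) -> np.ndarray:
    # unweighted bootstrap; signatures differ across scikit-learn releases
    try:
        return _generate_unsampled_indices(tree.random_state, n_samples, n_samples_bootstrap, None)
    except TypeError:
        return _generate_unsampled_indices(tree.random_state, n_samples, n_samples_bootstrap)


def oob_importance(forest, X: pd.DataFrame, y, seed: int = 0) -> ImportanceRanking:
    """Mean increase in out-of-bag MSE after permuting each predictor.

    For every tree, the samples left out of its bootstrap form a private
    test set; the importance of a predictor is the average (over trees) of
    the OOB MSE after permuting that column minus the baseline OOB MSE.
    A predictor no tree ever splits on scores exactly zero.  Trees with no
    out-of-bag samples are skipped with a warning.
    """
    if not getattr(forest, "bootstrap", True):
        raise ValueError("OOB importance requires a bootstrap forest")
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    try:
        nboot = _get_n_samples_bootstrap(n, forest.max_samples, None)
    except TypeError:
        nboot = _get_n_samples_bootstrap(n, forest.max_samples)
    rng = np.random.default_rng(seed)
    cols = list(X.columns)
    deltas = np.zeros((len(forest.estimators_), len(cols)))
    used = np.zeros(len(forest.estimators_), dtype=bool)
    for t_idx, tree in enumerate(forest.estimators_):
        oob = _tree_oob_indices(tree, n, nboot)
        if len(oob) == 0:
            warnings.warn(f"tree {t_idx} has no out-of-bag samples; skipped")
            continue
        used[t_idx] = True
        X_oob = Xv[oob]
        base_mse = float(np.mean((tree.predict(X_oob) - yv[oob]) ** 2))
        for c_idx in range(len(cols)):
            if c_idx not in set(tree.tree_.feature[tree.tree_.feature >= 0]):
                continue  # never split upon: permuting cannot change predictions
            perm = rng.permutation(len(oob))
            X_perm = X_oob.copy()
            X_perm[:, c_idx] = X_oob[perm, c_idx]
            mse = float(np.mean((tree.predict(X_perm) - yv[oob]) ** 2))
            deltas[t_idx, c_idx] = mse - base_mse
    if not used.any():
        raise ValueError("no tree had out-of-bag samples")
    scores = deltas[used].mean(axis=0)
    order = sorted(range(len(cols)), key=lambda i: (-scores[i], cols[i]))
    return ImportanceRanking(tuple((cols[i], float(scores[i])) for i in order))


# ---------------------------------------------------------------------------
# Rule application and scoring
# ---------------------------------------------------------------------------

def apply_rule(rule: GuidelineRule, data) -> np.ndarray | bool:
    """Evaluate the conjunction; an empty rule flags nobody.

    ``data`` is a patient dict (returns bool) or a DataFrame (returns a
    boolean array).  A missing predictor raises, naming the predictor.
    """
    if isinstance(data, dict):
        flags = apply_rule(rule, pd.DataFrame([data]))
        return bool(flags[0])
    out = np.ones(len(data), dtype=bool)
    for t in rule.terms:
        if t.predictor not in data.columns:
            raise RuleEvaluationError(f"rule predictor {t.predictor!r} missing from data")
        out &= t.mask(data[t.predictor].to_numpy(dtype=float))
    if not rule.terms:
        out[:] = False
    return out


def _flags_for_terms(terms, X: pd.DataFrame) -> np.ndarray:
    out = np.ones(len(X), dtype=bool)
    for t in terms:
        out &= t.mask(X[t.predictor].to_numpy(dtype=float))
    if not terms:
        out[:] = False
    return out


def _youden(flags: np.ndarray, labels: np.ndarray) -> float:
    pos = labels == 1
    neg = ~pos
    sens = flags[pos].mean() if pos.any() else 0.0
    spec = (~flags[neg]).mean() if neg.any() else 0.0
    return float(sens + spec - 1.0)


def rule_performance(rule: GuidelineRule, X: pd.DataFrame, labels) -> dict:
    labels = np.asarray(labels).astype(int)
    flags = apply_rule(rule, X)
    pos, neg = labels == 1, labels == 0
    sens = float(flags[pos].mean()) if pos.any() else None
    spec = float((~flags[neg]).mean()) if neg.any() else None
    j = sens + spec - 1.0 if sens is not None and spec is not None else None
    return {"sensitivity": sens, "specificity": spec, "J": j,
            "flagged_fraction": float(flags.mean())}


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def _coordinate_ascent(
    terms: list[GuidelineTerm],
    X: pd.DataFrame,
    labels: np.ndarray,
    order: list[str],
    n_grid: int = 101,
    max_cycles: int = 20,
    tol: float = 1e-6,
) -> list[GuidelineTerm]:
    """Refine cutoffs one predictor at a time, maximizing training Youden.

    Candidate cutoffs form an even grid over each predictor's observed
    range; ties go to the more permissive cutoff (lower for >=, higher
    for <=), favouring sensitivity, which suits a screening rule.
    """
    terms = list(terms)
    if not terms:
        return terms
    by_name = {t.predictor: i for i, t in enumerate(terms)}
    cycle_order = [p for p in order if p in by_name]
    best_j = _youden(_flags_for_terms(terms, X), labels)
    for _ in range(max_cycles):
        start_j = best_j
        for pred in cycle_order:
            i = by_name[pred]
            term = terms[i]
            col = X[pred].to_numpy(dtype=float)
            grid = np.linspace(col.min(), col.max(), n_grid)
            others = [t for k, t in enumerate(terms) if k != i]
            base = _flags_for_terms(others, X) if others else np.ones(len(X), dtype=bool)
            permissive = grid if term.direction == ">=" else grid[::-1]
            best_cut, best_here = term.cutoff, best_j
            for cut in permissive:
                cand = replace(term, cutoff=float(cut))
                j = _youden(base & cand.mask(col), labels)
                if j > best_here + tol:
                    best_here, best_cut = j, float(cut)
            terms[i] = replace(term, cutoff=best_cut)
            best_j = best_here
        if best_j - start_j < tol:
            break
    return terms


def _prune_vacuous(terms: list[GuidelineTerm], X: pd.DataFrame) -> list[GuidelineTerm]:
    """Drop terms whose cutoff sits at the permissive range edge (always true)."""
    kept = []
    for t in terms:
        col = X[t.predictor].to_numpy(dtype=float)
        if t.direction == ">=" and t.cutoff <= col.min():
            continue
        if t.direction == "<=" and t.cutoff >= col.max():
            continue
        kept.append(t)
    return kept


def extract_rule(
    forest,
    X: pd.DataFrame,
    magnitudes,
    labels,
    binarization_threshold: float,
    categories_of: dict[str, str] | None = None,
    top_k: int = 8,
    band: float | None = None,
    importance_seed: int = 0,
    objective: str = "",
) -> GuidelineRule:
    """Boundary-probe a forest into a conjunctive guideline rule.

    ``magnitudes`` is the forest's regression target (used for the OOB
    importance ranking); ``binarization_threshold`` is the Youden-optimal
    violation-call threshold from the screening stage; ``band`` is the
    half-width of the boundary region around it (defaults to the SD of the
    forest's training residuals, widened geometrically if it captures no
    patients).
    """
    labels = np.asarray(labels).astype(int)
    magnitudes = np.asarray(magnitudes, dtype=float)
    ranking = oob_importance(forest, X, magnitudes, seed=importance_seed)
    top = ranking.top(top_k)
    preds = forest.predict(np.asarray(X, dtype=float))
    if band is None:
        band = float(np.std(preds - magnitudes)) or 1.0
    # Probe from the violation side of the boundary: with the other
    # predictors held at values typical of predicted violations, sweeping one
    # predictor toward normality locates the combination that produces a
    # boundary prediction — the cutoff for that predictor's term.  If no
    # patient is predicted a violation, fall back to the band around the
    # threshold, widening geometrically until it is non-empty.
    region = preds >= binarization_threshold
    if not region.any():
        region = np.abs(preds - binarization_threshold) <= band
        while not region.any():
            band *= 2.0
            region = np.abs(preds - binarization_threshold) <= band
    base_point = X.loc[region].median()

    terms: list[GuidelineTerm] = []
    cats = categories_of or {}
    for pred in top:
        col = X[pred].to_numpy(dtype=float)
        grid = np.linspace(col.min(), col.max(), 101)
        probe = pd.DataFrame(
            {c: np.full(len(grid), base_point[c]) for c in X.columns}, columns=X.columns
        )
        probe[pred] = grid
        out = forest.predict(np.asarray(probe, dtype=float))
        above = out >= binarization_threshold
        if above.all() or not above.any():
            warnings.warn(f"no boundary crossing for predictor {pred!r}; dropped")
            continue
        if grid[above].mean() > grid[~above].mean():
            direction, cutoff = ">=", float(grid[above].min())
        else:
            direction, cutoff = "<=", float(grid[above].max())
        terms.append(GuidelineTerm(pred, direction, cutoff, cats.get(pred, "")))

    terms = _coordinate_ascent(terms, X, labels, order=top)
    terms = _prune_vacuous(terms, X)
    terms.sort(key=lambda t: t.predictor)
    rule = GuidelineRule(objective=objective, terms=terms, provenance=["extracted"])
    rule.performance["training"] = rule_performance(rule, X, labels)
    return rule


# ---------------------------------------------------------------------------
# Refinement
# ---------------------------------------------------------------------------

def remove_redundant_terms(rule: GuidelineRule, X: pd.DataFrame) -> GuidelineRule:
    """Drop terms implied, on the training data, by the remaining conjunction.

    A term is redundant when removing it leaves the flagged set unchanged
    (every patient satisfying the other terms also satisfies it) — e.g. a
    bilateral-treatment term implied by a contralateral-dose term.  Repeats
    to a fixpoint; the flagged set is invariant.
    """
    terms = list(rule.terms)
    changed = True
    while changed:
        changed = False
        full = _flags_for_terms(terms, X)
        for i in range(len(terms)):
            rest = terms[:i] + terms[i + 1:]
            if rest and np.array_equal(_flags_for_terms(rest, X), full):
                terms = rest
                changed = True
                break
            if not rest and not full.any():
                # a lone term flagging nobody is not redundant; keep it
                continue
    out = GuidelineRule(
        objective=rule.objective,
        terms=terms,
        performance=dict(rule.performance),
        provenance=rule.provenance + (["redundant_terms_removed"] if len(terms) < len(rule.terms) else []),
    )
    return out


def drop_costly_category(
    rule: GuidelineRule,
    X: pd.DataFrame,
    labels,
    category: str,
    max_J_loss: float = 0.10,
) -> GuidelineRule:
    """Try removing all terms of a measurement category (typically Obs).

    Surviving cutoffs are re-refined by coordinate ascent; the reduced rule
    is kept iff the training Youden loss is at most ``max_J_loss``,
    otherwise the original rule is returned unchanged.  Either outcome is
    recorded in the provenance.
    """
    labels = np.asarray(labels).astype(int)
    dropped = [t for t in rule.terms if t.category == category]
    if not dropped:
        return rule
    survivors = [t for t in rule.terms if t.category != category]
    order = [t.predictor for t in survivors]
    refined = _coordinate_ascent(survivors, X, labels, order=order)
    refined.sort(key=lambda t: t.predictor)
    j_old = _youden(_flags_for_terms(list(rule.terms), X), labels)
    j_new = _youden(_flags_for_terms(refined, X), labels)
    if j_old - j_new <= max_J_loss:
        out = GuidelineRule(
            objective=rule.objective,
            terms=refined,
            performance={},
            provenance=rule.provenance + [f"dropped_category:{category}"],
        )
        out.performance["training"] = rule_performance(out, X, labels)
        return out
    return GuidelineRule(
        objective=rule.objective,
        terms=list(rule.terms),
        performance=dict(rule.performance),
        provenance=rule.provenance + [f"kept_category:{category}"],
    )
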
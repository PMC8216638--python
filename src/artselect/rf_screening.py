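"""Cross-validated random-forest screening over predictor-category subsets.

For each ART objective a grid of screening cells is trained: one cell per
(non-empty predictor-category subset) x (label format).  Each cell fits a
random-forest *regressor* on the signed violation magnitude under five
random initializations with five-fold cross-validation, so every patient
gets one out-of-fold magnitude estimate per initialization.  Sweeping the
threshold that converts the regression estimate into a normal/violation call
traces an ROC curve; the maximum Youden index J = sensitivity +
specificity - 1 is the primary performance metric and AUC is secondary.

A greedy stepwise procedure then selects the cell meta-parameters (category
inclusion flags, paradigm, tolerance mode): at each round the parameter
whose levels most clearly separate strong from poor cells — smallest
Kruskal-Wallis p-value over per-initialization Youden indices — is fixed at
the level with the highest median J, and the grid is filtered, until no
parameter separates at the chosen significance level.  Ties within a small
Youden band are resolved by comparing the most complete and most
parsimonious surviving cells on specificity over the sensitivity band
0.60-0.80.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .errors import SelectionError, UndefinedROCError
from .labeling import LabelScheme
from .synthetic_cohort import CATEGORIES

DEFAULT_N_TREES = 500
DEFAULT_INIT_SEEDS = (101, 202, 303, 404, 505)


@dataclass(frozen=True)
class ScreeningCell:
    """One point of the screening grid."""

    objective: str
    category_subset: tuple[str, ...]
    label_scheme: LabelScheme
    init_seeds: tuple[int, ...] = DEFAULT_INIT_SEEDS
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if not self.category_subset:
            raise ValueError("category_subset must be non-empty")
        unknown = set(self.category_subset) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)}")


@dataclass(frozen=True)
class InitMetrics:
    seed: int
    roc: np.ndarray  # (k, 3): threshold, sensitivity, specificity
    auc: float
    youden: tuple[float, float, float, float]  # threshold, sens, spec, J


@dataclass
class ScreeningResult:
    cell: ScreeningCell
    n_features: int
    cv_predictions: dict[int, np.ndarray]  # init seed -> out-of-fold estimates
    per_init: list[InitMetrics]

    @property
    def auc_values(self) -> np.ndarray:
        return np.array([m.auc for m in self.per_init])

    @property
    def auc_mean(self) -> float:
        return float(self.auc_values.mean())

    @property
    def auc_sd(self) -> float:
        return float(self.auc_values.std(ddof=1)) if len(self.per_init) > 1 else 0.0

    @property
    def youden_values(self) -> np.ndarray:
        return np.array([m.youden[3] for m in self.per_init])

    @property
    def mean_J(self) -> float:
        return float(self.youden_values.mean())

    @property
    def mean_threshold(self) -> float:
        return float(np.mean([m.youden[0] for m in self.per_init]))


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

class FeatureBuilder:
    """Select category columns, impute missing values with training medians.

    Each column with any missing value in the full table additionally gets a
    0/1 missingness-indicator column.  Categorical predictors are already
    integer-coded at generation time; tree models are invariant to the
    monotone coding.
    """

    def __init__(self, frame: pd.DataFrame, categories_of: dict[str, str], train_mask):
        self.categories_of = dict(categories_of)
        self.frame = frame
        self.train_mask = np.asarray(train_mask, dtype=bool)
        self.medians = {
            c: float(frame.loc[self.train_mask, c].median()) for c in categories_of
        }

    def predictors_in(self, categories) -> list[str]:
        cats = set(categories)
        return sorted(c for c, cat in self.categories_of.items() if cat in cats)

    def matrix(self, categories) -> pd.DataFrame:
        cols = self.predictors_in(categories)
        if not cols:
            raise ValueError(f"no predictors in categories {sorted(set(categories))}")
        out = {}
        for c in cols:
            col = self.frame[c].astype(float)
            if col.isna().any():
                out[f"{c}__missing"] = col.isna().astype(float).to_numpy()
                col = col.fillna(self.medians[c])
            out[c] = col.to_numpy()
        return pd.DataFrame(out, index=self.frame.index)


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def train_rf_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    cell: ScreeningCell,
    n_trees: int = DEFAULT_N_TREES,
) -> dict[int, np.ndarray]:
    """Out-of-fold magnitude estimates for each of the cell's init seeds.

    Fold assignment and forest fitting are fully determined by the seeds:
    init seed *s* drives both the shuffled K-fold split and the forest's
    random state, so reruns are bit-identical.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * cell.cv_folds:
        raise ValueError(f"need >= 2 patients per fold ({n} for {cell.cv_folds} folds)")
    preds: dict[int, np.ndarray] = {}
    if np.ptp(y) == 0:
        warnings.warn("constant regression target; predictions set to the target mean")
        for s in cell.init_seeds:
            preds[s] = np.full(n, y.mean())
        return preds
    for s in cell.init_seeds:
        out = np.empty(n)
        kf = KFold(n_splits=cell.cv_folds, shuffle=True, random_state=s)
        for train_idx, test_idx in kf.split(X):
            rf = RandomForestRegressor(
                n_estimators=n_trees, random_state=s, n_jobs=1, max_features=1.0 / 3.0
            )
            rf.fit(X[train_idx], y[train_idx])
            out[test_idx] = rf.predict(X[test_idx])
        preds[s] = out
    return preds


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return (arr == "violation").astype(int)
    return arr.astype(int)


def roc_from_predictions(predictions, labels) -> np.ndarray:
    """ROC by sweeping a violation-call threshold over the regression output.

    Thresholds are the midpoints between consecutive sorted unique
    predictions, plus -inf/+inf sentinels; a patient is called a violation
    when its estimate is >= the threshold.  Returns an array of rows
    (threshold, sensitivity, specificity) in increasing threshold order.
    """
    y = _as_binary(labels)
    p = np.asarray(predictions, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedROCError("both label classes are required for an ROC curve")
    uniq = np.unique(p)
    thresholds = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    rows = []
    for t in thresholds:
        called = p >= t
        tp = int(np.sum(called & (y == 1)))
        tn = int(np.sum(~called & (y == 0)))
        rows.append((t, tp / n_pos, tn / n_neg))
    return np.array(rows)


def auc(predictions, labels) -> float:
    """Pairwise concordance probability, ties counted 1/2 (Mann-Whitney)."""
    y = _as_binary(labels)
    p = np.asarray(predictions, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedROCError("both label classes are required for AUC")
    ranks = stats.rankdata(p)
    rank_sum = ranks[y == 1].sum()
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def youden_optimal(roc: np.ndarray) -> tuple[float, float, float, float]:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Ties are broken toward higher sensitivity, then lower threshold
    (screening intent: prefer catching violations).
    """
    if len(roc) == 0:
        raise ValueError("empty ROC")
    best = None
    for t, sens, spec in roc:
        j = sens + spec - 1.0
        key = (j, sens, -t)
        if best is None or key > best[0]:
            best = (key, (float(t), float(sens), float(spec), float(j)))
    return best[1]


def screen_cell(
    X: pd.DataFrame,
    magnitudes: np.ndarray,
    labels,
    cell: ScreeningCell,
    n_trees: int = DEFAULT_N_TREES,
) -> ScreeningResult:
    """Fit one grid cell and score each initialization by ROC/AUC/Youden."""
    cv_preds = train_rf_cv(X, magnitudes, cell, n_trees=n_trees)
    per_init = []
    for s in cell.init_seeds:
        roc = roc_from_predictions(cv_preds[s], labels)
        per_init.append(
            InitMetrics(seed=s, roc=roc, auc=auc(cv_preds[s], labels), youden=youden_optimal(roc))
        )
    return ScreeningResult(
        cell=cell, n_features=X.shape[1], cv_predictions=cv_preds, per_init=per_init
    )


def category_subsets(categories=CATEGORIES, exclude: tuple[str, ...] = ()) -> list[tuple[str, ...]]:
    """All non-empty subsets of the available categories, in a fixed order."""
    cats = [c for c in categories if c not in exclude]
    subsets = []
    for mask in range(1, 1 << len(cats)):
        subsets.append(tuple(c for i, c in enumerate(cats) if mask >> i & 1))
    return sorted(subsets, key=lambda s: (len(s), s))


# ---------------------------------------------------------------------------
# Greedy stepwise meta-parameter selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionRound:
    parameter: str
    p_values: dict[str, float]  # parameter -> KW p this round
    chosen_level: object
    p_value: float


@dataclass
class SelectionReport:
    fixed: dict[str, object]
    rounds: list[SelectionRound]
    shortlist: list[ScreeningResult]
    chosen: ScreeningResult | None = None

    def to_dict(self) -> dict:
        return {
            "fixed": {k: v for k, v in self.fixed.items()},
            "rounds": [
                {
                    "parameter": r.parameter,
                    "p_values": r.p_values,
                    "chosen_level": r.chosen_level,
                    "p_value": r.p_value,
                }
                for r in self.rounds
            ],
            "shortlist": [_cell_id(res.cell) for res in self.shortlist],
            "chosen": _cell_id(self.chosen.cell) if self.chosen else None,
        }


def _cell_id(cell: ScreeningCell) -> str:
    return f"{cell.objective}|{'+'.join(cell.category_subset)}|{cell.label_scheme.key}"


def _meta_levels(result: ScreeningResult) -> dict[str, object]:
    levels: dict[str, object] = {
        f"include_{c}": c in result.cell.category_subset for c in CATEGORIES
    }
    levels["paradigm"] = result.cell.label_scheme.paradigm
    levels["tolerance_mode"] = result.cell.label_scheme.tolerance_mode
    return levels


def greedy_stepwise_select(
    results: list[ScreeningResult],
    alpha: float = 0.05,
    delta_j: float = 0.02,
) -> SelectionReport:
    """Fix cell meta-parameters one at a time by Kruskal-Wallis separation.

    Each round groups the per-initialization Youden indices of the surviving
    cells by the levels of every unfixed meta-parameter and computes a
    Kruskal-Wallis rank-sum test.  The parameter with the smallest p-value is
    fixed at the level with the highest median J; cells at other levels are
    discarded.  Rounds stop when every parameter is fixed or the smallest p
    exceeds ``alpha``.  The shortlist holds surviving cells within
    ``delta_j`` of the best mean J.
    """
    if len(results) < 2:
        raise SelectionError("greedy selection needs >= 2 screening results")
    surviving = list(results)
    fixed: dict[str, object] = {}
    rounds: list[SelectionRound] = []
    param_names = list(_meta_levels(results[0]))

    while True:
        candidates = {}
        for name in param_names:
            if name in fixed:
                continue
            groups: dict[object, list[float]] = {}
            for res in surviving:
                groups.setdefault(_meta_levels(res)[name], []).extend(res.youden_values)
            if len(groups) < 2:
                continue
            try:
                stat, p = stats.kruskal(*groups.values())
            except ValueError:  # all values identical across groups
                p = 1.0
            candidates[name] = (float(p), groups)
        if not candidates:
            break
        p_values = {name: p for name, (p, _) in candidates.items()}
        best_name = min(candidates, key=lambda k: (candidates[k][0], k))
        best_p, groups = candidates[best_name]
        if best_p > alpha:
            break
        best_level = max(groups, key=lambda lv: (float(np.median(groups[lv])), str(lv)))
        fixed[best_name] = best_level
        rounds.append(SelectionRound(best_name, p_values, best_level, best_p))
        surviving = [r for r in surviving if _meta_levels(r)[best_name] == best_level]
        if not surviving:
            raise SelectionError("greedy selection eliminated every cell")

    if not surviving:
        raise SelectionError("greedy selection left no surviving cells")
    best_j = max(r.mean_J for r in surviving)
    shortlist = [r for r in surviving if r.mean_J >= best_j - delta_j]
    report = SelectionReport(fixed=fixed, rounds=rounds, shortlist=shortlist)
    report.chosen = resolve_tie(shortlist)
    return report


def specificity_at_sensitivity(roc: np.ndarray, sens_target: float) -> float:
    """Best achievable specificity among operating points with sens >= target."""
    ok = roc[:, 1] >= sens_target
    if not ok.any():
        return 0.0
    return float(roc[ok, 2].max())


def _band_specificity(result: ScreeningResult, grid: np.ndarray) -> float:
    per_init = [
        np.mean([specificity_at_sensitivity(m.roc, s) for s in grid]) for m in result.per_init
    ]
    return float(np.mean(per_init))


def resolve_tie(shortlist: list[ScreeningResult]) -> ScreeningResult:
    """Most-complete vs most-parsimonious comparison on the 0.60-0.80 band.

    Of the shortlist members with the most and the fewest input predictors,
    the one with the larger mean specificity over a 21-point sensitivity grid
    spanning [0.60, 0.80] wins.  A single-member shortlist is returned
    unchanged.
    """
    if not shortlist:
        raise SelectionError("empty shortlist")
    if len(shortlist) == 1:
        return shortlist[0]
    complete = max(shortlist, key=lambda r: (r.n_features, _cell_id(r.cell)))
    parsimonious = min(shortlist, key=lambda r: (r.n_features, _cell_id(r.cell)))
    if complete is parsimonious:
        return complete
    grid = np.linspace(0.60, 0.80, 21)
    sc, sp = _band_specificity(complete, grid), _band_specificity(parsimonious, grid)
    return complete if sc >= sp else parsimonious


def learning_curve(
    X: pd.DataFrame,
    magnitudes: np.ndarray,
    labels,
    cell: ScreeningCell,
    sizes=(100, 125, 150, 175, 200),
    n_trees: int = DEFAULT_N_TREES,
) -> dict[int, tuple[float, float]]:
    """Refit the cell on chronological training prefixes.

    Returns size -> (auc_mean, auc_sd) over the cell's initializations.
    Sizes too small for the fold count, or whose prefix lacks a label class,
    are skipped with a warning.
    """
    y = np.asarray(magnitudes, dtype=float)
    lab = _as_binary(labels)
    out: dict[int, tuple[float, float]] = {}
    for size in sizes:
        if size > len(y):
            raise ValueError(f"size {size} exceeds the training set ({len(y)})")
        if size < 2 * cell.cv_folds:
            warnings.warn(f"size {size} below the fold minimum; skipped")
            continue
        sub_lab = lab[:size]
        if sub_lab.min() == sub_lab.max():
            warnings.warn(f"size {size}: single-class prefix; skipped")
            continue
        res = screen_cell(X.iloc[:size], y[:size], sub_lab, cell, n_trees=n_trees)
        out[size] = (res.auc_mean, res.auc_sd)
    return out
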
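"""Screening stage: ROC/AUC/Youden against brute-force oracles, CV forests,
greedy stepwise selection, tie resolution, learning curves."""

import numpy as np
import pytest

from artselect.errors import UndefinedROCError
from artselect.labeling import LabelScheme
from artselect.rf_screening import (
    InitMetrics,
    ScreeningCell,
    ScreeningResult,
    auc,
    category_subsets,
    greedy_stepwise_select,
    learning_curve,
    resolve_tie,
    roc_from_predictions,
    screen_cell,
    specificity_at_sensitivity,
    train_rf_cv,
    youden_optimal,
)
from conftest import ALARA_DEVIATION, INIT_SEEDS, planted_study


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_auc(predictions, labels01):
    """O(n^2) pairwise concordance, ties counted 1/2."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels01, dtype=int)
    pos, neg = p[y == 1], p[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(predictions, labels01):
    """Exhaustive scan over every threshold between sorted predictions."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels01, dtype=int)
    uniq = np.unique(p)
    thresholds = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
    best = None
    for t in thresholds:
        called = p >= t
        sens = called[y == 1].mean()
        spec = (~called[y == 0]).mean()
        j = sens + spec - 1
        key = (j, sens, -t)
        if best is None or key > best[0]:
            best = (key, (t, sens, spec, j))
    return best[1]


# ---------------------------------------------------------------------------
# ROC / AUC / Youden
# ---------------------------------------------------------------------------

class TestROC:
    def test_separable_predictions_reach_perfect_corner(self):
        roc = roc_from_predictions([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0])
        assert any(np.isclose(s, 1) and np.isclose(sp, 1) for _, s, sp in roc)
        # sensitivity is non-increasing along increasing thresholds
        assert np.all(np.diff(roc[:, 1]) <= 1e-12)

    def test_interleaved_predictions_give_half_concordance(self):
        preds, labels = [0.9, 0.2, 0.8, 0.4], [1, 1, 0, 0]
        assert auc(preds, labels) == pytest.approx(brute_force_auc(preds, labels))
        assert auc(preds, labels) == pytest.approx(0.5)

    def test_constant_predictions_collapse_to_corner_points(self):
        roc = roc_from_predictions([0.5] * 6, [1, 0, 1, 0, 1, 0])
        pts = {(round(s, 6), round(sp, 6)) for _, s, sp in roc}
        assert pts == {(1.0, 0.0), (0.0, 1.0)}

    def test_single_class_labels_rejected(self):
        with pytest.raises(UndefinedROCError):
            roc_from_predictions([1.0, 2.0], [1, 1])
        with pytest.raises(UndefinedROCError):
            auc([1.0, 2.0], [0, 0])

    def test_tied_prediction_concordance_counts_half(self):
        preds, labels = [3.0, 2.0, 1.0, 2.0, 0.5, 0.0], [1, 1, 1, 0, 0, 0]
        expected = brute_force_auc(preds, labels)
        assert expected == pytest.approx(7.5 / 9)
        assert auc(preds, labels) == pytest.approx(expected, abs=1e-12)


class TestOracleEquivalence:
    def test_auc_and_youden_match_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # coarse grid forces ties between predictions
            preds = np.round(rng.normal(size=n) + labels, 1)
            assert auc(preds, labels) == pytest.approx(
                brute_force_auc(preds, labels), abs=1e-12
            )
            got = youden_optimal(roc_from_predictions(preds, labels))
            want = brute_force_youden(preds, labels)
            assert got[3] == pytest.approx(want[3], abs=1e-12)
            assert got[1] == pytest.approx(want[1], abs=1e-12)
            assert got[0] == pytest.approx(want[0], abs=1e-12)


class TestYouden:
    def test_separable_curve_attains_unit_index(self):
        roc = roc_from_predictions([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0])
        assert youden_optimal(roc)[3] == pytest.approx(1.0)

    def test_index_is_sensitivity_plus_specificity_minus_one(self):
        roc = np.array([[0.5, 1.0, 0.66], [1.5, 0.5, 0.9]])
        t, sens, spec, j = youden_optimal(roc)
        assert (t, sens, spec) == (0.5, 1.0, 0.66)
        assert j == pytest.approx(0.66)

    def test_tie_breaks_toward_higher_sensitivity(self):
        roc = np.array([[0.0, 1.0, 0.5], [1.0, 0.5, 1.0]])  # both J = 0.5
        assert youden_optimal(roc)[1] == 1.0


# ---------------------------------------------------------------------------
# Cross-validated forests
# ---------------------------------------------------------------------------

def _cell(subset=("RTx",), seeds=(1, 2), scheme=ALARA_DEVIATION):
    return ScreeningCell("brainstem", subset, scheme, seeds, 5)


class TestTrainRFCV:
    def test_reruns_are_bit_identical(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 3))
        y = X[:, 0] + rng.normal(0, 0.1, 60)
        import pandas as pd

        Xf = pd.DataFrame(X, columns=list("abc"))
        a = train_rf_cv(Xf, y, _cell(), n_trees=20)
        b = train_rf_cv(Xf, y, _cell(), n_trees=20)
        for s in a:
            np.testing.assert_array_equal(a[s], b[s])

    def test_constant_target_warns_and_returns_mean(self):
        import pandas as pd

        X = pd.DataFrame({"a": np.arange(20.0)})
        with pytest.warns(UserWarning, match="constant"):
            preds = train_rf_cv(X, np.full(20, 3.0), _cell(), n_trees=5)
        for arr in preds.values():
            np.testing.assert_allclose(arr, 3.0)

    def test_informative_feature_yields_high_out_of_fold_correlation(self):
        import pandas as pd

        rng = np.random.default_rng(7)
        y = rng.normal(size=200)
        X = pd.DataFrame({"signal": y})
        preds = train_rf_cv(X, y, _cell(seeds=(1,)), n_trees=50)
        r = np.corrcoef(preds[1], y)[0, 1]
        assert r > 0.95

    def test_pure_noise_features_give_null_auc(self):
        import pandas as pd

        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        y = rng.normal(size=200)
        labels = (y > np.quantile(y, 0.75)).astype(int)
        preds = train_rf_cv(X, y * 0 + rng.normal(size=200), _cell(seeds=(1, 2)), n_trees=25)
        for s in preds:
            assert 0.35 <= auc(preds[s], labels) <= 0.65


def test_planted_signal_beats_shuffled_null_across_seeds():
    """On planted two-term cohorts the informative cell's cross-validated AUC
    clears 0.75 while label-shuffled nulls stay at chance (<= 0.65), for
    every one of 10 simulation seeds."""
    hits_signal = hits_null = 0
    for seed in range(10):
        _, _, tm, builder, mags, labels = planted_study(seed, n=250)
        X = builder.matrix(("RTx",)).loc[tm].reset_index(drop=True)
        y, lab = mags[tm], labels[tm]
        cell = _cell(seeds=(1, 2))
        res = screen_cell(X, y, lab, cell, n_trees=25)
        hits_signal += res.auc_mean >= 0.75
        rng = np.random.default_rng(seed)
        lab_shuffled = rng.permutation(lab)
        null_auc = np.mean([auc(res.cv_predictions[s], lab_shuffled) for s in (1, 2)])
        hits_null += null_auc <= 0.65
    assert hits_signal == 10
    assert hits_null == 10


# ---------------------------------------------------------------------------
# Greedy stepwise selection
# ---------------------------------------------------------------------------

def _fake_result(subset, paradigm, j_values, n_features=3):
    scheme = LabelScheme(paradigm, "deviation", 1.0)
    cell = ScreeningCell("obj", subset, scheme, tuple(range(len(j_values))), 5)
    per_init = [
        InitMetrics(
            seed=i,
            roc=np.array([[-np.inf, 1.0, 0.0], [np.inf, 0.0, 1.0]]),
            auc=0.5 + j / 2,
            youden=(0.0, (1 + j) / 2, (1 + j) / 2, j),
        )
        for i, j in enumerate(j_values)
    ]
    return ScreeningResult(cell=cell, n_features=n_features, cv_predictions={}, per_init=per_init)


class TestGreedySelection:
    def test_strong_parameter_fixed_first_then_weaker(self):
        results = []
        for subset in (("EMR", "RTx"), ("EMR",)):
            for paradigm in ("planning_criteria", "alara"):
                base = 0.8 if "RTx" in subset else 0.2
                bump = 0.05 if paradigm == "planning_criteria" else 0.0
                js = [base + bump + 0.01 * k for k in range(5)]
                results.append(_fake_result(subset, paradigm, js))
        report = greedy_stepwise_select(results, alpha=1.0)
        assert report.rounds[0].parameter == "include_RTx"
        assert report.rounds[0].chosen_level is True
        assert report.rounds[1].parameter == "paradigm"
        assert report.rounds[1].chosen_level == "planning_criteria"
        assert report.rounds[0].p_value <= report.rounds[1].p_value

    def test_indistinguishable_parameter_left_unfixed(self):
        results = []
        for subset in (("EMR", "RTx"), ("EMR",)):
            for paradigm in ("planning_criteria", "alara"):
                base = 0.8 if "RTx" in subset else 0.2
                js = [base + 0.01 * k for k in range(5)]  # paradigm-independent
                results.append(_fake_result(subset, paradigm, js))
        report = greedy_stepwise_select(results, alpha=0.05)
        assert "include_RTx" in report.fixed
        assert "paradigm" not in report.fixed

    def test_shortlist_collects_cells_within_band_of_best(self):
        results = [
            _fake_result(("RTx",), "alara", [0.80] * 5, n_features=2),
            _fake_result(("RTx", "pCT"), "alara", [0.79] * 5, n_features=6),
            _fake_result(("RTx", "EMR"), "alara", [0.50] * 5, n_features=6),
        ]
        report = greedy_stepwise_select(results, alpha=1e-9, delta_j=0.02)
        ids = {tuple(r.cell.category_subset) for r in report.shortlist}
        assert ("RTx",) in ids and ("RTx", "pCT") in ids
        assert ("RTx", "EMR") not in ids


class TestResolveTie:
    def _result_with_roc(self, roc_points, n_features):
        scheme = LabelScheme("alara", "deviation", 1.0)
        cell = ScreeningCell("obj", ("RTx",), scheme, (0,), 5)
        roc = np.array(roc_points)
        m = InitMetrics(seed=0, roc=roc, auc=0.8, youden=youden_optimal(roc))
        return ScreeningResult(cell=cell, n_features=n_features, cv_predictions={}, per_init=[m])

    def test_single_candidate_returned_unchanged(self):
        r = self._result_with_roc([[-np.inf, 1, 0], [np.inf, 0, 1]], 1)
        assert resolve_tie([r]) is r

    def test_uniformly_better_specificity_wins(self):
        a = self._result_with_roc([[-np.inf, 1.0, 0.8], [np.inf, 0.0, 1.0]], 5)
        b = self._result_with_roc([[-np.inf, 1.0, 0.6], [np.inf, 0.0, 1.0]], 1)
        assert resolve_tie([a, b]) is a

    def test_band_comparison_matches_dense_integration_oracle(self):
        # piecewise curves that cross inside the 0.60-0.80 sensitivity band
        a_pts = [[-np.inf, 1.0, 0.1], [0.3, 0.75, 0.7], [0.7, 0.55, 0.95], [np.inf, 0.0, 1.0]]
        b_pts = [[-np.inf, 1.0, 0.3], [0.4, 0.72, 0.55], [0.8, 0.5, 0.99], [np.inf, 0.0, 1.0]]
        a = self._result_with_roc(a_pts, 5)
        b = self._result_with_roc(b_pts, 1)

        def dense_mean_spec(roc):
            grid = np.linspace(0.60, 0.80, 10001)
            return np.trapezoid(
                [specificity_at_sensitivity(roc, s) for s in grid], grid
            ) / (0.80 - 0.60)

        winner = resolve_tie([a, b])
        oracle = a if dense_mean_spec(np.array(a_pts)) >= dense_mean_spec(np.array(b_pts)) else b
        assert winner is oracle


# ---------------------------------------------------------------------------
# Learning curve
# ---------------------------------------------------------------------------

def test_learning_curve_at_full_size_matches_direct_screening():
    _, _, tm, builder, mags, labels = planted_study(0, n=250)
    X = builder.matrix(("RTx",)).loc[tm].reset_index(drop=True)
    y, lab = mags[tm], labels[tm]
    cell = _cell(seeds=(1, 2))
    lc = learning_curve(X, y, lab, cell, sizes=(200,), n_trees=15)
    direct = screen_cell(X, y, lab, cell, n_trees=15)
    assert lc[200][0] == pytest.approx(direct.auc_mean, abs=1e-12)
    assert lc[200][1] == pytest.approx(direct.auc_sd, abs=1e-12)


def test_category_subsets_enumerates_all_nonempty_combinations():
    subs = category_subsets()
    assert len(subs) == 15
    assert ("EMR", "pCT", "RTx", "Obs") in subs
    no_obs = category_subsets(exclude=("Obs",))
    assert len(no_obs) == 7
    assert all("Obs" not in s for s in no_obs)
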
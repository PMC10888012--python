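"""Confusion metrics, ROC/AUC, MCC scans, balanced resampling."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from stabpath.evaluation import (
    DDG_GRID,
    RSA_GRID,
    ConfusionCounts,
    MethodSpec,
    ScoredLabel,
    balanced_resampling_eval,
    compare_methods,
    confusion_at_cutoff,
    make_grid,
    mcc_scan,
    metrics,
    roc_curve,
)
from stabpath.variant_model import ValidationError


def scored(pathogenic_scores, benign_scores):
    return [ScoredLabel(s, "pathogenic") for s in pathogenic_scores] + [
        ScoredLabel(s, "benign") for s in benign_scores
    ]


def concordance_auc(data):
    """Pair-counting oracle: fraction of (pathogenic, benign) pairs with the
    pathogenic score lower, ties scoring half."""
    pos = [d.score for d in data if d.label == "pathogenic"]
    neg = [d.score for d in data if d.label == "benign"]
    total = 0.0
    for p in pos:
        for b in neg:
            total += 1.0 if p < b else (0.5 if p == b else 0.0)
    return total / (len(pos) * len(neg))


def random_scored(rng, n_max=500, tie_prone=True):
    n = int(rng.integers(4, n_max + 1))
    if tie_prone and rng.random() < 0.5:
        scores = rng.integers(-5, 6, size=n).astype(float)  # heavy ties
    else:
        scores = rng.normal(size=n)
    labels = rng.random(n) < rng.uniform(0.2, 0.8)
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    return [
        ScoredLabel(float(s), "pathogenic" if l else "benign")
        for s, l in zip(scores, labels)
    ]


class TestConfusion:
    def test_simple_cutoffs(self):
        data = scored([-3], [1])
        c = confusion_at_cutoff(data, -1)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)
        c = confusion_at_cutoff(data, 2)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 0, 1, 0)

    def test_matches_per_record_loop(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            data = random_scored(rng, n_max=100)
            cutoff = float(rng.normal())
            c = confusion_at_cutoff(data, cutoff)
            tp = tn = fp = fn = 0
            for d in data:
                called = d.score <= cutoff
                if d.label == "pathogenic":
                    tp, fn = tp + called, fn + (not called)
                else:
                    fp, tn = fp + called, tn + (not called)
            assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            confusion_at_cutoff([], 0.0)


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert m == {"tpr": 1.0, "fpr": 0.0, "fnr": 0.0, "accuracy": 1.0, "mcc": 1.0}

    def test_worked_example(self):
        m = metrics(ConfusionCounts(tp=3, tn=4, fp=1, fn=2))
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["tpr"] == pytest.approx(0.6)
        assert m["fpr"] == pytest.approx(0.2)
        assert m["fnr"] == pytest.approx(0.4)
        assert m["mcc"] == pytest.approx(10 / math.sqrt(600), abs=1e-12)

    def test_label_swap_leaves_mcc_unchanged(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 50, size=4))
            a = metrics(ConfusionCounts(tp, tn, fp, fn))["mcc"]
            b = metrics(ConfusionCounts(tn, tp, fn, fp))["mcc"]
            assert a == pytest.approx(b, abs=1e-12)

    def test_zero_denominator_convention(self):
        # nothing predicted pathogenic: tp+fp = 0 zeroes a factor
        m = metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert m["mcc"] == 0.0

    def test_absent_class_rejected(self):
        with pytest.raises(ValidationError):
            metrics(ConfusionCounts(tp=5, tn=0, fp=0, fn=2))


class TestRocCurve:
    def test_perfect_separation(self):
        assert roc_curve(scored([-3, -2], [1, 2])).auc == pytest.approx(1.0)

    def test_all_scores_identical_is_chance(self):
        assert roc_curve(scored([0, 0], [0, 0, 0])).auc == pytest.approx(0.5)

    def test_worked_example_seven_ninths(self):
        data = scored([-2, -1, 0], [-1.5, 0.5, 1])
        assert roc_curve(data).auc == pytest.approx(7 / 9, abs=1e-12)

    def test_monotone_sweep_with_correct_endpoints(self):
        rng = np.random.default_rng(5)
        curve = roc_curve(random_scored(rng))
        tprs = [p[1] for p in curve.points]
        fprs = [p[2] for p in curve.points]
        assert tprs == sorted(tprs) and fprs == sorted(fprs)
        assert (tprs[0], fprs[0]) == (0.0, 0.0)
        assert (tprs[-1], fprs[-1]) == (1.0, 1.0)

    def test_trapezoid_equals_concordance_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            data = random_scored(rng, n_max=120)
            assert roc_curve(data).auc == pytest.approx(
                concordance_auc(data), abs=1e-9
            )

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            data = random_scored(rng, n_max=200)
            y = [d.label == "pathogenic" for d in data]
            s = [-d.score for d in data]  # sklearn: higher = positive
            assert roc_curve(data).auc == pytest.approx(
                roc_auc_score(y, s), abs=1e-9
            )

    def test_direction_flip_complements_auc(self):
        rng = np.random.default_rng(8)
        data = random_scored(rng, n_max=200, tie_prone=False)
        auc_le = roc_curve(data, direction="le").auc
        auc_ge = roc_curve(data, direction="ge").auc
        assert auc_le + auc_ge == pytest.approx(1.0, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_curve([ScoredLabel(0.0, "benign")])


def midpoint_scan_oracle(data):
    """Exhaustive MCC over all score midpoints plus outer sentinels."""
    values = sorted({d.score for d in data})
    cutoffs = [values[0] - 1.0]
    cutoffs += [(a + b) / 2 for a, b in zip(values, values[1:])]
    cutoffs += [values[-1] + 1.0, *values]
    return max(metrics(confusion_at_cutoff(data, c))["mcc"] for c in cutoffs)


class TestMccScan:
    def test_perfect_data_reaches_unity_between_classes(self):
        data = scored([-3, -2.5], [1, 2])
        scan = mcc_scan(data, {"min": -5, "max": 5, "step": 0.5})
        assert scan.optimal_mcc == pytest.approx(1.0)
        assert -2.5 <= scan.optimal_cutoff < 1.0

    def test_optimum_matches_midpoint_enumeration(self):
        data = scored([-2, -1, 0], [-1.5, 0.5, 1])
        scan = mcc_scan(data, {"min": -5, "max": 5, "step": 0.1})
        assert scan.optimal_mcc == pytest.approx(midpoint_scan_oracle(data))

    def test_single_cutoff_grid(self):
        data = scored([-1], [1])
        scan = mcc_scan(data, [0.0])
        assert scan.optimal_cutoff == 0.0

    def test_optimum_dominates_grid(self):
        rng = np.random.default_rng(9)
        data = random_scored(rng, n_max=100)
        scan = mcc_scan(data, DDG_GRID)
        assert scan.optimal_mcc == pytest.approx(max(scan.mcc_at))

    def test_ties_break_to_smallest_magnitude(self):
        data = scored([-3], [3])  # any cutoff in (-3, 3) gives MCC 1
        scan = mcc_scan(data, [-2.0, -1.0, 0.0, 1.0, 2.0])
        assert scan.optimal_cutoff == 0.0

    def test_make_grid_inclusive_endpoints(self):
        grid = make_grid(-5.0, 5.0, 0.1)
        assert len(grid) == 101
        assert grid[0] == -5.0 and grid[-1] == 5.0
        assert 1.1 in grid  # no floating-point drift at one decimal


class TestBalancedResampling:
    def test_sample_size_arithmetic(self):
        rng = np.random.default_rng(10)
        data = scored(rng.normal(size=1934), rng.normal(size=1405))
        summary = balanced_resampling_eval(data, 0.0, n_reps=2, seed=0)
        assert summary.sample_n_per_class == 702

    def test_label_determined_scores_give_perfect_accuracy(self):
        data = scored([-1.0] * 20, [1.0] * 20)
        summary = balanced_resampling_eval(data, 0.0, n_reps=20, seed=1)
        assert summary.accuracy_mean == 1.0 and summary.accuracy_sd == 0.0

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(11)
        data = scored(rng.normal(-1, 1, 100), rng.normal(1, 1, 100))
        a = balanced_resampling_eval(data, 0.0, n_reps=10, seed=5)
        b = balanced_resampling_eval(data, 0.0, n_reps=10, seed=5)
        assert a == b

    def test_mean_accuracy_matches_closed_form(self):
        """With class-conditional exceedance p and q at the cutoff, a balanced
        sample has expected accuracy (p + (1-q)) / 2."""
        rng = np.random.default_rng(12)
        n = 4000
        pathogenic = rng.normal(-1.0, 1.0, n)
        benign = rng.normal(1.0, 1.0, n)
        cutoff = 0.0
        p = np.mean(pathogenic <= cutoff)  # pathogenic correctly called
        q = np.mean(benign <= cutoff)      # benign miscalled
        expected = (p + (1 - q)) / 2
        data = scored(pathogenic, benign)
        summary = balanced_resampling_eval(data, cutoff, n_reps=100, seed=6)
        mc_se = summary.accuracy_sd / np.sqrt(100)
        # subsampling from the same finite population: the mean must sit on
        # the population value up to Monte-Carlo error
        assert abs(summary.accuracy_mean - expected) < max(3 * mc_se, 1e-3)

    def test_tiny_classes_rejected(self):
        with pytest.raises(ValidationError):
            balanced_resampling_eval(scored([0.0], [1.0]), 0.5)


class TestCompareMethods:
    def make_dataset(self, rng, n=300):
        labels = ["pathogenic"] * n + ["benign"] * n
        informative = np.concatenate([rng.normal(-1, 1, n), rng.normal(1, 1, n)])
        noise = rng.normal(size=2 * n)
        rsa = np.concatenate(
            [rng.beta(2, 4, n), rng.beta(2.6, 2.4, n)]
        )
        table = {"informative": informative, "noise": noise, "rsa": rsa}
        return table, labels

    def test_informative_method_beats_random(self):
        rng = np.random.default_rng(13)
        table, labels = self.make_dataset(rng)
        report = compare_methods(
            table,
            [
                MethodSpec("signal", lambda t: t["informative"]),
                MethodSpec("random", lambda t: t["noise"]),
            ],
            labels=labels,
            n_reps=50,
            seed=1,
        )
        by = report.set_index("method")
        assert by.loc["signal", "avg_accuracy"] > by.loc["random", "avg_accuracy"]

    def test_fixed_cutoff_source_delegates_to_scan(self):
        rng = np.random.default_rng(14)
        table, labels = self.make_dataset(rng)
        data = [
            ScoredLabel(float(s), l) for s, l in zip(table["informative"], labels)
        ]
        expected = mcc_scan(data, DDG_GRID).optimal_cutoff
        report = compare_methods(
            table,
            [MethodSpec("signal", lambda t: t["informative"], cutoff="mcc-opt")],
            labels=labels,
            n_reps=5,
            seed=2,
        )
        assert report.loc[0, "cutoff"] == expected

    def test_rsa_at_035_is_informative(self):
        rng = np.random.default_rng(15)
        table, labels = self.make_dataset(rng, n=500)
        report = compare_methods(
            table,
            [MethodSpec("rsa", lambda t: t["rsa"], cutoff=0.35, grid=RSA_GRID)],
            labels=labels,
            n_reps=50,
            seed=3,
        )
        assert report.loc[0, "avg_accuracy"] > 0.5
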
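import numpy as np
import pytest

from ppgbp.evaluate import (
    EvalReport,
    aami_check,
    attention_group_report,
    bland_altman,
    bland_altman_plot,
    bp_group,
    crossval,
    error_stats,
    make_folds,
    make_report,
    scatter_plot,
)
from ppgbp.model import PreparedDataset


class TestErrorStats:
    def test_perfect_equality_short_circuits_to_r_one(self):
        me, std, r = error_stats([100.0, 120.0, 140.0], [100.0, 120.0, 140.0])
        assert me == 0.0 and std == 0.0 and r == 1.0

    def test_hand_computed_example(self):
        me, std, r = error_stats([100.0, 120.0], [102.0, 118.0])
        assert me == 0.0
        assert std == pytest.approx(2 * np.sqrt(2))
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        y = np.array([100.0, 110.0, 120.0])
        _, _, r = error_stats(y, -y + 240.0)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_estimate_gives_missing_r(self):
        me, std, r = error_stats([100.0, 120.0], [110.0, 110.0])
        assert r is None
        assert me == 0.0

    def test_agrees_with_textbook_formulas(self):
        rng = np.random.default_rng(0)
        y = rng.normal(120, 15, 200)
        yh = y + rng.normal(0, 5, 200)
        me, std, r = error_stats(y, yh)
        e = yh - y
        assert me == pytest.approx(e.sum() / len(e), abs=1e-10)
        assert std == pytest.approx(
            np.sqrt(((e - e.mean()) ** 2).sum() / (len(e) - 1)), abs=1e-10
        )
        num = ((y - y.mean()) * (yh - yh.mean())).sum()
        den = np.sqrt(((y - y.mean()) ** 2).sum() * ((yh - yh.mean()) ** 2).sum())
        assert r == pytest.approx(num / den, abs=1e-10)


class TestBlandAltman:
    def test_zero_differences(self):
        limits, _, inside = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert limits == (0.0, 0.0, 0.0)
        assert inside == 1.0

    def test_hand_computed_limits(self):
        (mean_diff, lower, upper), pairs, _ = bland_altman(
            [100.0, 100.0], [102.0, 98.0]
        )
        assert mean_diff == 0.0
        assert upper == pytest.approx(1.96 * 2 * np.sqrt(2), abs=1e-6)
        assert lower == pytest.approx(-upper)
        assert pairs["diff"].tolist() == [2.0, -2.0]

    def test_gaussian_coverage_near_95_percent(self):
        rng = np.random.default_rng(42)
        y = rng.normal(120, 15, 10000)
        yh = y + rng.normal(0, 5, 10000)
        _, _, inside = bland_altman(y, yh)
        assert inside == pytest.approx(0.95, abs=0.01)


class TestAAMI:
    @pytest.mark.parametrize(
        "me, std, expected",
        [
            (0.21, 7.72, True),   # within 5 and 8 mmHg
            (0.43, 9.35, False),  # SD above the 8 mmHg bound
            (5.0, 8.0, True),     # boundaries inclusive
            (-5.1, 7.0, False),
        ],
    )
    def test_criterion(self, me, std, expected):
        assert aami_check(me, std) is expected

    def test_report_limits_consistent(self):
        rng = np.random.default_rng(1)
        y = rng.normal(120, 15, 50)
        yh = y + rng.normal(0, 4, 50)
        rep = make_report("SBP", y, yh)
        mean_diff, lower, upper = rep.bland_altman
        assert lower == pytest.approx(rep.me - 1.96 * rep.std)
        assert upper == pytest.approx(rep.me + 1.96 * rep.std)


class TestFolds:
    def test_even_partition(self):
        ids = [f"S{i}" for i in range(10)]
        split = make_folds(ids, k=5, seed=0)
        sizes = [len(split.test_subjects(f)) for f in range(1, 6)]
        assert sizes == [2] * 5

    def test_disjoint_and_deterministic(self):
        ids = [f"S{i}" for i in range(13)]
        a = make_folds(ids, k=5, seed=3)
        b = make_folds(ids, k=5, seed=3)
        assert a.assignments == b.assignments
        for f in range(1, 6):
            assert not (a.test_subjects(f) & a.train_subjects(f))

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], k=5, seed=0)


class _MeanRecipe:
    """Stub model: predicts the training-set mean (tests crossval plumbing)."""

    target = "DBP"

    def __init__(self, train_set):
        self.mean = float(train_set.dbp.mean())
        _MeanRecipe.target = "DBP"

    def predict_batch(self, dataset):
        return np.full(len(dataset), self.mean), None


class TestCrossval:
    def test_structure_and_pooling(self, tiny_dataset):
        reports, pooled = crossval(tiny_dataset, _MeanRecipe, k=4, seed=0)
        assert len(reports) == 4
        assert isinstance(pooled, EvalReport)
        # pooled ME equals the case-weighted mean of fold MEs
        weighted = sum(r.me * r.n_cases for r in reports) / sum(
            r.n_cases for r in reports
        )
        assert pooled.me == pytest.approx(weighted, abs=1e-10)

    def test_subject_disjointness_enforced(self, tiny_dataset):
        seen = []

        class Spy(_MeanRecipe):
            def __init__(self, train_set):
                super().__init__(train_set)
                seen.append(set(train_set.subject_ids))

        _, _ = crossval(tiny_dataset, Spy, k=4, seed=0)
        all_subjects = set(tiny_dataset.subject_ids)
        for train_subjects in seen:
            test_subjects = all_subjects - train_subjects
            assert test_subjects and not (train_subjects & test_subjects)


class TestBPGroups:
    def test_threshold_classification(self):
        assert bp_group(150.0, 80.0) == "hypertensive"
        assert bp_group(120.0, 95.0) == "hypertensive"
        assert bp_group(88.0, 70.0) == "hypotensive"
        assert bp_group(120.0, 58.0) == "hypotensive"
        assert bp_group(120.0, 80.0) == "normotensive"

    def test_uniform_weights_uniform_means(self):
        n = 12
        sbp = np.full(n, 120.0)
        dbp = np.full(n, 80.0)
        w = np.full((n, 9), 1 / 9)
        rep = attention_group_report(sbp, dbp, w)
        assert rep["normotensive"]["n"] == n
        assert rep["normotensive"]["mean_weights"] == pytest.approx(np.full(9, 1 / 9))
        assert rep["hypertensive"]["n"] == 0
        assert rep["hypertensive"]["mean_weights"] is None

    def test_hand_computed_group_means(self):
        sbp = np.array([150.0, 150.0, 85.0])
        dbp = np.array([95.0, 95.0, 55.0])
        w = np.zeros((3, 9))
        w[0, 0] = 1.0
        w[1, 1] = 1.0
        w[2, 4] = 1.0
        rep = attention_group_report(sbp, dbp, w)
        expected_ht = np.zeros(9)
        expected_ht[0] = expected_ht[1] = 0.5
        assert rep["hypertensive"]["mean_weights"] == pytest.approx(expected_ht)
        assert rep["hypotensive"]["mean_weights"][4] == 1.0

    def test_group_means_stay_on_simplex(self):
        rng = np.random.default_rng(0)
        n = 50
        sbp = rng.uniform(85, 175, n)
        dbp = rng.uniform(55, 105, n)
        raw = rng.random((n, 9))
        w = raw / raw.sum(axis=1, keepdims=True)
        rep = attention_group_report(sbp, dbp, w)
        for g, v in rep.items():
            if v["n"]:
                assert v["mean_weights"].sum() == pytest.approx(1.0, abs=1e-6)


class TestPlots:
    def test_plot_files_written(self, tmp_path):
        rng = np.random.default_rng(0)
        y = rng.normal(120, 15, 40)
        yh = y + rng.normal(0, 5, 40)
        s = tmp_path / "scatter.png"
        b = tmp_path / "ba.png"
        scatter_plot(y, yh, "SBP", s)
        bland_altman_plot(y, yh, "SBP", b)
        assert s.stat().st_size > 0
        assert b.stat().st_size > 0
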
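"""Agreement metrics against brute-force loop oracles, and the AAMI/BHS
device-standard verdict logic."""

import math

import numpy as np
import pytest

from mstbp.evaluation import (
    EvalReport,
    aami_check,
    average_reports,
    bhs_grade,
    bland_altman,
    evaluate,
    mae,
    mean_error,
    pearson_r,
    sd,
)
from mstbp.preprocess import BPLabels, Segment


# -- independent element-loop oracles ---------------------------------------

def _loop_me(y, z):
    return sum(a - b for a, b in zip(y, z)) / len(y)


def _loop_mae(y, z):
    return sum(abs(b - a) for a, b in zip(y, z)) / len(y)


def _loop_sd(y, z):
    d = [b - a for a, b in zip(y, z)]
    m = sum(d) / len(d)
    return math.sqrt(sum((x - m) ** 2 for x in d) / (len(d) - 1))


def _loop_r(y, z):
    my = sum(y) / len(y)
    mz = sum(z) / len(z)
    num = sum((b - mz) * (a - my) for a, b in zip(y, z))
    den = math.sqrt(sum((a - my) ** 2 for a in y) * sum((b - mz) ** 2 for b in z))
    return num / den


def _loop_cp(errors, thr):
    return 100.0 * sum(1 for e in errors if e <= thr) / len(errors)


class TestMetricArithmetic:
    def test_mean_error_example(self):
        assert mean_error([100.0, 100.0], [98.0, 104.0]) == pytest.approx(-1.0)

    def test_mean_error_antisymmetric(self):
        y = np.array([120.0, 118.0, 90.0])
        z = np.array([119.0, 121.0, 95.0])
        assert mean_error(y, z) == pytest.approx(-mean_error(z, y))

    def test_constant_offset(self):
        y = np.array([100.0, 110.0, 120.0])
        z = y + 3.0
        assert mae(y, z) == pytest.approx(3.0)
        assert sd(y, z) == pytest.approx(0.0)
        assert pearson_r(y, z) == pytest.approx(1.0)

    def test_anticorrelation(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(y, -y) == pytest.approx(-1.0)

    def test_matches_oracles_on_many_seeded_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(3, 40)
            y = rng.uniform(60, 180, n)
            z = y + rng.normal(0, 8, n)
            assert mean_error(y, z) == pytest.approx(_loop_me(y, z), abs=1e-12)
            assert mae(y, z) == pytest.approx(_loop_mae(y, z), abs=1e-12)
            assert sd(y, z) == pytest.approx(_loop_sd(y, z), abs=1e-12)
            assert pearson_r(y, z) == pytest.approx(_loop_r(y, z), abs=1e-12)

    def test_guards(self):
        with pytest.raises(ValueError):
            mean_error([], [])
        with pytest.raises(ValueError):
            sd([1.0], [2.0])
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0], [2.0, 3.0])


class TestAamiCheck:
    def test_published_summary_passes(self):
        # the bedside-data summary (ME 0.007, SD 5.81, 514 subjects)
        assert aami_check(0.007, 5.81, 514)["pass"]

    def test_me_boundary(self):
        assert not aami_check(5.1, 7.0, 100)["pass"]
        assert aami_check(5.0, 7.0, 100)["pass"]

    def test_inclusive_bounds(self):
        assert aami_check(0.0, 8.0, 85)["pass"]
        assert not aami_check(0.0, 8.01, 85)["pass"]
        assert not aami_check(0.0, 8.0, 84)["pass"]

    def test_monotone_margins(self):
        worse = aami_check(4.0, 7.0, 90)["margins"]
        better = aami_check(2.0, 5.0, 200)["margins"]
        assert all(better[k] >= worse[k] for k in worse)


class TestBhsGrade:
    def test_all_zero_grade_a(self):
        out = bhs_grade(np.zeros(50))
        assert (out["cp5"], out["cp10"], out["cp15"]) == (100.0, 100.0, 100.0)
        assert out["grade"] == "A"

    def test_constructed_grade_b(self):
        errors = np.array([4.0] * 59 + [9.0] * 30 + [14.0] * 10 + [20.0])
        out = bhs_grade(errors)
        assert (out["cp5"], out["cp10"], out["cp15"]) == (59.0, 89.0, 99.0)
        assert out["grade"] == "B"  # misses A's 60% at 5 mmHg

    def test_all_large_grade_d(self):
        out = bhs_grade(np.full(100, 16.0))
        assert (out["cp5"], out["cp10"], out["cp15"]) == (0.0, 0.0, 0.0)
        assert out["grade"] == "D"

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            e = np.abs(rng.normal(0, 7, rng.integers(5, 80)))
            out = bhs_grade(e)
            for key, thr in (("cp5", 5.0), ("cp10", 10.0), ("cp15", 15.0)):
                assert out[key] == pytest.approx(_loop_cp(e, thr), abs=1e-12)

    def test_improving_one_error_never_lowers_grade(self):
        rng = np.random.default_rng(2)
        order = "ABCD"
        for _ in range(20):
            e = np.abs(rng.normal(0, 8, 40))
            g0 = bhs_grade(e)["grade"]
            e2 = e.copy()
            e2[int(rng.integers(0, 40))] = 0.0
            assert order.index(bhs_grade(e2)["grade"]) <= order.index(g0)


class TestBlandAltman:
    def test_perfect_agreement_collapses(self):
        y = np.array([100.0, 120.0, 140.0])
        out = bland_altman(y, y)
        assert out["mean_diff"] == out["lower"] == out["upper"] == 0.0

    def test_symmetric_errors_zero_mean(self):
        y = np.full(10, 100.0)
        z = y + np.array([2.0, -2.0] * 5)
        assert bland_altman(y, z)["mean_diff"] == pytest.approx(0.0)

    def test_gaussian_coverage(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(80, 160, 10_000)
        z = y + rng.normal(0, 5, 10_000)
        out = bland_altman(y, z)
        assert out["fraction_inside"] == pytest.approx(0.95, abs=0.01)


class _StubModel:
    """Echoes the reference labels: a perfect estimator."""

    def __init__(self, labels):
        self._labels = labels

    def forward(self, x):
        return self._labels.copy()


def _segments_from_labels(labels, subjects=None):
    segs = []
    for i, (s, d, m) in enumerate(labels):
        subject = subjects[i] if subjects else f"s{i:03d}"
        segs.append(
            Segment(
                x=np.zeros((2, 1000)),
                labels=BPLabels(sbp=s, dbp=d, map=m),
                subject_id=subject,
            )
        )
    return segs


class TestEvaluate:
    def test_perfect_stub_model(self):
        rng = np.random.default_rng(4)
        sbp = rng.uniform(90, 170, 90)
        dbp = rng.uniform(60, 100, 90)
        labels = np.stack([sbp, dbp, (sbp + 2 * dbp) / 3], axis=1)
        report = evaluate(_StubModel(labels), _segments_from_labels(labels))
        for task in ("sbp", "dbp", "map"):
            m = report.tasks[task]
            assert m.mae == m.me == m.sd == 0.0
            assert m.bhs["grade"] == "A"
        assert report.aami_pass  # 90 distinct subjects

    def test_report_consistent_with_standalone_metrics(self):
        rng = np.random.default_rng(5)
        ref = rng.uniform(80, 160, (40, 3))
        est = ref + rng.normal(0, 4, (40, 3))
        report = evaluate(_StubModel(est), _segments_from_labels(ref))
        m = report.tasks["sbp"]
        assert m.me == pytest.approx(mean_error(ref[:, 0], est[:, 0]))
        assert m.mae == pytest.approx(mae(ref[:, 0], est[:, 0]))
        assert m.sd == pytest.approx(sd(ref[:, 0], est[:, 0]))
        assert m.r == pytest.approx(pearson_r(ref[:, 0], est[:, 0]))

    def test_average_reports_is_unweighted_mean(self):
        rng = np.random.default_rng(6)
        reports = []
        for _ in range(3):
            ref = rng.uniform(80, 160, (30, 3))
            est = ref + rng.normal(0, 4, (30, 3))
            reports.append(evaluate(_StubModel(est), _segments_from_labels(ref)))
        avg = average_reports(reports)
        expected = np.mean([r.tasks["dbp"].mae for r in reports])
        assert avg.tasks["dbp"].mae == pytest.approx(expected, abs=1e-12)

    def test_report_saves_text_and_csv(self, tmp_path):
        ref = np.random.default_rng(7).uniform(80, 160, (20, 3))
        report = evaluate(_StubModel(ref + 1.0), _segments_from_labels(ref))
        report.save(tmp_path)
        assert (tmp_path / "report.csv").exists()
        assert "SBP" in (tmp_path / "report.txt").read_text()
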
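"""Accuracy metrics and device-validation verdicts.

Per task (SBP/DBP/MAP): Pearson correlation r, mean error ME = mean(y - z)
(reference minus estimate), mean absolute error MAE, and SD — the sample
standard deviation of the signed differences about their own mean, the
quantity Bland-Altman limits are built from.

Device standards:

* AAMI — pass iff |ME| <= 5 mmHg, SD <= 8 mmHg, and at least 85 subjects
  (all bounds inclusive).
* BHS — cumulative percentages of absolute errors within 5/10/15 mmHg;
  grade A requires 60/85/95%, B 50/75/90%, C 40/65/80%, else D.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TaskMetrics",
    "EvalReport",
    "mean_error",
    "mae",
    "sd",
    "pearson_r",
    "aami_check",
    "bhs_grade",
    "bland_altman",
    "evaluate",
    "average_reports",
    "error_histogram",
]

TASKS = ("sbp", "dbp", "map")
BHS_THRESHOLDS = {"A": (60.0, 85.0, 95.0), "B": (50.0, 75.0, 90.0), "C": (40.0, 65.0, 80.0)}
AAMI_ME_LIMIT = 5.0
AAMI_SD_LIMIT = 8.0
AAMI_MIN_SUBJECTS = 85


def _check_pair(ref, est, min_n=1):
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    if ref.shape != est.shape or ref.ndim != 1:
        raise ValueError("ref and est must be 1-D arrays of equal length")
    if len(ref) < min_n:
        raise ValueError(f"need at least {min_n} samples, got {len(ref)}")
    return ref, est


def mean_error(ref: np.ndarray, est: np.ndarray) -> float:
    """ME = mean(reference - estimate), in mmHg."""
    ref, est = _check_pair(ref, est)
    return float(np.mean(ref - est))


def mae(ref: np.ndarray, est: np.ndarray) -> float:
    """Mean absolute error, mmHg."""
    ref, est = _check_pair(ref, est)
    return float(np.mean(np.abs(est - ref)))


def sd(ref: np.ndarray, est: np.ndarray, literal: bool = False) -> float:
    """Dispersion of the errors, mmHg (n-1 denominator).

    Default: sample SD of the signed differences about their own mean.
    ``literal=True`` centres (est - ref) on mean(ref - est) instead — an
    audit variant reproducing a sign-inconsistent printed formula.
    """
    ref, est = _check_pair(ref, est, min_n=2)
    d = est - ref
    center = mean_error(ref, est) if literal else d.mean()
    return float(np.sqrt(np.sum((d - center) ** 2) / (len(d) - 1)))


def pearson_r(ref: np.ndarray, est: np.ndarray) -> float:
    """Pearson correlation coefficient between reference and estimate."""
    ref, est = _check_pair(ref, est, min_n=2)
    yc = ref - ref.mean()
    zc = est - est.mean()
    denom = np.sqrt(np.sum(yc**2) * np.sum(zc**2))
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.sum(yc * zc) / denom)


def aami_check(me: float, sd_value: float, n_subjects: int) -> dict:
    """AAMI verdict with per-criterion margins (positive margin = satisfied)."""
    if not (np.isfinite(me) and np.isfinite(sd_value)):
        raise ValueError("ME and SD must be finite")
    margins = {
        "me": AAMI_ME_LIMIT - abs(me),
        "sd": AAMI_SD_LIMIT - sd_value,
        "subjects": n_subjects - AAMI_MIN_SUBJECTS,
    }
    return {"pass": all(v >= 0 for v in margins.values()), "margins": margins}


def bhs_grade(abs_errors: np.ndarray) -> dict:
    """Cumulative error percentages at 5/10/15 mmHg and the resulting grade."""
    e = np.asarray(abs_errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error vector")
    cp = tuple(100.0 * np.mean(e <= thr) for thr in (5.0, 10.0, 15.0))
    grade = "D"
    for g in ("A", "B", "C"):
        if all(c >= t for c, t in zip(cp, BHS_THRESHOLDS[g])):
            grade = g
            break
    return {"cp5": cp[0], "cp10": cp[1], "cp15": cp[2], "grade": grade}


def bland_altman(ref: np.ndarray, est: np.ndarray) -> dict:
    """Mean difference (est - ref), +-1.96 SD limits of agreement, and the
    fraction of points inside them."""
    ref, est = _check_pair(ref, est, min_n=2)
    d = est - ref
    mean_d = float(d.mean())
    s = float(np.std(d, ddof=1))
    lo, hi = mean_d - 1.96 * s, mean_d + 1.96 * s
    inside = float(np.mean((d >= lo) & (d <= hi)))
    return {"mean_diff": mean_d, "lower": lo, "upper": hi, "fraction_inside": inside}


def error_histogram(errors: np.ndarray, lo: float = -20.0, hi: float = 20.0, width: float = 1.0):
    """Signed-error histogram with 1-mmHg bins over [-20, 20] by default."""
    edges = np.arange(lo, hi + width, width)
    counts, edges = np.histogram(np.asarray(errors, dtype=float), bins=edges)
    return counts, edges


@dataclass
class TaskMetrics:
    """Agreement metrics for one task (SBP, DBP, or MAP)."""

    r: float
    me: float
    mae: float
    sd: float
    n: int
    bhs: dict
    bland_altman: dict
    histogram_counts: np.ndarray | None = None


@dataclass
class EvalReport:
    """Full evaluation: per-task metrics plus device-standard verdicts."""

    tasks: dict[str, TaskMetrics]
    n_subjects: int
    aami: dict[str, dict] = field(default_factory=dict)

    @property
    def aami_pass(self) -> bool:
        return all(v["pass"] for v in self.aami.values())

    def bhs_grades(self) -> dict[str, str]:
        return {t: m.bhs["grade"] for t, m in self.tasks.items()}

    def to_rows(self) -> list[dict]:
        rows = []
        for task, m in self.tasks.items():
            rows.append(
                {
                    "task": task,
                    "n": m.n,
                    "r": m.r,
                    "me": m.me,
                    "mae": m.mae,
                    "sd": m.sd,
                    "cp5": m.bhs["cp5"],
                    "cp10": m.bhs["cp10"],
                    "cp15": m.bhs["cp15"],
                    "bhs_grade": m.bhs["grade"],
                    "aami_pass": self.aami[task]["pass"] if task in self.aami else "",
                }
            )
        return rows

    def save(self, directory: str | Path) -> None:
        """Write report.csv and report.txt (plus per-task histogram CSVs)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = self.to_rows()
        with open(directory / "report.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)
        lines = [f"subjects: {self.n_subjects}", f"AAMI: {'pass' if self.aami_pass else 'fail'}"]
        for row in rows:
            lines.append(
                f"{row['task'].upper()}: r={row['r']:.3f} ME={row['me']:.3f} "
                f"MAE={row['mae']:.3f} SD={row['sd']:.3f} BHS={row['bhs_grade']}"
            )
        (directory / "report.txt").write_text("\n".join(lines) + "\n")
        for task, m in self.tasks.items():
            if m.histogram_counts is not None:
                counts, edges = m.histogram_counts
                with open(directory / f"histogram_{task}.csv", "w", newline="") as fh:
                    w = csv.writer(fh)
                    w.writerow(["bin_left", "bin_right", "count"])
                    w.writerows(zip(edges[:-1], edges[1:], counts))


def _task_metrics(ref: np.ndarray, est: np.ndarray) -> TaskMetrics:
    errors = np.abs(est - ref)
    try:
        r = pearson_r(ref, est)
    except ValueError:
        r = float("nan")  # constant vector (e.g. a perfect stub estimator)
    return TaskMetrics(
        r=r,
        me=mean_error(ref, est),
        mae=mae(ref, est),
        sd=sd(ref, est) if len(ref) > 1 else 0.0,
        n=len(ref),
        bhs=bhs_grade(errors),
        bland_altman=bland_altman(ref, est) if len(ref) > 1 else {},
        histogram_counts=error_histogram(est - ref),
    )


def evaluate(model, test_segments) -> EvalReport:
    """Run the model on held-out segments and assemble the full report."""
    if not test_segments:
        raise ValueError("empty test set")
    x = np.stack([s.x for s in test_segments]).astype(float)
    ref = np.stack([s.labels.as_array() for s in test_segments])
    est = model.forward(x)  # evaluation mode: batch-norm uses running stats
    n_subjects = len({s.subject_id for s in test_segments})
    tasks = {}
    aami = {}
    for j, task in enumerate(TASKS):
        m = _task_metrics(ref[:, j], est[:, j])
        tasks[task] = m
        aami[task] = aami_check(m.me, m.sd, n_subjects)
    return EvalReport(tasks=tasks, n_subjects=n_subjects, aami=aami)


def average_reports(reports: list[EvalReport]) -> EvalReport:
    """Unweighted mean of per-fold metrics (the cross-validation summary)."""
    if not reports:
        raise ValueError("no reports to average")
    tasks = {}
    n_subjects = int(round(np.mean([r.n_subjects for r in reports])))
    aami = {}
    for task in TASKS:
        ms = [r.tasks[task] for r in reports]
        mean_bhs = {
            key: float(np.mean([m.bhs[key] for m in ms])) for key in ("cp5", "cp10", "cp15")
        }
        grade = "D"
        for g in ("A", "B", "C"):
            if all(
                mean_bhs[k] >= t
                for k, t in zip(("cp5", "cp10", "cp15"), BHS_THRESHOLDS[g])
            ):
                grade = g
                break
        mean_bhs["grade"] = grade
        avg = TaskMetrics(
            r=float(np.mean([m.r for m in ms])),
            me=float(np.mean([m.me for m in ms])),
            mae=float(np.mean([m.mae for m in ms])),
            sd=float(np.mean([m.sd for m in ms])),
            n=int(sum(m.n for m in ms)),
            bhs=mean_bhs,
            bland_altman={},
            histogram_counts=None,
        )
        tasks[task] = avg
        aami[task] = aami_check(avg.me, avg.sd, n_subjects)
    return EvalReport(tasks=tasks, n_subjects=n_subjects, aami=aami)
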
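"""Detector evaluation: matching, precision/recall, PR curves, FP/h, workload.

Matching rule: a detection may claim an annotation iff its peak time falls
inside the annotation interval dilated by ``tolerance_s`` on both sides;
assignment is greedy by descending detection score and one-to-one (among
eligible annotations the closest midpoint wins).  Precision = TP/(TP+FP),
recall = TP/(TP+FN).  Average precision is the step-wise area under the
precision-recall curve swept over the unique detection scores.

The workload arithmetic converts a false-positive rate into analyst review
time: an experienced analyst verifies up to 2,000 detections per working
hour, and a detector is operationally useful below ~20 false positives per
recording hour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detector import Detection
from .errors import EvaluationError
from .signal_io import Annotation

__all__ = [
    "MatchResult",
    "PRCurve",
    "WorkloadEstimate",
    "match",
    "precision_recall",
    "pr_curve",
    "fp_per_hour",
    "recall_vs_fph",
    "workload",
    "relative_improvement",
]


@dataclass(frozen=True)
class MatchResult:
    """One-to-one assignment of detections to annotations."""

    tp_pairs: tuple  # (detection, annotation) pairs
    fp_detections: tuple
    fn_annotations: tuple

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_detections)

    @property
    def fn(self) -> int:
        return len(self.fn_annotations)


@dataclass(frozen=True)
class PRCurve:
    thresholds: np.ndarray  # descending
    precision: np.ndarray
    recall: np.ndarray
    average_precision: float


@dataclass(frozen=True)
class WorkloadEstimate:
    """Analyst review-time economics for a detector operating point."""

    fp_count: float
    verification_hours_fp: float
    verification_hours_tp: float
    total_hours: float
    fp_per_hour: float
    recording_hours: float
    n_true_calls: int
    review_rate_per_hour: float = 2000.0
    fp_budget_per_hour: float = 20.0


def match(
    detections: list[Detection],
    annotations: list[Annotation],
    tolerance_s: float = 0.5,
) -> MatchResult:
    """Greedily match detections to annotations, one-to-one, by score."""
    ids = {d.stream_id for d in detections if d.stream_id}
    if len(ids) > 1:
        raise EvaluationError(f"detections mix streams: {sorted(ids)}")
    order = sorted(
        range(len(detections)),
        key=lambda i: (-detections[i].score, detections[i].peak_time_s),
    )
    taken = [False] * len(annotations)
    tp, fp = [], []
    for i in order:
        det = detections[i]
        best, best_dist = None, np.inf
        for j, ann in enumerate(annotations):
            if taken[j]:
                continue
            if (
                ann.begin_time_s - tolerance_s
                <= det.peak_time_s
                <= ann.end_time_s + tolerance_s
            ):
                dist = abs(det.peak_time_s - ann.midpoint_s)
                if dist < best_dist:
                    best, best_dist = j, dist
        if best is None:
            fp.append(det)
        else:
            taken[best] = True
            tp.append((det, annotations[best]))
    fn = tuple(a for j, a in enumerate(annotations) if not taken[j])
    return MatchResult(tuple(tp), tuple(fp), fn)


@dataclass(frozen=True)
class PrecisionRecall:
    precision: float  # NaN when undefined
    recall: float
    precision_defined: bool = True
    recall_defined: bool = True


def precision_recall(m: MatchResult) -> PrecisionRecall:
    """Exact TP/(TP+FP) and TP/(TP+FN); undefined ratios are flagged NaN."""
    p_def, r_def = m.tp + m.fp > 0, m.tp + m.fn > 0
    return PrecisionRecall(
        precision=m.tp / (m.tp + m.fp) if p_def else float("nan"),
        recall=m.tp / (m.tp + m.fn) if r_def else float("nan"),
        precision_defined=p_def,
        recall_defined=r_def,
    )


def _threshold_sweep(detections, annotations, tolerance_s):
    """Yield (threshold, MatchResult) over descending unique scores."""
    thresholds = sorted({d.score for d in detections}, reverse=True)
    for thr in thresholds:
        surviving = [d for d in detections if d.score >= thr]
        yield thr, match(surviving, annotations, tolerance_s)


def pr_curve(
    detections: list[Detection],
    annotations: list[Annotation],
    tolerance_s: float = 0.5,
) -> PRCurve:
    """Precision-recall curve and step-wise average precision."""
    if not annotations:
        raise EvaluationError("PR curve requires at least one annotation")
    thr, prec, rec = [], [], []
    for t, m in _threshold_sweep(detections, annotations, tolerance_s):
        pr = precision_recall(m)
        thr.append(t)
        prec.append(pr.precision if pr.precision_defined else 1.0)
        rec.append(pr.recall)
    ap = 0.0
    prev_r = 0.0
    for p, r in zip(prec, rec):
        ap += (r - prev_r) * p
        prev_r = r
    return PRCurve(
        thresholds=np.asarray(thr),
        precision=np.asarray(prec),
        recall=np.asarray(rec),
        average_precision=float(ap),
    )


def fp_per_hour(m: MatchResult, recording_hours: float) -> float:
    if recording_hours <= 0:
        raise EvaluationError("recording_hours must be positive")
    return m.fp / recording_hours


def recall_vs_fph(
    detections: list[Detection],
    annotations: list[Annotation],
    recording_hours: float,
    tolerance_s: float = 0.5,
) -> list[tuple[float, float, float]]:
    """(threshold, FP/h, recall) triples over the descending score sweep.

    Includes the degenerate all-suppressed point (0 FP/h, 0 recall).
    """
    if recording_hours <= 0:
        raise EvaluationError("recording_hours must be positive")
    points = [(float("inf"), 0.0, 0.0)]
    for t, m in _threshold_sweep(detections, annotations, tolerance_s):
        points.append((t, m.fp / recording_hours, precision_recall(m).recall))
    return points


def workload(
    fp_rate_per_hour: float,
    recording_hours: float,
    n_true_calls: int,
    review_rate_per_hour: float = 2000.0,
    fp_budget_per_hour: float = 20.0,
) -> WorkloadEstimate:
    """Analyst hours needed to verify a detector's output."""
    if min(fp_rate_per_hour, recording_hours, n_true_calls) < 0:
        raise EvaluationError("workload inputs must be non-negative")
    if review_rate_per_hour <= 0:
        raise EvaluationError("review_rate_per_hour must be positive")
    fp_count = fp_rate_per_hour * recording_hours
    v_fp = fp_count / review_rate_per_hour
    v_tp = n_true_calls / review_rate_per_hour
    return WorkloadEstimate(
        fp_count=fp_count,
        verification_hours_fp=v_fp,
        verification_hours_tp=v_tp,
        total_hours=v_fp + v_tp,
        fp_per_hour=fp_rate_per_hour,
        recording_hours=recording_hours,
        n_true_calls=n_true_calls,
        review_rate_per_hour=review_rate_per_hour,
        fp_budget_per_hour=fp_budget_per_hour,
    )


def relative_improvement(recall: float, baseline_recall: float) -> int:
    """Percent recall improvement over a baseline, rounded to integer percent."""
    if baseline_recall <= 0:
        raise EvaluationError("baseline_recall must be positive")
    return int(round(100.0 * (recall - baseline_recall) / baseline_recall))


def plot_pr_curve(curve: PRCurve, ax=None, **kwargs):
    """Step plot of a PR curve (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.step(curve.recall, curve.precision, where="post", **kwargs)
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.05)
    ax.set_title(f"AP = {curve.average_precision:.3f}")
    return ax
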
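"""End-to-end orchestration: the two-stage training protocol and experiments.

Stage 1 trains a preliminary classifier on annotated positives plus random
negatives (both shift-augmented).  Stage 2 runs that classifier as a
detector over the training streams, pools its confident false positives as
hard negatives, and retrains from a fresh random initialization.  An
experiment then detects on held-out streams and reports PR/AP, FP-per-hour
vs recall, and the analyst-workload block.

All randomness flows from one global seed through fixed per-stage offsets,
so every stage is independently reproducible.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import dataset as ds
from . import evaluation as ev
from .detector import non_max_suppress, score_stream
from .errors import LeakageError
from .features import StftParams
from .model import TrainConfig, build_architecture, train, train_replicates
from .signal_io import Annotation, AudioStream

__all__ = ["RunConfig", "StageArtifacts", "two_stage_train", "run_experiment"]

# per-stage seed offsets (added to the global seed, kept below 2**31)
_STAGE_SEED = {"negatives": 11, "augment": 23, "stage1": 37, "stage2": 53}


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of a full run."""

    arch: str = "lenet_variant"
    feature_params: StftParams = field(default_factory=StftParams)
    train_config: TrainConfig = field(default_factory=TrainConfig)
    normalization_mode: str = "unit_frobenius"
    negatives_per_positive: float = 2.0
    guard_s: float = 1.0
    copies_per_example: int = 1
    max_shift_s: float = 0.2
    mining_prob_threshold: float = 0.5
    dedup_tol_s: float = 0.1
    max_hard_negatives: int | None = None
    detect_min_prob: float = 0.05
    detect_hop_s: float = 0.1
    nms_radius_s: float = 1.0
    match_tolerance_s: float = 0.5
    review_rate_per_hour: float = 2000.0
    fp_budget_per_hour: float = 20.0
    n_replicates: int = 1
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _STAGE_SEED[stage]) % (2**31)


@dataclass
class StageArtifacts:
    """Everything the two training stages produced."""

    stage1_examples: list
    stage2_examples: list
    hard_negatives: list
    stage1_scorer: object
    stage2_scorer: object
    stage2_replicates: list
    counts: dict


def _build_stage1_examples(streams, truths, config: RunConfig):
    positives, negatives = [], []
    for stream, anns in zip(streams, truths):
        for ann in anns:
            positives.append(
                ds.extract_positive(stream, ann, config.feature_params)
            )
        n_neg = int(round(config.negatives_per_positive * len(anns)))
        if n_neg:
            negatives.extend(
                ds.sample_negatives(
                    stream,
                    anns,
                    n=n_neg,
                    guard_s=config.guard_s,
                    rng_seed=config.stage_seed("negatives"),
                    params=config.feature_params,
                )
            )
    stream_map = {s.source_id: s for s in streams}
    return ds.augment(
        positives + negatives,
        stream_map,
        max_shift_s=config.max_shift_s,
        copies_per_example=config.copies_per_example,
        rng_seed=config.stage_seed("augment"),
    )


def two_stage_train(
    streams: list[AudioStream],
    truths: list[list[Annotation]],
    config: RunConfig,
    out_dir: str | os.PathLike | None = None,
) -> StageArtifacts:
    """Run the two-stage protocol; optionally persist stage artifacts."""
    examples = _build_stage1_examples(streams, truths, config)
    arch = build_architecture(config.arch)
    cfg1 = replace(config.train_config, rng_seed=config.stage_seed("stage1"))
    scorer1 = train(arch, examples, cfg1, config.normalization_mode)

    hard = []
    pooled_times: list[float] = []
    for stream, anns in zip(streams, truths):
        mined = ds.mine_hard_negatives(
            scorer1,
            stream,
            anns,
            prob_threshold=config.mining_prob_threshold,
            dedup_tol_s=config.dedup_tol_s,
            match_tolerance_s=config.match_tolerance_s,
            existing_times=pooled_times,
            hop_s=config.detect_hop_s,
            nms_radius_s=config.nms_radius_s,
        )
        pooled_times.extend(m.origin_time_s for m in mined)
        hard.extend(mined)
    if config.max_hard_negatives is not None:
        hard = hard[: config.max_hard_negatives]

    stage2_examples = examples + hard
    cfg2 = replace(config.train_config, rng_seed=config.stage_seed("stage2"))
    if config.n_replicates > 1:
        replicates = train_replicates(
            arch, stage2_examples, cfg2, config.n_replicates, config.normalization_mode
        )
        scorer2 = replicates[0]
    else:
        scorer2 = train(arch, stage2_examples, cfg2, config.normalization_mode)
        replicates = [scorer2]

    counts = {
        "positives": sum(1 for e in examples if e.provenance == "annotated"),
        "random_negatives": sum(
            1 for e in examples if e.provenance == "random_negative"
        ),
        "augmented": sum(1 for e in examples if e.provenance == "augmented"),
        "hard_negatives": len(hard),
        "stage1_total": len(examples),
        "stage2_total": len(stage2_examples),
    }
    art = StageArtifacts(
        stage1_examples=examples,
        stage2_examples=stage2_examples,
        hard_negatives=hard,
        stage1_scorer=scorer1,
        stage2_scorer=scorer2,
        stage2_replicates=replicates,
        counts=counts,
    )
    if out_dir is not None:
        _persist(art, config, out_dir)
    return art


def _persist(art: StageArtifacts, config: RunConfig, out_dir):
    from .model import save_checkpoint

    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "run_config.json"), "w") as fh:
        json.dump(_config_dict(config), fh, indent=1)
    ds.manifest(art.stage1_examples).to_csv(
        os.path.join(out_dir, "stage1_manifest.tsv"), sep="\t", index=False
    )
    ds.manifest(art.stage2_examples).to_csv(
        os.path.join(out_dir, "stage2_manifest.tsv"), sep="\t", index=False
    )
    save_checkpoint(art.stage1_scorer, os.path.join(out_dir, "stage1_model"))
    save_checkpoint(art.stage2_scorer, os.path.join(out_dir, "stage2_model"))
    with open(os.path.join(out_dir, "counts.json"), "w") as fh:
        json.dump(art.counts, fh, indent=1)


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d


def _evaluate_scorer(scorer, test_streams, test_truths, config: RunConfig) -> dict:
    """Detect on held-out streams and compute the evaluation surfaces."""
    all_dets, all_anns = [], []
    hours = 0.0
    offset = 0.0  # streams laid out on one disjoint global timeline
    for stream, anns in zip(test_streams, test_truths):
        track = score_stream(scorer, stream, hop_s=config.detect_hop_s)
        dets = non_max_suppress(
            track, min_prob=config.detect_min_prob, radius_s=config.nms_radius_s
        )
        all_dets.extend(
            replace(
                d,
                peak_time_s=d.peak_time_s + offset,
                window_begin_s=d.window_begin_s + offset,
                window_end_s=d.window_end_s + offset,
                stream_id="",
            )
            for d in dets
        )
        all_anns.extend(
            replace(
                a, begin_time_s=a.begin_time_s + offset, end_time_s=a.end_time_s + offset
            )
            for a in anns
        )
        hours += stream.duration_s / 3600.0
        offset += stream.duration_s + 2 * config.match_tolerance_s + 1.0
    curve = ev.pr_curve(all_dets, all_anns, config.match_tolerance_s)
    fph_curve = ev.recall_vs_fph(all_dets, all_anns, hours, config.match_tolerance_s)
    # best recall at the FP/h budget
    feasible = [pt for pt in fph_curve if pt[1] <= config.fp_budget_per_hour]
    op_thr, op_fph, op_recall = max(feasible, key=lambda p: p[2])
    wl = ev.workload(
        op_fph, hours, len(all_anns), config.review_rate_per_hour,
        config.fp_budget_per_hour,
    )
    return {
        "average_precision": curve.average_precision,
        "recall_at_fp_budget": op_recall,
        "fph_at_operating_point": op_fph,
        "operating_threshold": op_thr,
        "recording_hours": hours,
        "n_detections": len(all_dets),
        "n_annotations": len(all_anns),
        "pr_curve": {
            "thresholds": curve.thresholds.tolist(),
            "precision": curve.precision.tolist(),
            "recall": curve.recall.tolist(),
        },
        "recall_vs_fph": [
            {"threshold": t, "fph": f, "recall": r} for t, f, r in fph_curve
        ],
        "workload": asdict(wl),
    }


def run_experiment(
    train_streams: list[AudioStream],
    train_truths: list[list[Annotation]],
    test_streams: list[AudioStream],
    test_truths: list[list[Annotation]],
    config: RunConfig,
    out_dir: str | os.PathLike | None = None,
) -> dict:
    """Two-stage train, detect on held-out streams, and report metrics.

    Refuses to run when a stream id appears in both splits.  With
    ``n_replicates > 1`` scalar metrics are means across replicates (their
    spread is reported alongside).
    """
    train_ids = {s.source_id for s in train_streams}
    test_ids = {s.source_id for s in test_streams}
    overlap = train_ids & test_ids
    if overlap:
        raise LeakageError(f"streams in both train and test: {sorted(overlap)}")

    art = two_stage_train(train_streams, train_truths, config, out_dir=out_dir)
    per_rep = [
        _evaluate_scorer(s, test_streams, test_truths, config)
        for s in art.stage2_replicates
    ]
    stage1_eval = _evaluate_scorer(
        art.stage1_scorer, test_streams, test_truths, config
    )
    aps = [r["average_precision"] for r in per_rep]
    recalls = [r["recall_at_fp_budget"] for r in per_rep]
    report = {
        "counts": art.counts,
        "stage1": {"average_precision": stage1_eval["average_precision"]},
        "stage2": per_rep[0],
        "replicates": {
            "n": len(per_rep),
            "average_precision_mean": float(np.mean(aps)),
            "average_precision_std": float(np.std(aps)),
            "recall_at_fp_budget_mean": float(np.mean(recalls)),
        },
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1)
    return report
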
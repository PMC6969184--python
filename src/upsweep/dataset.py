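"""Construction of labeled training examples.

Positives are 2 s clips starting 1 s before each annotated call's temporal
midpoint.  Initial negatives are sampled at random from call-free periods
(annotation intervals dilated by a guard of 1 s).  Shift augmentation
re-cuts each clip in the waveform with a uniform offset of up to +/-200 ms.
Hard negatives are the sliding-window detector's confident false positives
(probability >= 0.5) on training audio, pooled for a second training round.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    AnnotationOutsideStreamError,
    InsufficientCallFreeTimeError,
    UntrainedScorerError,
)
from .features import SpectrogramPatch, StftParams, patch_from_clip
from .signal_io import Annotation, AudioStream

__all__ = [
    "LabeledExample",
    "extract_positive",
    "sample_negatives",
    "augment",
    "mine_hard_negatives",
    "manifest",
]

CLIP_S = 2.0
LABELS = ("upcall", "background")
PROVENANCES = ("annotated", "random_negative", "augmented", "hard_negative")


@dataclass(frozen=True)
class LabeledExample:
    """A patch with its class label and provenance."""

    patch: SpectrogramPatch
    label: str
    provenance: str
    origin_time_s: float
    origin_stream: str = ""
    edge_padded: bool = False

    def __post_init__(self):
        if self.label not in LABELS or self.provenance not in PROVENANCES:
            raise ValueError("unknown label or provenance")
        if self.provenance == "annotated" and self.label != "upcall":
            raise ValueError("annotated examples are upcalls")
        if self.provenance in ("random_negative", "hard_negative") and (
            self.label != "background"
        ):
            raise ValueError("mined/random examples are background")


def _cut_example(
    stream: AudioStream,
    start_s: float,
    label: str,
    provenance: str,
    params: StftParams,
) -> LabeledExample:
    clip = stream.slice_seconds(start_s, start_s + CLIP_S)
    padded = start_s < stream.start_time_s or (
        start_s + CLIP_S > stream.start_time_s + stream.duration_s
    )
    return LabeledExample(
        patch=patch_from_clip(clip, params),
        label=label,
        provenance=provenance,
        origin_time_s=start_s,
        origin_stream=stream.source_id,
        edge_padded=padded,
    )


def extract_positive(
    stream: AudioStream, ann: Annotation, params: StftParams | None = None
) -> LabeledExample:
    """Cut the 2 s clip starting 1 s before the annotation's midpoint.

    Clips running past a stream edge are zero-padded and flagged; an
    annotation wholly outside the stream raises.
    """
    params = params or StftParams()
    t0, t1 = stream.start_time_s, stream.start_time_s + stream.duration_s
    if ann.end_time_s <= t0 or ann.begin_time_s >= t1:
        raise AnnotationOutsideStreamError(
            f"annotation [{ann.begin_time_s}, {ann.end_time_s}] s outside stream "
            f"[{t0}, {t1}] s"
        )
    start = ann.midpoint_s - CLIP_S / 2
    return _cut_example(stream, start, "upcall", "annotated", params)


def _free_start_intervals(
    stream: AudioStream, annotations: list[Annotation], guard_s: float
) -> list[tuple[float, float]]:
    """Start times s such that [s - guard, s + 2 + guard] hits no annotation."""
    t0 = stream.start_time_s
    t1 = t0 + stream.duration_s - CLIP_S
    if t1 <= t0:
        return []
    # forbidden start intervals from each annotation
    forbidden = sorted(
        (a.begin_time_s - guard_s - CLIP_S, a.end_time_s + guard_s)
        for a in annotations
    )
    free = []
    cursor = t0
    for b, e in forbidden:
        if b > cursor:
            free.append((cursor, min(b, t1)))
        cursor = max(cursor, e)
        if cursor >= t1:
            break
    if cursor < t1:
        free.append((cursor, t1))
    return [(b, e) for b, e in free if e > b]


def sample_negatives(
    stream: AudioStream,
    annotations: list[Annotation],
    n: int,
    guard_s: float = 1.0,
    rng_seed: int = 0,
    params: StftParams | None = None,
) -> list[LabeledExample]:
    """Sample ``n`` 2 s background windows from call-free time.

    Each window, dilated by ``guard_s``, overlaps no annotation.  Raises
    :class:`InsufficientCallFreeTimeError` when no call-free start exists.
    """
    params = params or StftParams()
    free = _free_start_intervals(stream, annotations, guard_s)
    total = sum(e - b for b, e in free)
    if total <= 0:
        raise InsufficientCallFreeTimeError(requested=n, achievable=0)
    rng = np.random.default_rng(rng_seed)
    lengths = np.array([e - b for b, e in free])
    cum = np.cumsum(lengths)
    out = []
    for _ in range(n):
        u = rng.uniform(0, total)
        k = min(int(np.searchsorted(cum, u, side="right")), len(free) - 1)
        start = free[k][0] + (u - (cum[k] - lengths[k]))
        out.append(
            _cut_example(stream, float(start), "background", "random_negative", params)
        )
    return out


def augment(
    examples: list[LabeledExample],
    streams: dict[str, AudioStream] | AudioStream,
    max_shift_s: float = 0.2,
    copies_per_example: int = 1,
    rng_seed: int = 0,
) -> list[LabeledExample]:
    """Pool the originals with time-shifted copies re-cut from the waveform.

    Shifts are uniform on [-max_shift_s, +max_shift_s]; labels are
    inherited, provenance becomes ``augmented``.
    """
    if isinstance(streams, AudioStream):
        streams = {streams.source_id: streams}
    rng = np.random.default_rng(rng_seed)
    out = list(examples)
    for ex in examples:
        stream = streams[ex.origin_stream]
        for _ in range(copies_per_example):
            shift = rng.uniform(-max_shift_s, max_shift_s)
            shifted = _cut_example(
                stream,
                ex.origin_time_s + shift,
                ex.label,
                "augmented",
                ex.patch.params,
            )
            out.append(shifted)
    return out


def mine_hard_negatives(
    scorer,
    stream: AudioStream,
    annotations: list[Annotation],
    prob_threshold: float = 0.5,
    dedup_tol_s: float = 0.1,
    match_tolerance_s: float = 0.5,
    existing_times: list[float] | None = None,
    hop_s: float = 0.1,
    nms_radius_s: float = 1.0,
) -> list[LabeledExample]:
    """Collect the detector's confident false positives on training audio.

    Runs sliding-window scoring + NMS over ``stream``, keeps detections with
    probability >= ``prob_threshold`` whose peak falls outside every
    annotation dilated by ``match_tolerance_s`` (the evaluation matching
    window), drops candidates within ``dedup_tol_s`` of an already-pooled
    negative's clip start, and returns them as background examples.
    """
    from .detector import non_max_suppress, score_stream

    if scorer is None or getattr(scorer, "net", None) is None:
        raise UntrainedScorerError("mine_hard_negatives requires a trained scorer")
    track = score_stream(scorer, stream, hop_s=hop_s)
    detections = non_max_suppress(
        track, min_prob=prob_threshold, radius_s=nms_radius_s,
        stream_id=stream.source_id,
    )
    pooled = list(existing_times or [])
    out = []
    for det in detections:
        hits_truth = any(
            a.begin_time_s - match_tolerance_s
            <= det.peak_time_s
            <= a.end_time_s + match_tolerance_s
            for a in annotations
        )
        if hits_truth:
            continue
        start = det.peak_time_s - CLIP_S / 2
        if any(abs(start - t) < dedup_tol_s for t in pooled):
            continue
        pooled.append(start)
        out.append(
            _cut_example(
                stream, start, "background", "hard_negative", scorer.feature_params
            )
        )
    return out


def save_examples(examples: list[LabeledExample], path) -> None:
    """Save patches + manifest as a single .npz archive."""
    import io

    m = manifest(examples)
    buf = io.StringIO()
    m.to_csv(buf, sep="\t", index=False)
    if examples:
        patches = np.stack([e.patch.values for e in examples]).astype(np.float32)
    else:
        patches = np.zeros((0, 40, 40), dtype=np.float32)
    np.savez_compressed(
        path,
        patches=patches,
        manifest=np.frombuffer(buf.getvalue().encode(), dtype=np.uint8),
    )


def load_examples(path, params: StftParams | None = None) -> list[LabeledExample]:
    import io

    import pandas as pd

    params = params or StftParams()
    with np.load(path) as data:
        patches = data["patches"].astype(np.float64)
        m = pd.read_csv(
            io.BytesIO(data["manifest"].tobytes()), sep="\t", keep_default_na=False
        )
    out = []
    for values, (_, row) in zip(patches, m.iterrows()):
        out.append(
            LabeledExample(
                patch=SpectrogramPatch(
                    values=values,
                    time_origin_s=float(row["origin_time_s"]),
                    freq_origin_hz=params.freq_origin_hz,
                    params=params,
                ),
                label=row["label"],
                provenance=row["provenance"],
                origin_time_s=float(row["origin_time_s"]),
                origin_stream=str(row["stream"]),
                edge_padded=bool(row["edge_padded"]),
            )
        )
    return out


def manifest(examples: list[LabeledExample]) -> "pd.DataFrame":
    """One row per example: stream id, origin time, label, provenance."""
    import pandas as pd

    return pd.DataFrame(
        {
            "stream": [e.origin_stream for e in examples],
            "origin_time_s": [e.origin_time_s for e in examples],
            "label": [e.label for e in examples],
            "provenance": [e.provenance for e in examples],
            "edge_padded": [e.edge_padded for e in examples],
        }
    )
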
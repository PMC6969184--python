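"""Training-example construction: positives, negatives, augmentation, mining."""

import numpy as np
import pytest

from upsweep import dataset as ds
from upsweep.errors import (
    AnnotationOutsideStreamError,
    InsufficientCallFreeTimeError,
    UntrainedScorerError,
)
from upsweep.features import StftParams, patch_from_clip
from upsweep.signal_io import Annotation, AudioStream


class TestExtractPositive:
    def test_window_centered_one_second_before_midpoint(self, small_scene):
        ann = Annotation(10.0, 11.0, 60, 200)
        ex = ds.extract_positive(small_scene.stream, ann)
        assert ex.origin_time_s == pytest.approx(9.5)  # midpoint 10.5 - 1.0
        assert ex.label == "upcall"
        assert ex.provenance == "annotated"
        assert not ex.edge_padded

    def test_edge_annotation_zero_padded_and_flagged(self):
        stream = AudioStream(np.random.default_rng(0).normal(size=8000), 2000.0)
        ann = Annotation(0.2, 0.6, 60, 200)  # midpoint 0.4 -> clip [-0.6, 1.4]
        ex = ds.extract_positive(stream, ann)
        assert ex.origin_time_s == pytest.approx(-0.6)
        assert ex.edge_padded

    def test_annotation_outside_stream_rejected(self, silence_2s):
        with pytest.raises(AnnotationOutsideStreamError):
            ds.extract_positive(silence_2s, Annotation(10.0, 11.0, 60, 200))

    def test_positive_has_more_inband_energy_than_background(self, small_scene):
        # calls concentrate energy in their annotated frequency rows
        ann = small_scene.annotations[0]
        pos = ds.extract_positive(small_scene.stream, ann)
        neg = ds.sample_negatives(
            small_scene.stream, small_scene.annotations, n=1, rng_seed=9
        )[0]
        params = pos.patch.params
        rows = slice(
            max(0, int((ann.low_freq_hz - params.freq_origin_hz) / params.bin_width_hz)),
            int((ann.high_freq_hz - params.freq_origin_hz) / params.bin_width_hz) + 1,
        )
        assert pos.patch.values[rows].sum() > neg.patch.values[rows].sum()


class TestSampleNegatives:
    def test_no_annotations_anywhere(self):
        stream = AudioStream(np.zeros(20000), 2000.0)
        out = ds.sample_negatives(stream, [], n=5, rng_seed=0)
        assert len(out) == 5
        assert {e.provenance for e in out} == {"random_negative"}

    def test_fully_covered_stream_errors(self):
        stream = AudioStream(np.zeros(20000), 2000.0)
        ann = Annotation(0.0, 10.0, 60, 200)
        with pytest.raises(InsufficientCallFreeTimeError) as err:
            ds.sample_negatives(stream, [ann], n=3)
        assert err.value.achievable == 0

    def test_no_sampled_window_overlaps_truth(self, small_scene):
        guard = 1.0
        out = ds.sample_negatives(
            small_scene.stream, small_scene.annotations, n=50, guard_s=guard, rng_seed=3
        )
        for ex in out:
            lo, hi = ex.origin_time_s - guard, ex.origin_time_s + 2.0 + guard
            for ann in small_scene.annotations:
                assert not (lo < ann.end_time_s and hi > ann.begin_time_s)

    def test_reproducible(self, small_scene):
        a = ds.sample_negatives(small_scene.stream, small_scene.annotations, 10, rng_seed=5)
        b = ds.sample_negatives(small_scene.stream, small_scene.annotations, 10, rng_seed=5)
        assert [x.origin_time_s for x in a] == [x.origin_time_s for x in b]


class TestAugment:
    def test_zero_copies_is_identity(self, small_scene):
        pos = [ds.extract_positive(small_scene.stream, a) for a in small_scene.annotations]
        out = ds.augment(pos, small_scene.stream, copies_per_example=0)
        assert out == pos

    def test_counting_and_provenance(self, small_scene):
        pos = [ds.extract_positive(small_scene.stream, a) for a in small_scene.annotations][:5]
        out = ds.augment(pos, small_scene.stream, copies_per_example=1, rng_seed=1)
        assert len(out) == 10
        assert sum(1 for e in out if e.provenance == "augmented") == 5
        assert all(e.label == "upcall" for e in out)

    def test_exact_one_hop_shift_moves_patch_columns(self, small_scene):
        # re-cutting at +50 ms must equal a one-column shift of the original
        ann = small_scene.annotations[1]
        ex = ds.extract_positive(small_scene.stream, ann)
        shifted_clip = small_scene.stream.slice_seconds(
            ex.origin_time_s + 0.05, ex.origin_time_s + 2.05
        )
        shifted = patch_from_clip(shifted_clip)
        np.testing.assert_allclose(
            shifted.values[:, :36], ex.patch.values[:, 1:37], atol=1e-9
        )

    def test_reproducible(self, small_scene):
        pos = [ds.extract_positive(small_scene.stream, a) for a in small_scene.annotations]
        a = ds.augment(pos, small_scene.stream, copies_per_example=2, rng_seed=8)
        b = ds.augment(pos, small_scene.stream, copies_per_example=2, rng_seed=8)
        assert [x.origin_time_s for x in a] == [x.origin_time_s for x in b]


class FakeOracleScorer:
    """Duck-typed scorer that knows the truth: p=1 on annotated calls, else 0."""

    def __init__(self, annotations):
        self.annotations = annotations
        self.feature_params = StftParams()
        self.normalization_mode = "unit_frobenius"
        self.net = object()

    def predict_proba(self, patches):
        out = []
        for p in patches:
            center = p.time_origin_s + 1.0
            hit = any(
                a.begin_time_s - 0.2 <= center <= a.end_time_s + 0.2
                for a in self.annotations
            )
            out.append(1.0 if hit else 0.0)
        return np.asarray(out)


class TestMineHardNegatives:
    def test_untrained_scorer_rejected(self, small_scene):
        with pytest.raises(UntrainedScorerError):
            ds.mine_hard_negatives(None, small_scene.stream, small_scene.annotations)

    def test_perfect_oracle_mines_nothing(self, small_scene):
        scorer = FakeOracleScorer(small_scene.annotations)
        out = ds.mine_hard_negatives(scorer, small_scene.stream, small_scene.annotations)
        assert out == []

    def test_oracle_on_silence_mines_nothing(self):
        stream = AudioStream(np.zeros(30 * 2000), 2000.0)
        out = ds.mine_hard_negatives(FakeOracleScorer([]), stream, [])
        assert out == []

    def test_weak_scorer_mines_only_off_truth_windows(self, confounder_scene, scene_scorer):
        mined = ds.mine_hard_negatives(
            scene_scorer, confounder_scene.stream, confounder_scene.annotations
        )
        tol = 0.5
        for ex in mined:
            assert ex.label == "background"
            assert ex.provenance == "hard_negative"
            peak = ex.origin_time_s + 1.0
            for ann in confounder_scene.annotations:
                assert not (
                    ann.begin_time_s - tol <= peak <= ann.end_time_s + tol
                )

    def test_dedup_against_existing_pool(self, confounder_scene, scene_scorer):
        first = ds.mine_hard_negatives(
            scene_scorer, confounder_scene.stream, confounder_scene.annotations
        )
        again = ds.mine_hard_negatives(
            scene_scorer,
            confounder_scene.stream,
            confounder_scene.annotations,
            existing_times=[e.origin_time_s for e in first],
        )
        assert again == []


class TestInvariantsAndRoundTrip:
    def test_label_provenance_invariants_enforced(self, toy_examples):
        with pytest.raises(ValueError):
            ds.LabeledExample(
                patch=toy_examples[0].patch,
                label="background",
                provenance="annotated",
                origin_time_s=0.0,
            )
        with pytest.raises(ValueError):
            ds.LabeledExample(
                patch=toy_examples[0].patch,
                label="upcall",
                provenance="hard_negative",
                origin_time_s=0.0,
            )

    def test_example_archive_round_trip(self, small_scene, tmp_path):
        pos = [ds.extract_positive(small_scene.stream, a) for a in small_scene.annotations]
        path = tmp_path / "ex.npz"
        ds.save_examples(pos, path)
        out = ds.load_examples(path)
        assert len(out) == len(pos)
        for a, b in zip(pos, out):
            assert a.label == b.label and a.provenance == b.provenance
            np.testing.assert_allclose(a.patch.values, b.patch.values, atol=1e-6)
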
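"""Shared fixtures: small synthetic scenes, toy datasets, a cheap scorer."""

import numpy as np
import pytest

from upsweep.dataset import LabeledExample
from upsweep.features import SpectrogramPatch
from upsweep.model import TrainConfig, build_architecture, train
from upsweep.signal_io import AudioStream
from upsweep.synth import SceneConfig, render_scene


@pytest.fixture(scope="session")
def small_scene():
    """2-minute confounder-free scene with a handful of calls."""
    return render_scene(
        SceneConfig(
            duration_s=120.0,
            call_rate_per_hour=180.0,
            confounder_rate_per_hour=0.0,
            snr_db=12.0,
            rng_seed=42,
        )
    )


@pytest.fixture(scope="session")
def confounder_scene():
    """2-minute scene rich in upsweep-like confounders."""
    return render_scene(
        SceneConfig(
            duration_s=120.0,
            call_rate_per_hour=120.0,
            confounder_rate_per_hour=300.0,
            snr_db=12.0,
            rng_seed=43,
        )
    )


def make_toy_examples(n=60, seed=0, offset=2.0, fraction_positive=0.5):
    """Linearly separable toy set: classes differ by an offset in one cell."""
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * fraction_positive))
    examples = []
    for i in range(n):
        values = rng.random((40, 40)) * 0.1
        positive = i < n_pos
        if positive:
            values[10, 10] += offset
        patch = SpectrogramPatch(values=values, normalization_mode="unit_frobenius")
        examples.append(
            LabeledExample(
                patch=patch,
                label="upcall" if positive else "background",
                provenance="annotated" if positive else "random_negative",
                origin_time_s=float(i),
            )
        )
    rng.shuffle(examples)
    return examples


@pytest.fixture(scope="session")
def toy_examples():
    return make_toy_examples()


@pytest.fixture(scope="session")
def scene_scorer(small_scene):
    """A quickly trained LeNet scorer on the small scene (shared, read-only)."""
    from upsweep import dataset as ds

    pos = [ds.extract_positive(small_scene.stream, a) for a in small_scene.annotations]
    neg = ds.sample_negatives(
        small_scene.stream, small_scene.annotations, n=2 * len(pos), rng_seed=1
    )
    return train(
        build_architecture("lenet_variant"),
        pos + neg,
        TrainConfig(batch_size=8, epochs=8, rng_seed=0),
    )


@pytest.fixture
def silence_2s():
    return AudioStream(np.zeros(4000), 2000.0)
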
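import numpy as np
import pytest

from tonguekin.synthkin import ClipSpec, VariabilityConfig, generate_segmentation_dataset, render_clip


@pytest.fixture(scope="session")
def rendered_clip():
    """One rendered 2 Hz / 14.5 mm clip with ground truth (session-cached)."""
    spec = ClipSpec(freq_true=2.0, amp_true=14.5, seed=7)
    frames, truth = render_clip(spec)
    return spec, frames, truth


@pytest.fixture(scope="session")
def tiny_seg_dataset():
    """Small segmentation dataset at 64 px for fast tests."""
    return generate_segmentation_dataset(12, VariabilityConfig(size=64), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
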
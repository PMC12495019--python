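import numpy as np
import pytest

from epifocal import focal, phantom


@pytest.fixture(scope="session")
def flat_truth():
    """Phantom truth with a flat focus surface at slice 10."""
    return phantom.make_phantom_truth(seed=0, manifold_coeffs={(0, 0): 10.0})


@pytest.fixture(scope="session")
def sharp_stack(flat_truth):
    """Noise-free, defocus-free stack: every slice is the sharp scene."""
    stack, _ = phantom.render_stack(
        flat_truth, noise=(0.0, 0.0), defocus_per_slice=0.0
    )
    return stack


@pytest.fixture(scope="session")
def sharp_scene(flat_truth):
    return phantom.render_scene(flat_truth)


@pytest.fixture(scope="session")
def curved_truth():
    """Phantom with a random degree-5 focus surface (the default)."""
    return phantom.make_phantom_truth(seed=0)


@pytest.fixture(scope="session")
def curved_stack(curved_truth):
    stack, _ = phantom.render_stack(curved_truth)  # default SNR-10 noise
    return stack


@pytest.fixture(scope="session")
def segmented_sharp(sharp_stack):
    """Full pipeline on the sharp stack: (infocus, labels, table)."""
    from epifocal import segment

    infocus = focal.correct_stack(sharp_stack)
    labels, table = segment.segment_infocus(infocus)
    return infocus, labels, table
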
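import numpy as np
import pytest
from hypothesis import settings

import retmorph as rm
from retmorph.synthetic import EyeSpec, generate_eye

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_eye():
    """One default synthetic eye (512x512, dd = 120 px) with ground truth."""
    mask, disc, truths = generate_eye(EyeSpec(seed=0))
    return mask, disc, truths


@pytest.fixture(scope="session")
def default_record(default_eye):
    mask, disc, _ = default_eye
    record, bifs = rm.measure_eye(mask, disc)
    return record, bifs


@pytest.fixture(scope="session")
def zoned_graphs(default_eye):
    """Per-class zoned vessel graphs of the default eye."""
    mask, disc, _ = default_eye
    graphs = {}
    for cls in (rm.ARTERY, rm.VEIN):
        skel = rm.skeletonize_class(mask, cls)
        widths = rm.estimate_widths(mask.class_mask(cls), skel)
        graphs[cls] = rm.assign_zones(rm.build_graph(skel, widths, cls), disc)
    return graphs


def make_bar_mask(height=64, width=200, bar_width=5, label=1):
    """Horizontal bar of given width centered vertically."""
    px = np.zeros((height, width), dtype=np.uint8)
    r0 = height // 2 - bar_width // 2
    px[r0:r0 + bar_width, :] = label
    return rm.SegmentationMask(px)
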
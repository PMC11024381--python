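"""Shared fixtures: small rendered flowers with known geometry.

Session scope keeps the renderer and the GMM segmenter from re-running in
every test; fixtures are deterministic so tests can freeze expectations.
"""

import numpy as np
import pytest

import tepals as tp

CANVAS = (420, 280)


@pytest.fixture(scope="session")
def six_tepal():
    """A clean 6-tepal whorled flower (EIEIEI), rendered with ground truth."""
    spec = tp.FlowerSpec(n_tepals=6, lr_pattern="LRLRLR", canvas=CANVAS, seed=3)
    image, truth = tp.render_flower(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def six_tepal_segmented(six_tepal):
    """The same flower after detection and color-model segmentation."""
    _, image, _ = six_tepal
    box = tp.detect_flower(image)
    return tp.segment_flower(image, box)


@pytest.fixture(scope="session")
def six_tepal_points(six_tepal_segmented):
    return tp.detect_overlap_points(six_tepal_segmented)


@pytest.fixture(scope="session")
def five_tepal():
    """A 5-tepal spiral flower (all L): quincuncial-like depth cycle."""
    spec = tp.FlowerSpec(n_tepals=5, lr_pattern="LLLLL", canvas=CANVAS, seed=9)
    image, truth = tp.render_flower(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def catalog():
    return tp.load_catalog()
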
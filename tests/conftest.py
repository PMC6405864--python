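import logging

import numpy as np
import pytest

from fibriltrace.curve_model import SpaceCurve, line_curve
from fibriltrace.synthetic_scenes import SyntheticScene, make_scene, render_scene

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def single_tube_volume():
    """One straight axial tube in a 64^3 box at 0.9 nm/voxel."""
    scene = make_scene("parallel", n_fibrils=1, spacing_nm=10.0,
                       box_nm=(57.6, 57.6, 57.6), seed=0)
    return scene, render_scene(scene, voxel_size_nm=0.9)


@pytest.fixture(scope="session")
def three_tube_volume():
    scene = make_scene("parallel", n_fibrils=3, spacing_nm=10.0,
                       box_nm=(45.0, 45.0, 18.0), seed=1)
    return scene, render_scene(scene, voxel_size_nm=0.9)


def random_gentle_curve(rng, box=(60.0, 60.0, 60.0)):
    """A mildly bent curve well inside the box (for distance oracles)."""
    center = np.array(box) / 2 + rng.uniform(-8, 8, size=3)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    c = line_curve(center, direction, (-18.0, 18.0))
    from dataclasses import replace
    return replace(c,
                   poly_x=(rng.uniform(-2, 2), rng.uniform(-0.1, 0.1),
                           rng.uniform(-0.004, 0.004)),
                   poly_y=(rng.uniform(-2, 2), rng.uniform(-0.1, 0.1),
                           rng.uniform(-0.004, 0.004)))
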
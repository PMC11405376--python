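import math

import numpy as np
import pytest

from oviscan import phantom, segment


@pytest.fixture(scope="session")
def simple_fold_phantom():
    """Four identical folds, 50 px long and 12 px wide, at 7.4 µm/px."""
    spec = phantom.FoldPhantomSpec(
        n_folds=4, fold_length_px=50.0, fold_width_px=12.0, px_size_um=7.4, seed=1
    )
    tissue, lumen, truth = phantom.make_fold_cross_section(spec)
    return spec, tissue, lumen, truth


@pytest.fixture(scope="session")
def split_fold_phantom(simple_fold_phantom):
    spec, tissue, lumen, truth = simple_fold_phantom
    external, internal = segment.split_structures(tissue)
    return spec, tissue, external, internal, truth


def fold_angle(fold, shape):
    """Angular position of a detected fold around the slice centre."""
    cy, cx = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    return math.atan2(fold.apex[0] - cy, fold.apex[1] - cx) % (2 * math.pi)


def pair_by_angle(folds, shape, truth):
    """Match detected folds to ground-truth folds by angular position."""
    angles = [fold_angle(f, shape) for f in folds]
    pairs = []
    for ta, tl, tw in zip(
        truth.fold_angles_rad, truth.true_fold_lengths_um, truth.true_fold_widths_um
    ):
        deltas = [min(abs(a - ta), 2 * math.pi - abs(a - ta)) for a in angles]
        pairs.append((int(np.argmin(deltas)), tl, tw))
    return pairs
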
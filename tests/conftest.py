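"""Shared fixtures: synthetic root systems, random masks, trained models.

Everything is generated programmatically with fixed seeds; session scope
keeps the expensive pieces (random-forest training, the 20 recovery
roots) to a single computation per run.
"""

from dataclasses import replace

import numpy as np
import pytest

from rootscape import (
    SyntheticRootSpec,
    make_library,
    render_views,
    simulate_root_system,
    skeletonize,
    train_segmenter,
)

#: Conditions for the descriptor-recovery study: stroke width 3 px
#: (radius 1.5), planar growth, overlap-free in projection.
RECOVERY_SPEC = SyntheticRootSpec(
    base_radius=1.5,
    n_primary=2,
    branch_rate=0.8,
    max_order=2,
    planar=True,
    no_overlap=True,
    noise_sigma=0.0,
    blur_sigma=0.0,
)
RECOVERY_SEEDS = tuple(range(100, 120))


def random_blob_mask(rng: np.random.Generator, shape=(80, 80)) -> np.ndarray:
    """A random nonempty mask made of a few rectangles and discs."""
    mask = np.zeros(shape, dtype=bool)
    for _ in range(rng.integers(2, 6)):
        if rng.random() < 0.5:
            r0, c0 = rng.integers(0, shape[0] - 10), rng.integers(0, shape[1] - 10)
            h, w = rng.integers(3, 25), rng.integers(3, 25)
            mask[r0 : min(r0 + h, shape[0]), c0 : min(c0 + w, shape[1])] = True
        else:
            rr, cc = np.ogrid[: shape[0], : shape[1]]
            cy, cx = rng.integers(5, shape[0] - 5), rng.integers(5, shape[1] - 5)
            rad = rng.integers(2, 12)
            mask |= (rr - cy) ** 2 + (cc - cx) ** 2 <= rad**2
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return mask


def random_point_mask(rng: np.random.Generator, shape=(60, 60), max_points=200) -> np.ndarray:
    """A sparse mask of <= max_points random pixels."""
    mask = np.zeros(shape, dtype=bool)
    n = rng.integers(1, max_points + 1)
    rows = rng.integers(0, shape[0], n)
    cols = rng.integers(0, shape[1], n)
    mask[rows, cols] = True
    return mask


@pytest.fixture(scope="session")
def recovery_cases():
    """20 seeded overlap-free roots with their rendered view and skeleton."""
    cases = []
    for seed in RECOVERY_SEEDS:
        spec = replace(RECOVERY_SPEC, seed=seed)
        axes, gt = simulate_root_system(spec)
        view = render_views(axes, spec, angles=(0.0,))[0]
        cases.append(
            {
                "spec": spec,
                "axes": axes,
                "gt": gt,
                "view": view,
                "graph": skeletonize(view.mask),
            }
        )
    return cases


@pytest.fixture(scope="session")
def trained_segmenter_eval():
    """RF segmenter trained on 20 synthetic images + 10 held-out F1 scores."""
    train_recs = make_library(20, seed=11)
    test_recs = make_library(10, seed=99)
    model = train_segmenter([(r["image"], r["mask"]) for r in train_recs], seed=0)
    f1s = []
    for rec in test_recs:
        pred = model.predict_mask(rec["image"]).values
        truth = rec["mask"].values
        tp = (pred & truth).sum()
        fp = (pred & ~truth).sum()
        fn = (~pred & truth).sum()
        f1s.append(2 * tp / (2 * tp + fp + fn))
    return model, np.array(f1s)
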
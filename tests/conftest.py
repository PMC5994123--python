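import numpy as np
import pytest

from densethresh.density_maps import DensityMap


@pytest.fixture
def tiny_map() -> DensityMap:
    """The worked 2x2 example: heights (2, 6, 10, 0) mm, thickness 10 mm."""
    return DensityMap(
        heights=np.array([[2.0, 6.0], [10.0, 0.0]]),
        breast_mask=np.ones((2, 2), dtype=bool),
        pixel_area=1.0,
        breast_thickness=10.0,
        subject_id="tiny",
    )


@pytest.fixture
def random_map_factory():
    """Random valid small maps with zero pixels, partial masks and clipping."""

    def make(seed: int, shape=(4, 4), thickness=12.0) -> DensityMap:
        rng = np.random.default_rng(seed)
        mask = rng.random(shape) < 0.8
        if not mask.any():
            mask[0, 0] = True
        heights = np.clip(rng.exponential(2.0, shape) - 0.5, 0.0, thickness)
        heights[~mask] = 0.0
        return DensityMap(
            heights=heights,
            breast_mask=mask,
            pixel_area=float(rng.uniform(0.5, 4.0)),
            breast_thickness=thickness,
            subject_id=f"rand{seed}",
        )

    return make


@pytest.fixture
def small_matched_data():
    """A deterministic 1:3 matched dataset generator (softmax labelling)."""

    def make(seed: int, n_sets: int = 50, k: int = 1, beta=None):
        rng = np.random.default_rng(seed)
        beta = np.zeros(k) if beta is None else np.atleast_1d(beta)
        x = rng.standard_normal((n_sets * 4, k))
        set_id = np.repeat(np.arange(n_sets), 4)
        eta = (x @ beta).reshape(n_sets, 4)
        p = np.exp(eta - eta.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        pos = (p.cumsum(axis=1) < rng.random((n_sets, 1))).sum(axis=1)
        is_case = np.zeros(n_sets * 4, dtype=bool)
        is_case[np.arange(n_sets) * 4 + pos] = True
        return x, set_id, is_case

    return make
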
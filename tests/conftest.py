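import numpy as np
import pytest

import morphosignal as ms


@pytest.fixture
def rng():
    return np.random.default_rng(20170524)


@pytest.fixture
def balanced_tree():
    """Rooted 4-tip tree with branch lengths."""
    return ms.Phylogeny.from_newick("((A:1,B:1):0.5,(C:0.7,D:1.3):0.8);")


@pytest.fixture
def tree14():
    """A fixed random 14-tip tree with Exponential(1) branch lengths."""
    return ms.random_tree(14, np.random.default_rng(42))


@pytest.fixture
def small_dataset(rng):
    """20 perturbed copies of the anchor template, rigidly scrambled."""
    base = ms.ANCHOR_TEMPLATE
    configs = []
    for i in range(20):
        coords = base + 0.02 * rng.normal(size=base.shape)
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        coords = coords @ rot.T * np.exp(rng.uniform(-0.3, 0.3)) + rng.uniform(-1, 1, 2)
        configs.append(ms.LandmarkConfiguration(
            specimen_id=f"s{i}", species_id=f"sp{i % 5}",
            anchor_side="ventral", coords=coords))
    return ms.LandmarkDataset(configs)


def rotate(coords, theta):
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    return coords @ rot.T


def grid_procrustes_distance(a, b, n_grid=20000, refine=4):
    """Brute-force partial Procrustes distance by rotation-angle scanning.

    Independent of the SVD route: centers and unit-scales both shapes, then
    scans the rotation angle on a progressively refined grid.
    """
    def prep(x):
        x = x - x.mean(axis=0)
        return x / np.sqrt(np.sum(x ** 2))

    a, b = prep(np.asarray(a, float)), prep(np.asarray(b, float))
    lo, hi = 0.0, 2 * np.pi
    best_theta = 0.0
    for _ in range(refine):
        thetas = np.linspace(lo, hi, n_grid)
        d2 = [np.sum((rotate(b, t) - a) ** 2) for t in thetas]
        i = int(np.argmin(d2))
        best_theta = thetas[i]
        span = (hi - lo) / n_grid
        lo, hi = best_theta - 2 * span, best_theta + 2 * span
    return float(np.sqrt(np.sum((rotate(b, best_theta) - a) ** 2)))
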
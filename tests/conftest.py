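import numpy as np
import pytest

from nvuquant import detect_pegs, make_peg_gallery


def brute_force_min_distances(a_pixels, b_pixels, dx_nm):
    """All-pairs oracle for nearest-boundary distances (exact, O(n·m))."""
    a = np.asarray(a_pixels, dtype=np.int64).reshape(-1, 2)
    b = np.asarray(b_pixels, dtype=np.int64).reshape(-1, 2)
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(d2.min(axis=1).astype(float)) * dx_nm


def random_blob_mask(rng, shape, n_seeds=3, n_growth=40):
    """A random, possibly multi-component binary mask for property tests."""
    mask = np.zeros(shape, dtype=bool)
    ys = rng.integers(0, shape[0], size=n_seeds)
    xs = rng.integers(0, shape[1], size=n_seeds)
    mask[ys, xs] = True
    for _ in range(n_growth):
        y = rng.integers(0, shape[0])
        x = rng.integers(0, shape[1])
        h = rng.integers(1, 5)
        w = rng.integers(1, 5)
        mask[y : y + h, x : x + w] = True
    return mask


def disk_mask(radius_px, pad=2):
    n = 2 * (radius_px + pad) + 1
    c = (n - 1) / 2
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2


def cross_mask():
    """Plus-shaped cross: 3×9 and 9×3 arms on a padded canvas."""
    m = np.zeros((13, 13), dtype=bool)
    m[5:8, 2:11] = True
    m[2:11, 5:8] = True
    return m


@pytest.fixture(scope="session")
def peg_gallery():
    """The canonical peg phantom: six valid pegs, five single-criterion decoys."""
    return make_peg_gallery(seed=0)


@pytest.fixture(scope="session")
def peg_detection(peg_gallery):
    vol, _ = peg_gallery
    return detect_pegs(vol)


def match_candidates_to_truth(result, truth):
    """Pair each ground-truth peg with the detector candidate covering it."""
    pairs = []
    for peg in truth.pegs:
        target = set(map(tuple, peg.voxels))
        match = None
        for cand in result.candidates:
            if cand.direction != peg.spec.direction:
                continue
            if len(set(map(tuple, cand.voxels)) & target) > 0.5 * len(target):
                match = cand
                break
        pairs.append((peg, match))
    return pairs
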
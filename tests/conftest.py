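"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use explicit Python loops over every pixel and
tip offset, staying independent of the vectorized implementation they check.
"""

import numpy as np
import pytest

import blindtip as bt


# ---------------------------------------------------------------- oracles --

def brute_dilate(s: np.ndarray, p: np.ndarray, origin) -> np.ndarray:
    """i(x,y) = max over valid (u,v) of s(x-u, y-v) + p(u,v), double loop."""
    H, W = s.shape
    h, w = p.shape
    out = np.full((H, W), -np.inf)
    for r in range(H):
        for c in range(W):
            for ur in range(h):
                for uc in range(w):
                    rr, cc = r - (ur - origin[0]), c - (uc - origin[1])
                    if 0 <= rr < H and 0 <= cc < W:
                        out[r, c] = max(out[r, c], s[rr, cc] + p[ur, uc])
    return out


def brute_erode(i: np.ndarray, p: np.ndarray, origin) -> np.ndarray:
    """s_r(x,y) = min over valid (u,v) of i(x+u, y+v) - p(u,v), double loop."""
    H, W = i.shape
    h, w = p.shape
    out = np.full((H, W), np.inf)
    for r in range(H):
        for c in range(W):
            for ur in range(h):
                for uc in range(w):
                    rr, cc = r + (ur - origin[0]), c + (uc - origin[1])
                    if 0 <= rr < H and 0 <= cc < W:
                        out[r, c] = min(out[r, c], i[rr, cc] - p[ur, uc])
    return out


def brute_sphere_heights(atoms, grid_shape, pixel_size):
    """Per-pixel max over atoms of the sphere-cap height, explicit loop."""
    H, W = grid_shape
    out = np.zeros((H, W))
    for r in range(H):
        for c in range(W):
            x = (c - (W - 1) / 2) * pixel_size
            y = (r - (H - 1) / 2) * pixel_size
            for (ax, ay, az), rad in zip(atoms.coordinates, atoms.radii):
                d2 = (x - ax) ** 2 + (y - ay) ** 2
                if d2 <= rad**2:
                    out[r, c] = max(out[r, c], az + np.sqrt(rad**2 - d2))
    return out


# --------------------------------------------------------------- fixtures --

@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def truth_tip():
    """Ground-truth hemisphere + cone tip: r=2.5 nm, theta=10 deg, 10x10 grid."""
    return bt.make_tip(bt.TipSpec())


@pytest.fixture(scope="session")
def blob_atoms():
    """A reduced synthetic globule (kept small for fast unit tests)."""
    return bt.make_blob_atoms(n_atoms=1500, extent=(2.6, 2.0, 1.7), rng=5)


@pytest.fixture(scope="session")
def tiny_dataset(blob_atoms):
    """Noise-free 4-frame movie on a 16x16 grid with a 5x5 ground-truth tip."""
    tip = bt.make_tip(bt.TipSpec(grid_shape=(5, 5)))
    return bt.generate_dataset(
        blob_atoms, tip, n_frames=4, grid_shape=(16, 16), pixel_size=1.5, sigma=0.0, seed=42
    )


@pytest.fixture(scope="session")
def carve_dataset(blob_atoms):
    """Noise-free 12-frame movie rich enough to pin the whole 5x5 tip."""
    tip = bt.make_tip(bt.TipSpec(grid_shape=(5, 5)))
    return bt.generate_dataset(
        blob_atoms, tip, n_frames=12, grid_shape=(20, 20), pixel_size=1.5, sigma=0.0, seed=42
    )


@pytest.fixture(scope="session")
def tiny_noisy_dataset(blob_atoms):
    tip = bt.make_tip(bt.TipSpec(grid_shape=(5, 5)))
    return bt.generate_dataset(
        blob_atoms, tip, n_frames=4, grid_shape=(16, 16), pixel_size=1.5, sigma=0.3, seed=43
    )


def random_instance(rng, im_shape=(6, 6), tip_shape=(3, 3), scale=2.0):
    """A random image + normalized random tip pair for property tests.

    The apex (p = 0) sits at the uv origin, the package's tip convention.
    """
    img = bt.HeightImage(rng.normal(size=im_shape) * scale)
    p = -np.abs(rng.normal(size=tip_shape)) * scale
    tip = bt.InvertedTip(p, origin_index=None)
    tip.p[tip.origin_index] = 0.0
    return img, tip
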
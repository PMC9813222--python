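"""Grayscale mathematical morphology on AFM height grids.

An AFM image is modelled as the grayscale *dilation* of the sample surface
``s(x, y)`` with the inverted tip ``p(u, v) = -t(-u, -v) <= 0``::

    i(x, y) = max_{u,v} [ s(x - u, y - v) + p(u, v) ]

The approximate deconvolution is the *erosion*::

    s_r(x, y) = min_{u,v} [ i(x + u, y + v) - p(u, v) ]

and the *opening* (erosion followed by dilation) satisfies the identity
``I o P = I`` exactly when ``P`` is the tip that produced ``I``.  Both blind
tip reconstruction algorithms in this package are built on these three
operators; the gradient-based one additionally needs the argmax/argmin
indices of the max/min reductions, which :func:`opening` can record.

Boundary rule: the max/min run only over tip offsets whose image index is in
range ("valid overlap"); no heights are invented outside the scanned area.
Ties in argmax/argmin are broken toward the smallest row-major tip index so
that gradient routing is deterministic.

All heights are in nm.  Arrays are indexed ``[row, col]`` = ``[y, x]`` with
the origin at the top-left pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "GeometryError",
    "HeightImage",
    "InvertedTip",
    "ArgTrace",
    "dilate",
    "erode",
    "opening",
]


class GeometryError(ValueError):
    """Incompatible pixel geometry between an image and a tip."""


def _as_float_grid(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 2D grid, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite heights")
    return arr


@dataclass
class HeightImage:
    """A 2D grid of heights (nm) on square pixels.

    Parameters
    ----------
    heights : array_like, shape (H, W)
        Surface or image heights in nm; must be finite.
    pixel_size : float
        Edge length of a pixel in nm.
    frame_id : int, optional
        Position of the frame within a movie/stack.
    """

    heights: np.ndarray
    pixel_size: float = 1.0
    frame_id: int | None = None

    def __post_init__(self):
        self.heights = _as_float_grid(self.heights, "heights")
        self.pixel_size = float(self.pixel_size)
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def copy(self) -> "HeightImage":
        return HeightImage(self.heights.copy(), self.pixel_size, self.frame_id)


def center_origin(shape: tuple[int, int]) -> tuple[int, int]:
    """Default uv origin of a tip grid: (floor(H/2), floor(W/2))."""
    return (shape[0] // 2, shape[1] // 2)


@dataclass
class InvertedTip:
    """The inverted tip surface ``p(u, v) = -t(-u, -v) <= 0`` on the uv grid.

    The apex sits at ``origin_index`` (defaults to the grid center) where a
    normalized tip has ``p = 0``; all other entries are non-positive.
    """

    p: np.ndarray
    pixel_size: float = 1.0
    origin_index: tuple[int, int] | None = None

    def __post_init__(self):
        self.p = _as_float_grid(self.p, "p")
        self.pixel_size = float(self.pixel_size)
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if np.any(self.p > 0):
            raise ValueError("inverted tip heights must satisfy p <= 0 everywhere")
        if self.origin_index is None:
            self.origin_index = center_origin(self.p.shape)
        orr, orc = (int(self.origin_index[0]), int(self.origin_index[1]))
        h, w = self.p.shape
        if not (0 <= orr < h and 0 <= orc < w):
            raise ValueError(f"origin_index {self.origin_index} outside tip grid {self.p.shape}")
        self.origin_index = (orr, orc)

    @property
    def shape(self) -> tuple[int, int]:
        return self.p.shape

    def tip_height(self) -> np.ndarray:
        """The (non-inverted) tip surface ``t(u, v) = -p(-u, -v) >= 0``.

        The returned grid is indexed so that its ``origin_index`` row/col is
        the apex, mirroring the uv axes of ``p`` through the origin.
        """
        h, w = self.p.shape
        orr, orc = self.origin_index
        t = np.full_like(self.p, np.nan)
        for r in range(h):
            for c in range(w):
                rr, cc = 2 * orr - r, 2 * orc - c
                t[r, c] = -self.p[rr, cc] if (0 <= rr < h and 0 <= cc < w) else np.nan
        return t

    def copy(self) -> "InvertedTip":
        return InvertedTip(self.p.copy(), self.pixel_size, self.origin_index)


@dataclass
class ArgTrace:
    """Flat tip indices selected by the max/min reductions of an opening.

    ``erosion_arg[y]`` is the tip pixel attaining the min for eroded pixel y;
    ``dilation_arg[x]`` the tip pixel attaining the max for output pixel x;
    ``consumed[x]`` the flat image index of the eroded pixel that the dilation
    read at x.  These are exactly the routes along which MSE gradients flow.
    """

    erosion_arg: np.ndarray
    dilation_arg: np.ndarray
    consumed: np.ndarray


class _GridGeometry:
    """Precomputed gather indices for a (image shape, tip shape, origin) triple.

    ``plus[k, x]`` is the flat index of image pixel ``x + off_k`` (used by
    erosion), ``minus[k, x]`` of ``x - off_k`` (dilation); out-of-range
    entries point at the sentinel slot ``H*W`` so a padded flat array can be
    gathered without branching.
    """

    def __init__(self, im_shape, tip_shape, origin):
        H, W = im_shape
        h, w = tip_shape
        orr, orc = origin
        off_r = np.repeat(np.arange(h) - orr, w)
        off_c = np.tile(np.arange(w) - orc, h)
        self.offsets = np.stack([off_r, off_c], axis=1)  # (K, 2)
        gr = np.arange(H)[:, None] + np.zeros(W, dtype=int)[None, :]
        gc = np.arange(W)[None, :] + np.zeros(H, dtype=int)[:, None]
        gr, gc = gr.ravel(), gc.ravel()

        def build(sign):
            R = gr[None, :] + sign * off_r[:, None]
            C = gc[None, :] + sign * off_c[:, None]
            valid = (R >= 0) & (R < H) & (C >= 0) & (C < W)
            return np.where(valid, R * W + C, H * W)

        self.plus = build(+1)
        self.minus = build(-1)
        self.n_pixels = H * W
        self.im_shape = (H, W)
        self.tip_shape = (h, w)
        self.origin = (orr, orc)


@lru_cache(maxsize=64)
def _geometry(im_shape, tip_shape, origin) -> _GridGeometry:
    return _GridGeometry(im_shape, tip_shape, origin)


def _check_pair(image: HeightImage, tip: InvertedTip) -> _GridGeometry:
    if not np.isclose(image.pixel_size, tip.pixel_size, rtol=1e-9, atol=0.0):
        raise GeometryError(
            f"pixel_size mismatch: image {image.pixel_size} nm vs tip {tip.pixel_size} nm"
        )
    H, W = image.shape
    h, w = tip.shape
    if h > H or w > W:
        raise GeometryError(f"tip grid {tip.shape} larger than image grid {image.shape}")
    return _geometry((H, W), (h, w), tip.origin_index)


# -- array kernels (shared with the training loop, which avoids re-validating) --

def _erode_arr(i_flat: np.ndarray, p_flat: np.ndarray, geom: _GridGeometry, want_arg=False):
    ext = np.append(i_flat, np.inf)
    vals = ext[geom.plus] - p_flat[:, None]
    out = vals.min(axis=0)
    if want_arg:
        return out, vals.argmin(axis=0)
    return out, None


def _dilate_arr(s_flat: np.ndarray, p_flat: np.ndarray, geom: _GridGeometry, want_arg=False):
    ext = np.append(s_flat, -np.inf)
    vals = ext[geom.minus] + p_flat[:, None]
    out = vals.max(axis=0)
    if want_arg:
        return out, vals.argmax(axis=0)
    return out, None


def dilate(surface: HeightImage, tip: InvertedTip) -> HeightImage:
    """Image profile obtained by scanning ``surface`` with ``tip``.

    ``i(x,y) = max_{u,v}[s(x-u, y-v) + p(u,v)]`` over valid-overlap offsets.
    For a normalized tip (apex 0) the output is >= the input everywhere.
    """
    geom = _check_pair(surface, tip)
    out, _ = _dilate_arr(surface.heights.ravel(), tip.p.ravel(), geom)
    return HeightImage(out.reshape(surface.shape), surface.pixel_size, surface.frame_id)


def erode(image: HeightImage, tip: InvertedTip) -> HeightImage:
    """Approximate deconvolution ``s_r(x,y) = min_{u,v}[i(x+u, y+v) - p(u,v)]``.

    The result is the least upper bound on sample surfaces reproducing
    ``image`` under dilation with ``tip``.
    """
    geom = _check_pair(image, tip)
    out, _ = _erode_arr(image.heights.ravel(), tip.p.ravel(), geom)
    return HeightImage(out.reshape(image.shape), image.pixel_size, image.frame_id)


def opening(
    image: HeightImage, tip: InvertedTip, want_trace: bool = False
) -> tuple[HeightImage, ArgTrace | None]:
    """Opening ``I o P`` = dilation of the erosion; optionally with arg traces."""
    geom = _check_pair(image, tip)
    i_flat = image.heights.ravel()
    p_flat = tip.p.ravel()
    ero, earg = _erode_arr(i_flat, p_flat, geom, want_arg=want_trace)
    out, darg = _dilate_arr(ero, p_flat, geom, want_arg=want_trace)
    opened = HeightImage(out.reshape(image.shape), image.pixel_size, image.frame_id)
    if not want_trace:
        return opened, None
    consumed = geom.minus[darg, np.arange(geom.n_pixels)]
    trace = ArgTrace(
        erosion_arg=earg.reshape(image.shape),
        dilation_arg=darg.reshape(image.shape),
        consumed=consumed.reshape(image.shape),
    )
    return opened, trace
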
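"""Villarrubia's blind tip reconstruction by iterative carving.

The estimator starts from a square pillar (``p = 0`` everywhere, the bluntest
inverted tip) and lowers ("carves") tip pixels wherever the current estimate
is inconsistent with dents observed in the image profiles.  For every scan
position c the translated tip must fit under the image while touching it at
some contact offset d; writing

    dill(u, v; c, d) = i(c + u - d) - i(c) + p(d)

the admissible contacts at c are the tip pixels d whose implied apex position
stays under the image, tested at the apex pixel:

    i(c - d) - i(c) + p(d) >= -thresh .

Because the true contact is unknown, the bound contributed by c is the
*maximum* of dill over admissible d; intersecting the bounds over all scan
positions and relaxing by the tolerance ``thresh`` gives the update

    p(u, v) <- min(p(u, v),  min_c max_{d admissible} dill + thresh) .

The apex pixel is pinned at the uv origin and never modified.  Heights only
ever decrease, and for noise-free data the estimate remains an upper bound on
the true tip (p_est >= p_true).  ``thresh`` (nm) sets the tolerance for
treating a dent as tip geometry rather than noise; small values overfit the
tip to noise, which is the weakness the gradient-based estimator addresses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import (
    GeometryError,
    HeightImage,
    InvertedTip,
    _check_pair,
    center_origin,
)
from .results import BTRResults

__all__ = ["CarveParams", "refine_tip_with_image", "reconstruct_tip", "OriginalBTR", "OriginalBTRResults"]


@dataclass
class CarveParams:
    """Carving controls: inconsistency tolerance ``thresh`` (nm) and sweep cap."""

    thresh: float = 0.0
    max_sweeps: int = 50

    def __post_init__(self):
        if self.thresh < 0:
            raise ValueError("thresh must be >= 0")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")


def _shifted_stack(i: np.ndarray, max_dr: int, max_dc: int) -> np.ndarray:
    """All integer shifts of ``i`` within +-max_dr/+-max_dc, -inf outside.

    ``stack[dr + max_dr, dc + max_dc, r, c] = i[r + dr, c + dc]``.
    """
    H, W = i.shape
    pad = np.full((H + 2 * max_dr, W + 2 * max_dc), -np.inf)
    pad[max_dr : max_dr + H, max_dc : max_dc + W] = i
    stack = np.empty((2 * max_dr + 1, 2 * max_dc + 1, H, W))
    for a in range(2 * max_dr + 1):
        for b in range(2 * max_dc + 1):
            stack[a, b] = pad[a : a + H, b : b + W]
    return stack


def refine_tip_with_image(
    tip: InvertedTip, image: HeightImage, params: CarveParams
) -> tuple[InvertedTip, int]:
    """One carving pass of ``tip`` against a single image.

    Evaluates every scan position against every tip pixel using the current
    estimate (Jacobi update) and returns the refined tip together with the
    number of lowered pixels.  The result is pixelwise <= the input.
    """
    geom = _check_pair(image, tip)
    i = image.heights
    p = tip.p.copy()
    h, w = p.shape
    orr, orc = tip.origin_index
    off_r = np.arange(h) - orr
    off_c = np.arange(w) - orc
    max_dr = int(np.abs(off_r).max()) * 2
    max_dc = int(np.abs(off_c).max()) * 2
    shifts = _shifted_stack(i, max_dr, max_dc)  # i(c + s) for s in range

    K = h * w
    u_r = np.repeat(off_r, w)
    u_c = np.tile(off_c, h)
    p_flat = p.ravel()
    # bound[k, c] accumulates max over admissible d of dill(u_k; c, d)
    bound = np.full((K, i.size), -np.inf)
    for kd in range(K):
        dr, dc = u_r[kd], u_c[kd]
        apex = shifts[max_dr - dr, max_dc - dc].ravel()  # i(c - d)
        elig = apex - i.ravel() + p_flat[kd] >= -params.thresh  # -inf apex -> False
        if not elig.any():
            continue
        # dill(u; c, d) = i(c + u - d) - i(c) + p(d); invalid image index -> -inf
        dill = (
            shifts[u_r - dr + max_dr, u_c - dc + max_dc].reshape(K, -1)
            - i.ravel()[None, :]
            + p_flat[kd]
        )
        np.maximum(bound, np.where(elig[None, :], dill, -np.inf), out=bound)
    # scan positions that constrain nothing impose no bound
    bound[~np.isfinite(bound)] = np.inf
    carve_to = bound.min(axis=1) + params.thresh
    apex_k = orr * w + orc
    update = carve_to < p_flat
    update[apex_k] = False  # apex pinned at the origin
    n_updates = int(update.sum())
    p_flat[update] = carve_to[update]
    return InvertedTip(np.minimum(p, 0.0).reshape(h, w), tip.pixel_size, tip.origin_index), n_updates


def reconstruct_tip(
    dataset, params: CarveParams, tip_grid_shape: tuple[int, int] = (10, 10)
) -> InvertedTip:
    """Carve a square pillar against the frames of ``dataset`` until converged.

    Frames are visited sequentially; full sweeps over all frames repeat until
    a sweep makes zero updates or ``params.max_sweeps`` is reached.
    """
    res = OriginalBTR(dataset, tip_grid_shape).fit(
        thresh=params.thresh, max_sweeps=params.max_sweeps
    )
    return res.tip


class OriginalBTR:
    """Villarrubia blind tip reconstruction model over an AFM dataset.

    Parameters
    ----------
    dataset : AFMDataset
        Frames sharing one pixel geometry.
    tip_shape : (int, int)
        uv grid of the tip estimate (rows, cols); apex pinned at the center.
    """

    def __init__(self, dataset, tip_shape: tuple[int, int] = (10, 10)):
        if len(dataset.frames) == 0:
            raise ValueError("dataset must contain at least one frame")
        H, W = dataset.grid_shape
        if tip_shape[0] > H or tip_shape[1] > W:
            raise GeometryError(f"tip grid {tip_shape} larger than image grid {(H, W)}")
        self.dataset = dataset
        self.tip_shape = tuple(tip_shape)
        self.origin_index = center_origin(self.tip_shape)

    def fit(self, thresh: float = 0.0, max_sweeps: int = 50) -> "OriginalBTRResults":
        params = CarveParams(thresh=thresh, max_sweeps=max_sweeps)
        tip = InvertedTip(
            np.zeros(self.tip_shape), self.dataset.pixel_size, self.origin_index
        )
        updates_per_sweep: list[int] = []
        for _ in range(params.max_sweeps):
            n_sweep = 0
            for frame in self.dataset.frames:
                # frame-level passes repeat until this frame stops carving,
                # then the next frame is taken up (sequential application)
                while True:
                    tip, n = refine_tip_with_image(tip, frame, params)
                    n_sweep += n
                    if n == 0:
                        break
            updates_per_sweep.append(n_sweep)
            if n_sweep == 0:
                break
        return OriginalBTRResults(self, params, tip, updates_per_sweep)


class OriginalBTRResults(BTRResults):
    """Fitted carving estimate with its convergence diagnostics."""

    def __init__(self, model, params, tip, updates_per_sweep):
        super().__init__(model, tip)
        self.params = params
        self.updates_per_sweep = updates_per_sweep
        self.n_sweeps = len(updates_per_sweep)
        self.converged = bool(updates_per_sweep and updates_per_sweep[-1] == 0)

    def _summary_rows(self):
        return [
            ("thresh (nm)", f"{self.params.thresh:g}"),
            ("sweeps", f"{self.n_sweeps}"),
            ("converged", str(self.converged)),
            ("carve updates", f"{sum(self.updates_per_sweep)}"),
        ]

    _method_name = "original blind tip reconstruction (carving)"
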
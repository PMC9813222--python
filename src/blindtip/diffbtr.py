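"""Gradient-based blind tip reconstruction with an L2-regularized opening loss.

The tip is estimated by minimizing

    L(p) = MSE(p) + lambda * ||p||^2 ,
    MSE(p) = (1/N) sum_{x,y} ( i_r(x,y) - i(x,y) )^2 ,

where ``i_r = I o P`` is the opening of the observed image with the candidate
tip.  The opening identity ``I o P = I`` holds exactly for the generating tip,
so on noise-free data the MSE minimum is zero at the true tip; the L2 penalty
biases the estimate toward blunt shapes, preventing the collapse onto thin
(delta-like) tips that also zero the MSE and that plain carving falls into on
noisy data.

Gradients flow through the max/min reductions of dilation and erosion via
their argmax/argmin indices (max-pooling style subgradients): each output
pixel routes +1 to the tip pixel selected by the dilation and -1 to the tip
pixel selected by the erosion it consumed.  Optimization is AdamW with
decoupled weight decay (the decay term implements the L2 penalty, so the
explicit gradient contains only the MSE part), followed after every frame
update by clamping to p <= 0 and integer recentering of the weighted
center-of-mass onto the uv origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphology import (
    HeightImage,
    InvertedTip,
    _check_pair,
    _dilate_arr,
    _erode_arr,
    center_origin,
)
from .results import BTRResults

__all__ = [
    "LossParams",
    "OptimizerState",
    "TrainHistory",
    "opening_mse",
    "mse_gradient",
    "adamw_step",
    "clamp_and_recenter",
    "train_tip",
    "DifferentiableBTR",
    "DifferentiableBTRResults",
]


@dataclass
class LossParams:
    """Loss and optimizer hyperparameters.

    lam is the L2 regularization weight; lr (nm), beta1, beta2 are the AdamW
    learning rate and moment decays.  The weight-decay factor applied per
    step is ``2 * lam * lr`` (the gradient-descent-consistent mapping of the
    penalty ``lam * ||p||^2``).
    """

    lam: float = 1e-7
    lr: float = 0.1
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    epochs: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        for b in (self.beta1, self.beta2):
            if not 0.0 < b < 1.0:
                raise ValueError("beta1/beta2 must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class OptimizerState:
    """AdamW first/second moment accumulators for the tip pixels."""

    m: np.ndarray
    v: np.ndarray
    step: int = 0

    @classmethod
    def zeros(cls, shape) -> "OptimizerState":
        return cls(np.zeros(shape), np.zeros(shape), 0)


@dataclass
class TrainHistory:
    """Per-epoch diagnostics recorded during training."""

    mse: list[float] = field(default_factory=list)
    reg: list[float] = field(default_factory=list)
    max_p: list[float] = field(default_factory=list)
    centroid_distance: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.mse) + 1),
                "mse": self.mse,
                "regularization": self.reg,
                "max_p": self.max_p,
                "centroid_distance": self.centroid_distance,
            }
        )


def opening_mse(frames, tip: InvertedTip) -> float:
    """Mean over frames of the per-pixel squared opening residual (nm^2)."""
    frames = list(frames)
    if not frames:
        raise ValueError("frames must be non-empty")
    total = 0.0
    for fr in frames:
        geom = _check_pair(fr, tip)
        i_flat = fr.heights.ravel()
        p_flat = tip.p.ravel()
        ero, _ = _erode_arr(i_flat, p_flat, geom)
        out, _ = _dilate_arr(ero, p_flat, geom)
        total += float(np.mean((out - i_flat) ** 2))
    return total / len(frames)


def _grad_and_mse(i_flat, p_flat, geom, ie=None):
    """Routed MSE gradient and residual for one frame on flat arrays.

    ``ie`` may carry the precomputed erosion gather ``i_ext[geom.plus]``,
    which is constant across training steps for a fixed frame.
    """
    if ie is None:
        ie = np.append(i_flat, np.inf)[geom.plus]
    E = ie - p_flat[:, None]
    ero = E.min(axis=0)
    earg = E.argmin(axis=0)
    e_ext = np.append(ero, -np.inf)
    D = e_ext[geom.minus] + p_flat[:, None]
    out = D.max(axis=0)
    darg = D.argmax(axis=0)
    resid = out - i_flat
    r2 = (2.0 / geom.n_pixels) * resid
    K = p_flat.size
    consumed = geom.minus[darg, np.arange(geom.n_pixels)]  # always a valid pixel
    grad = np.bincount(darg, weights=r2, minlength=K) - np.bincount(
        earg[consumed], weights=r2, minlength=K
    )
    mse = float(np.mean(resid**2))
    return grad, mse


def mse_gradient(frame: HeightImage, tip: InvertedTip) -> np.ndarray:
    """Gradient of the opening MSE of one frame w.r.t. every tip pixel.

    Routed through the dilation argmax and erosion argmin indices (ties go to
    the smallest row-major tip index); the regularization gradient is *not*
    included -- it is applied by the optimizer's decoupled weight decay.
    """
    geom = _check_pair(frame, tip)
    grad, _ = _grad_and_mse(frame.heights.ravel(), tip.p.ravel(), geom)
    return grad.reshape(tip.shape)


def adamw_step(
    tip: InvertedTip, grad: np.ndarray, state: OptimizerState, params: LossParams
) -> tuple[InvertedTip, OptimizerState]:
    """One AdamW update of the tip pixels (decoupled weight decay = 2*lam*lr)."""
    p = tip.p.copy()
    g = np.asarray(grad, dtype=np.float64).reshape(p.shape)
    _adamw_inplace(p, g, state, params)
    # the raw update may lift pixels above 0; the caller clamps
    return (
        InvertedTip(np.minimum(p, 0.0), tip.pixel_size, tip.origin_index),
        state,
    )


def _adamw_inplace(p: np.ndarray, g: np.ndarray, state: OptimizerState, params: LossParams):
    state.step += 1
    t = state.step
    state.m = params.beta1 * state.m + (1.0 - params.beta1) * g
    state.v = params.beta2 * state.v + (1.0 - params.beta2) * g * g
    mhat = state.m / (1.0 - params.beta1**t)
    vhat = state.v / (1.0 - params.beta2**t)
    p -= params.lr * mhat / (np.sqrt(vhat) + params.eps)
    p -= 2.0 * params.lam * params.lr * p


def _clamp_recenter_arr(p: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
    np.minimum(p, 0.0, out=p)
    w = p - p.min()
    tot = w.sum()
    if tot <= 0:
        return p
    h, wd = p.shape
    cr = (w.sum(axis=1) @ np.arange(h)) / tot
    cc = (w.sum(axis=0) @ np.arange(wd)) / tot
    dr = int(np.round(origin[0] - cr))
    dc = int(np.round(origin[1] - cc))
    if dr == 0 and dc == 0:
        return p
    out = np.full_like(p, p.min())
    src_r = slice(max(0, -dr), min(h, h - dr))
    dst_r = slice(max(0, dr), min(h, h + dr))
    src_c = slice(max(0, -dc), min(wd, wd - dc))
    dst_c = slice(max(0, dc), min(wd, wd + dc))
    out[dst_r, dst_c] = p[src_r, src_c]
    return out


def clamp_and_recenter(tip: InvertedTip) -> InvertedTip:
    """Zero out positive pixels, then shift the weighted centroid onto the origin.

    Weights are ``p - min(p)``; the shift is the integer translation bringing
    the weighted center of mass closest to the uv origin, with vacated border
    pixels filled with ``min(p)``.  An all-equal tip is returned unshifted.
    """
    p = _clamp_recenter_arr(tip.p.copy(), tip.origin_index)
    return InvertedTip(p, tip.pixel_size, tip.origin_index)


def _centroid_distance(p: np.ndarray, origin) -> float:
    w = p - p.min()
    tot = w.sum()
    if tot <= 0:
        return 0.0
    h, wd = p.shape
    cr = (w.sum(axis=1) @ np.arange(h)) / tot
    cc = (w.sum(axis=0) @ np.arange(wd)) / tot
    return float(np.hypot(cr - origin[0], cc - origin[1]))


def train_tip(
    dataset, params: LossParams, tip_grid_shape: tuple[int, int] = (10, 10)
) -> tuple[InvertedTip, TrainHistory]:
    """Functional entry point; see :class:`DifferentiableBTR` for the model form."""
    res = DifferentiableBTR(dataset, tip_grid_shape).fit(
        lam=params.lam,
        epochs=params.epochs,
        lr=params.lr,
        betas=(params.beta1, params.beta2),
        eps=params.eps,
    )
    return res.tip, res.history


class DifferentiableBTR:
    """Gradient-based blind tip reconstruction model over an AFM dataset.

    Parameters
    ----------
    dataset : AFMDataset
        Frames sharing one pixel geometry.
    tip_shape : (int, int)
        uv grid of the tip estimate (rows, cols), origin at the grid center.
    """

    def __init__(self, dataset, tip_shape: tuple[int, int] = (10, 10)):
        if len(dataset.frames) == 0:
            raise ValueError("dataset must contain at least one frame")
        H, W = dataset.grid_shape
        if tip_shape[0] > H or tip_shape[1] > W:
            raise ValueError(f"tip grid {tip_shape} larger than image grid {(H, W)}")
        self.dataset = dataset
        self.tip_shape = tuple(tip_shape)
        self.origin_index = center_origin(self.tip_shape)

    def fit(
        self,
        lam: float = 1e-7,
        epochs: int = 1000,
        lr: float = 0.1,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        callback=None,
    ) -> "DifferentiableBTRResults":
        """Minimize ``MSE(p) + lam * ||p||^2`` from a square-pillar start.

        Frames are visited one at a time (batch size 1, dataset order); each
        frame step runs gradient -> AdamW -> clamp -> recenter.  ``callback``
        (epoch, p-array) is invoked after every epoch if given.
        """
        params = LossParams(lam=lam, lr=lr, beta1=betas[0], beta2=betas[1], eps=eps, epochs=epochs)
        probe = InvertedTip(np.zeros(self.tip_shape), self.dataset.pixel_size, self.origin_index)
        geom = _check_pair(self.dataset.frames[0], probe)
        flats = [fr.heights.ravel() for fr in self.dataset.frames]
        # the erosion gather of each (fixed) frame is constant across steps
        gathers = [np.append(f, np.inf)[geom.plus] for f in flats]

        p = np.zeros(self.tip_shape)
        state = OptimizerState.zeros(self.tip_shape)
        history = TrainHistory()
        for epoch in range(params.epochs):
            frame_mses = []
            for i_flat, ie in zip(flats, gathers):
                grad, mse = _grad_and_mse(i_flat, p.ravel(), geom, ie=ie)
                frame_mses.append(mse)
                _adamw_inplace(p, grad.reshape(p.shape), state, params)
                p = _clamp_recenter_arr(p, self.origin_index)
            history.mse.append(float(np.mean(frame_mses)))
            history.reg.append(float(params.lam * np.sum(p * p)))
            history.max_p.append(float(p.max()))
            history.centroid_distance.append(_centroid_distance(p, self.origin_index))
            if callback is not None:
                callback(epoch, p.copy())
        tip = InvertedTip(p, self.dataset.pixel_size, self.origin_index)
        return DifferentiableBTRResults(self, params, tip, history)


class DifferentiableBTRResults(BTRResults):
    """Fitted gradient-based estimate with its training history."""

    def __init__(self, model, params, tip, history: TrainHistory):
        super().__init__(model, tip)
        self.params = params
        self.history = history

    _method_name = "differentiable blind tip reconstruction (AdamW)"

    def _summary_rows(self):
        return [
            ("lambda", f"{self.params.lam:g}"),
            ("epochs", f"{self.params.epochs}"),
            ("learning rate (nm)", f"{self.params.lr:g}"),
            ("final training MSE (nm^2)", f"{self.history.mse[-1]:.6g}"),
            ("final penalty (nm^2)", f"{self.history.reg[-1]:.6g}"),
        ]

    def plot_loss(self, ax=None):
        """Training-loss curve (running per-epoch MSE and penalty terms)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.history.to_frame()
        ax.semilogy(df["epoch"], df["mse"], label="MSE(p)")
        if np.any(np.asarray(df["regularization"]) > 0):
            ax.semilogy(df["epoch"], df["regularization"], label="lambda * ||p||^2")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss term (nm$^2$)")
        ax.legend()
        return ax
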
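"""Evaluation and model selection for blind tip reconstruction.

Deconvolution, leave-one-out cross-validated MSE(p) curves, the
one-standard-error rule for choosing the regularization weight, masked RMSD
metrics against ground truth (with exhaustive integer translation search for
the tip), and stage-tilt plane correction for real scanner data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphology import HeightImage, InvertedTip, erode
from .diffbtr import DifferentiableBTR, opening_mse
from .original import OriginalBTR

__all__ = [
    "CVResult",
    "EvalReport",
    "deconvolve",
    "loocv_mse",
    "select_one_se",
    "tip_rmsd",
    "surface_rmsd",
    "tilt_correct",
]


@dataclass
class CVResult:
    """Cross-validated MSE(p) at one parameter value (one fold per frame)."""

    parameter: float
    fold_mses: list[float]
    use_se: bool = True  # standard error (std/sqrt(K)) vs plain std for the 1-SE rule

    @property
    def n_folds(self) -> int:
        return len(self.fold_mses)

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_mses))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_mses, ddof=1)) if self.n_folds > 1 else 0.0

    @property
    def se(self) -> float:
        return self.std / np.sqrt(self.n_folds) if self.use_se else self.std


@dataclass
class EvalReport:
    """Collected twin-experiment evaluation: CV curve, choice, RMSD summaries."""

    cv_results: list[CVResult] = field(default_factory=list)
    chosen_parameter: float | None = None
    tip_rmsd: float | None = None
    surface_rmsds: list[float] = field(default_factory=list)

    def cv_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": [r.parameter for r in self.cv_results],
                "mean_mse": [r.mean for r in self.cv_results],
                "se_mse": [r.se for r in self.cv_results],
                "n_folds": [r.n_folds for r in self.cv_results],
            }
        )


def deconvolve(image: HeightImage, tip: InvertedTip) -> HeightImage:
    """Reconstruct the sample surface by eroding ``image`` with ``tip``.

    The result is an upper bound on the true surface (``s_r >= s``) whenever
    ``tip`` is (at least as blunt as) the generating tip.
    """
    return erode(image, tip)


def _reconstruct(dataset, method: str, parameter: float, tip_shape, method_config):
    cfg = dict(method_config or {})
    if method == "original":
        return OriginalBTR(dataset, tip_shape).fit(thresh=parameter, **cfg).tip
    if method == "differentiable":
        return DifferentiableBTR(dataset, tip_shape).fit(lam=parameter, **cfg).tip
    raise ValueError(f"unknown method {method!r}; expected 'original' or 'differentiable'")


def loocv_mse(
    dataset,
    method: str,
    parameter: float,
    tip_shape: tuple[int, int] = (10, 10),
    method_config: dict | None = None,
    use_se: bool = True,
) -> CVResult:
    """Leave-one-out cross-validated opening MSE at one parameter value.

    For each fold the tip is reconstructed on all frames but one and MSE(p)
    is evaluated on the held-out frame; folds = number of frames.
    """
    n = len(dataset.frames)
    if n < 2:
        raise ValueError("leave-one-out cross-validation needs at least 2 frames")
    fold_mses = []
    for k in range(n):
        train = dataset.subset([j for j in range(n) if j != k])
        tip = _reconstruct(train, method, parameter, tip_shape, method_config)
        fold_mses.append(opening_mse([dataset.frames[k]], tip))
    return CVResult(parameter, fold_mses, use_se=use_se)


def select_one_se(parameters, results: list[CVResult], slack: float = 0.0) -> float:
    """One-standard-error rule over an ascending parameter (lambda) list.

    Finds the parameter with minimum mean MSE, forms the bound
    ``mean_min + se_min`` (inflated by ``slack * se_min`` for the looser
    "within or around" reading), and returns the largest parameter whose mean
    does not exceed the bound.  Never returns a parameter below the minimizer.
    """
    parameters = list(parameters)
    if not parameters or len(parameters) != len(results):
        raise ValueError("parameters and results must be non-empty and aligned")
    order = np.argsort(parameters)
    parameters = [parameters[k] for k in order]
    results = [results[k] for k in order]
    means = np.array([r.mean for r in results])
    k_min = int(np.argmin(means))
    bound = means[k_min] + (1.0 + slack) * results[k_min].se
    eligible = [k for k in range(len(parameters)) if means[k] <= bound and k >= k_min]
    return parameters[max(eligible)]


def _masked_rmsd(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a[mask] - b[mask]) ** 2)))


def tip_rmsd(
    estimate: InvertedTip,
    truth: InvertedTip,
    mask_floor: float = -7.0,
    max_shift: tuple[int, int] | None = None,
) -> float:
    """Minimum masked RMSD between tip estimates over integer translations.

    The mask keeps uv pixels where the *truth* satisfies ``p > mask_floor``
    (default -7 nm, about the height of the imaged molecule, restricting the
    comparison to the part of the tip the data can constrain).  The estimate
    is translated exhaustively (vacated pixels filled with its minimum) over
    all shifts retaining at least 50% grid overlap, and the smallest RMSD is
    returned; the zero shift is always included, so the translation search
    can only lower the plain masked RMSD.
    """
    if not np.isclose(estimate.pixel_size, truth.pixel_size):
        raise ValueError("estimate and truth must share pixel_size")
    if estimate.p.shape != truth.p.shape:
        raise ValueError("estimate and truth must share the uv grid shape")
    mask = truth.p > mask_floor
    if not mask.any():
        raise ValueError(f"mask_floor={mask_floor} leaves no pixels to compare")
    h, w = truth.p.shape
    # 50% overlap: (h - |dr|)(w - |dc|) >= h*w/2
    rmax = h // 2 if max_shift is None else max_shift[0]
    cmax = w // 2 if max_shift is None else max_shift[1]
    fill = estimate.p.min()
    best = np.inf
    for dr in range(-rmax, rmax + 1):
        for dc in range(-cmax, cmax + 1):
            if max_shift is None and (h - abs(dr)) * (w - abs(dc)) * 2 < h * w:
                continue
            shifted = np.full_like(estimate.p, fill)
            src_r = slice(max(0, -dr), min(h, h - dr))
            dst_r = slice(max(0, dr), min(h, h + dr))
            src_c = slice(max(0, -dc), min(w, w - dc))
            dst_c = slice(max(0, dc), min(w, w + dc))
            shifted[dst_r, dst_c] = estimate.p[src_r, src_c]
            best = min(best, _masked_rmsd(shifted, truth.p, mask))
    return best


def surface_rmsd(estimate: HeightImage, truth: HeightImage, mask_floor: float = 1.0) -> float:
    """Masked RMSD between a reconstructed surface and the ground truth.

    The mask keeps xy pixels where the *reconstructed* surface exceeds
    ``mask_floor`` (default 1 nm, about 3 sigma of typical HS-AFM noise,
    which excludes bare-stage pixels).
    """
    if estimate.shape != truth.shape:
        raise ValueError("surfaces must share the grid shape")
    mask = estimate.heights > mask_floor
    if not mask.any():
        raise ValueError(f"mask_floor={mask_floor} leaves no pixels to compare")
    return _masked_rmsd(estimate.heights, truth.heights, mask)


def tilt_correct(image: HeightImage) -> HeightImage:
    """Remove the least-squares plane ``z = a*x + b*y + c`` from an image.

    Corrects stage tilt in real scanner data; the residual has zero mean and
    a pure-plane input maps to all zeros.
    """
    H, W = image.shape
    if H * W < 3:
        raise ValueError("tilt correction needs at least 3 pixels")
    yy, xx = np.mgrid[0:H, 0:W]
    A = np.column_stack([xx.ravel(), yy.ravel(), np.ones(H * W)])
    coef, *_ = np.linalg.lstsq(A, image.heights.ravel(), rcond=None)
    plane = (A @ coef).reshape(H, W)
    return HeightImage(image.heights - plane, image.pixel_size, image.frame_id)
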
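"""Shared results-object plumbing for the two tip estimators."""

from __future__ import annotations

import numpy as np

from .morphology import HeightImage, InvertedTip, erode, opening

__all__ = ["BTRResults"]


class BTRResults:
    """Base class carrying a fitted tip and the operations derived from it."""

    _method_name = "blind tip reconstruction"

    def __init__(self, model, tip: InvertedTip):
        self.model = model
        self.tip = tip

    # -- derived quantities -------------------------------------------------

    def deconvolve(self, image: HeightImage | None = None) -> HeightImage | list[HeightImage]:
        """Erode one image (or every dataset frame) with the fitted tip."""
        if image is not None:
            return erode(image, self.tip)
        return [erode(fr, self.tip) for fr in self.model.dataset.frames]

    def opening_mse(self, frames=None) -> float:
        """Mean opening residual ``MSE(p)`` of the fitted tip over ``frames``."""
        if frames is None:
            frames = self.model.dataset.frames
        total = 0.0
        for fr in frames:
            opened, _ = opening(fr, self.tip)
            total += float(np.mean((opened.heights - fr.heights) ** 2))
        return total / len(frames)

    def tip_volume(self) -> float:
        """Volume (nm^3) between the apex plane and the inverted tip surface."""
        return float((-self.tip.p).sum()) * self.tip.pixel_size**2

    # -- presentation -------------------------------------------------------

    def _summary_rows(self):  # overridden by subclasses
        return []

    def summary(self) -> str:
        ds = self.model.dataset
        rows = [
            ("method", self._method_name),
            ("frames", f"{len(ds.frames)}"),
            ("image grid", f"{ds.grid_shape[0]} x {ds.grid_shape[1]} px"),
            ("pixel size (nm)", f"{ds.pixel_size:g}"),
            ("tip grid", f"{self.tip.shape[0]} x {self.tip.shape[1]} px"),
            *self._summary_rows(),
            ("MSE(p) on data (nm^2)", f"{self.opening_mse():.6g}"),
            ("tip depth min p (nm)", f"{self.tip.p.min():.4g}"),
            ("tip volume (nm^3)", f"{self.tip_volume():.4g}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Blind tip reconstruction results", "=" * 38]
        lines += [f"{k.ljust(width)} : {v}" for k, v in rows]
        return "\n".join(lines)

    def plot_tip(self, ax=None):
        """Cross sections of the fitted tip through the apex row/column."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        orr, orc = self.tip.origin_index
        h, w = self.tip.shape
        x = (np.arange(w) - orc) * self.tip.pixel_size
        y = (np.arange(h) - orr) * self.tip.pixel_size
        ax.plot(x, self.tip.p[orr, :], label="x cross section")
        ax.plot(y, self.tip.p[:, orc], label="y cross section", ls="--")
        ax.set_xlabel("u (nm)")
        ax.set_ylabel("p (nm)")
        ax.legend()
        return ax
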
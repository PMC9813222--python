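"""File I/O for AFM datasets and tip grids.

Datasets live either in a directory of per-frame plain-matrix text files
(``frame_000.txt`` ...) plus a ``metadata.json`` sidecar, or in a multi-page
floating-point TIFF with heights in nm.  Tips are a matrix text file plus a
JSON sidecar carrying ``origin_index`` and ``pixel_size``.  Heights are
always nm; arrays are row = y, column = x with the origin at top-left.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .morphology import HeightImage, InvertedTip, center_origin
from .simulate import AFMDataset

__all__ = [
    "FormatError",
    "write_dataset",
    "read_image_stack",
    "write_tip",
    "read_tip",
]

FORMAT_VERSION = 1


class FormatError(ValueError):
    """Malformed or inconsistent on-disk dataset."""


def write_dataset(dataset: AFMDataset, path, tiff: bool = False) -> Path:
    """Write a dataset as per-frame matrices (or one TIFF) plus metadata.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": FORMAT_VERSION,
        "pixel_size_nm": dataset.pixel_size,
        "noise_sigma_nm": dataset.noise_sigma,
        "seed": dataset.seed,
        "n_frames": len(dataset.frames),
        "height_unit": "nm",
        "axes": "row = y, col = x, origin top-left",
    }
    if tiff:
        import tifffile

        stack = np.stack([fr.heights for fr in dataset.frames]).astype(np.float32)
        tifffile.imwrite(path / "frames.tif", stack)
    else:
        for k, fr in enumerate(dataset.frames):
            np.savetxt(path / f"frame_{k:04d}.txt", fr.heights, fmt="%.8g")
    (path / "metadata.json").write_text(json.dumps(meta, indent=2))
    if dataset.truth is not None:
        tdir = path / "truth"
        tdir.mkdir(exist_ok=True)
        write_tip(dataset.truth.tip, tdir / "tip.txt")
        for k, fr in enumerate(dataset.truth.surfaces):
            np.savetxt(tdir / f"surface_{k:04d}.txt", fr.heights, fmt="%.8g")
    return path


def _read_matrix(path: Path) -> np.ndarray:
    try:
        arr = np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None)
    except ValueError as exc:
        raise FormatError(f"could not parse matrix file {path}: {exc}") from exc
    return np.atleast_2d(arr)


def read_image_stack(path) -> AFMDataset:
    """Read a dataset directory (or a multi-page TIFF file) back into memory.

    Frames are ordered by filename (or TIFF page).  A missing metadata
    sidecar falls back to defaults (pixel_size 1 nm, sigma 0) with a warning;
    frames of inconsistent shape are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = {}
    meta_path = (path if path.is_dir() else path.parent) / "metadata.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        warnings.warn(f"no metadata.json next to {path}; assuming pixel_size=1 nm, sigma=0")
    pixel_size = float(meta.get("pixel_size_nm", 1.0))
    sigma = float(meta.get("noise_sigma_nm", 0.0))
    seed = meta.get("seed")

    if path.is_dir():
        tif = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        files = sorted(p for p in path.iterdir() if p.suffix in {".txt", ".csv", ".dat"})
        if tif:
            grids = _read_tiff(tif[0])
        elif files:
            grids = [_read_matrix(f) for f in files]
        else:
            raise FormatError(f"no frame files found in {path}")
    elif path.suffix.lower() in {".tif", ".tiff"}:
        grids = _read_tiff(path)
    else:
        grids = [_read_matrix(path)]

    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise FormatError(f"frames have inconsistent shapes: {sorted(shapes)}")
    frames = [HeightImage(g, pixel_size, k) for k, g in enumerate(grids)]
    return AFMDataset(frames, pixel_size, sigma, seed)


def _read_tiff(path: Path) -> list[np.ndarray]:
    import tifffile

    stack = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    if stack.ndim == 2:
        stack = stack[None]
    return [stack[k] for k in range(stack.shape[0])]


def write_tip(tip: InvertedTip, path) -> Path:
    """Write a tip matrix with a JSON sidecar (origin index, pixel size)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, tip.p, fmt="%.10g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "format_version": FORMAT_VERSION,
                "origin_index": list(tip.origin_index),
                "pixel_size_nm": tip.pixel_size,
                "height_unit": "nm",
            },
            indent=2,
        )
    )
    return path


def read_tip(path) -> InvertedTip:
    """Read a tip matrix; positive entries are clamped to 0 with a warning.

    A missing sidecar falls back to a centered origin and pixel_size 1 nm.
    """
    path = Path(path)
    p = _read_matrix(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        origin = tuple(meta.get("origin_index", center_origin(p.shape)))
        pixel_size = float(meta.get("pixel_size_nm", 1.0))
    else:
        warnings.warn(f"no sidecar {sidecar.name}; assuming centered origin, pixel_size=1 nm")
        origin, pixel_size = center_origin(p.shape), 1.0
    if np.any(p > 0):
        warnings.warn("tip file contains positive heights; clamping to 0")
        p = np.minimum(p, 0.0)
    return InvertedTip(p, pixel_size, origin)
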
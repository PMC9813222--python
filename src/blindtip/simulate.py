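"""Pseudo-AFM twin-experiment simulator.

Generates the three ingredients of a twin experiment: a ground-truth tip
(hemisphere capped cone, optionally doubled), molecular surfaces rasterized
from van-der-Waals spheres of randomly oriented atomic structures, and noisy
pseudo-AFM frames (dilation + i.i.d. Gaussian pixel noise).

Defaults follow the standard HS-AFM twin-experiment setup: 20 frames of
30x30 pixels at 1.5 nm/pixel, a 10x10 tip grid with apex radius 2.5 nm and
half angle 10 deg (14x10 for double tips), and noise sigma = 0.3 nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .morphology import HeightImage, InvertedTip, center_origin, dilate

__all__ = [
    "TipSpec",
    "AtomSet",
    "SimulationTruth",
    "AFMDataset",
    "VDW_RADII_NM",
    "make_tip",
    "make_double_tip",
    "random_rotation",
    "surface_from_atoms",
    "make_blob_atoms",
    "generate_dataset",
    "load_pdb_atoms",
]

#: van-der-Waals radii in nm used for all-atom structures (Bondi-style table).
VDW_RADII_NM = {"H": 0.12, "C": 0.17, "N": 0.155, "O": 0.152, "S": 0.18, "P": 0.18}
_DEFAULT_RADIUS_NM = 0.17


@dataclass
class TipSpec:
    """Geometric parameters of the hemisphere + cone-frustum model tip.

    ``apex_radius`` (nm) is the radius of the spherical cap at the apex and
    ``half_angle`` (degrees) the cone half angle; the two branches join
    tangentially at radial distance ``r*cos(theta)``.
    """

    apex_radius: float = 2.5
    half_angle: float = 10.0
    grid_shape: tuple[int, int] = (10, 10)
    pixel_size: float = 1.5

    def __post_init__(self):
        if not self.apex_radius > 0:
            raise ValueError(f"apex_radius must be > 0, got {self.apex_radius}")
        if not 0.0 < self.half_angle < 90.0:
            raise ValueError(f"half_angle must be in (0, 90) degrees, got {self.half_angle}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")


@dataclass
class AtomSet:
    """Spheres standing in for atoms: centers (nm) and per-atom vdW radii (nm)."""

    coordinates: np.ndarray  # (n, 3), columns x, y, z in nm
    radii: np.ndarray  # (n,)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64).reshape(-1, 3)
        self.radii = np.broadcast_to(
            np.asarray(self.radii, dtype=np.float64), (self.coordinates.shape[0],)
        ).copy()
        if self.coordinates.shape[0] == 0:
            raise ValueError("AtomSet must contain at least one atom")
        if np.any(self.radii <= 0):
            raise ValueError("all atom radii must be > 0")

    def __len__(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class SimulationTruth:
    """Ground truth attached to a simulated dataset."""

    tip: InvertedTip
    surfaces: list[HeightImage]
    clean_images: list[HeightImage]


@dataclass
class AFMDataset:
    """An ordered stack of AFM frames sharing one pixel geometry.

    ``truth`` is populated for simulated (twin-experiment) data and holds the
    generating tip plus the noise-free surfaces and images.
    """

    frames: list[HeightImage]
    pixel_size: float
    noise_sigma: float = 0.0
    seed: int | None = None
    truth: SimulationTruth | None = None

    def __post_init__(self):
        if len(self.frames) == 0:
            raise ValueError("AFMDataset must contain at least one frame")
        shape = self.frames[0].shape
        for fr in self.frames:
            if fr.shape != shape:
                raise ValueError(f"all frames must share one grid shape; {fr.shape} != {shape}")
            if not np.isclose(fr.pixel_size, self.pixel_size):
                raise ValueError("frame pixel_size disagrees with dataset pixel_size")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def subset(self, indices) -> "AFMDataset":
        return AFMDataset(
            [self.frames[k] for k in indices], self.pixel_size, self.noise_sigma, self.seed, self.truth
        )


def _tip_profile(d: np.ndarray, r: float, theta_deg: float) -> np.ndarray:
    """Tip depth t(d) at radial distance d from the apex axis (both nm)."""
    th = math.radians(theta_deg)
    d = np.asarray(d, dtype=np.float64)
    join = r * math.cos(th)
    sphere = r - np.sqrt(np.maximum(r * r - np.minimum(d, join) ** 2, 0.0))
    cone = r - r * math.sin(th) + (d - join) / math.tan(th)
    return np.where(d <= join, sphere, cone)


def make_tip(spec: TipSpec, origin_index: tuple[int, int] | None = None) -> InvertedTip:
    """Rasterize the hemisphere + cone tip onto its uv grid as ``p = -t``.

    The apex sits at ``origin_index`` (grid center by default) with p = 0.
    """
    h, w = spec.grid_shape
    origin = center_origin((h, w)) if origin_index is None else origin_index
    rr = (np.arange(h)[:, None] - origin[0]) * spec.pixel_size
    cc = (np.arange(w)[None, :] - origin[1]) * spec.pixel_size
    d = np.hypot(rr, cc)
    p = -_tip_profile(d, spec.apex_radius, spec.half_angle)
    return InvertedTip(p, spec.pixel_size, origin)


def make_double_tip(
    spec: TipSpec,
    offset_px: int = 4,
    grid_shape: tuple[int, int] | None = None,
) -> InvertedTip:
    """Two copies of the single tip with apexes ``offset_px`` pixels apart along x.

    The composite is the pixelwise maximum of the two single-tip fields; both
    apexes have p = 0.  The default grid is (10, 14): 14 pixels along the
    (fast-scan) x axis, 10 along y.
    """
    if offset_px < 0:
        raise ValueError("offset_px must be >= 0")
    shape = grid_shape if grid_shape is not None else ((10, 14) if offset_px else spec.grid_shape)
    h, w = shape
    orr, orc = center_origin(shape)
    left = (orr, orc - offset_px // 2)
    right = (left[0], left[1] + offset_px)
    for apex in (left, right):
        if not (0 <= apex[0] < h and 0 <= apex[1] < w):
            raise ValueError(f"apex {apex} falls outside the {shape} tip grid")
    spec2 = TipSpec(spec.apex_radius, spec.half_angle, shape, spec.pixel_size)
    p = np.maximum(make_tip(spec2, left).p, make_tip(spec2, right).p)
    return InvertedTip(p, spec.pixel_size, (orr, orc))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A rotation matrix drawn uniformly from SO(3) (Gaussian quaternion)."""
    q = rng.standard_normal(4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def surface_from_atoms(
    atoms: AtomSet,
    rotation: np.ndarray,
    grid_shape: tuple[int, int] = (30, 30),
    pixel_size: float = 1.5,
) -> HeightImage:
    """Rasterize the vdW-sphere surface of a rotated structure onto the stage grid.

    The structure is rotated about its center of mass, centered laterally on
    the grid, and rested on the stage (lowest sphere tangent to z = 0).  Each
    pixel-center height is the maximum over covering atoms of
    ``z_a + sqrt(rad_a^2 - lateral_dist^2)``, clipped at the stage level;
    uncovered pixels are 0.
    """
    R = np.asarray(rotation, dtype=np.float64)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
        np.linalg.det(R), 1.0, atol=1e-8
    ):
        raise ValueError("rotation must be a proper orthonormal 3x3 matrix (det +1)")
    xyz = atoms.coordinates - atoms.coordinates.mean(axis=0)
    xyz = xyz @ R.T
    rad = atoms.radii
    xyz[:, 2] -= (xyz[:, 2] - rad).min()  # rest the molecule on the stage

    H, W = grid_shape
    # pixel centers, molecule centered laterally on the grid
    ys = (np.arange(H) - (H - 1) / 2.0) * pixel_size
    xs = (np.arange(W) - (W - 1) / 2.0) * pixel_size
    heights = np.zeros((H, W))
    # chunk over atoms to bound the (n_atoms x n_pixels) distance matrix
    for start in range(0, len(atoms), 2048):
        ax, ay, az = (c[:, None, None] for c in xyz[start : start + 2048].T)
        ar = rad[start : start + 2048, None, None]
        d2 = (xs[None, None, :] - ax) ** 2 + (ys[None, :, None] - ay) ** 2
        cap = np.where(d2 <= ar**2, az + np.sqrt(np.maximum(ar**2 - d2, 0.0)), -np.inf)
        heights = np.maximum(heights, cap.max(axis=0))
    return HeightImage(np.maximum(heights, 0.0), pixel_size)


def make_blob_atoms(
    n_atoms: int = 6500,
    extent: tuple[float, float, float] = (4.0, 2.8, 2.2),
    rng: np.random.Generator | int | None = None,
    n_lobes: int = 3,
    atom_radius: float = _DEFAULT_RADIUS_NM,
) -> AtomSet:
    """A compact lobed globule of spheres standing in for a protein structure.

    Synthetic stand-in used when no PDB structure is available.  Atoms are
    drawn uniformly from ``n_lobes`` overlapping ellipsoidal subdomains spread
    along the long axis of an envelope with semi-axes ``extent`` (nm).  The
    defaults emulate a ~770-residue motor-domain-sized globule: ~6500 heavy
    atoms at all-atom packing density (~60 atoms/nm^3, vdW radius 0.17 nm),
    overall size ~8 x 5.6 x 4.4 nm, hence 4.5-8 nm tall depending on
    orientation, with an atomically rough surface and gentle subdomain
    clefts.  It reproduces the image statistics that matter for tip
    reconstruction (sharp rim, rough top, stage background); it does not
    reproduce any real protein's fold or secondary-structure texture.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(rng)
    ext = np.asarray(extent, dtype=np.float64)
    lobe_axes = ext * np.array([0.6, 0.85, 0.95])
    if n_lobes > 1:
        cx = np.linspace(-(ext[0] - lobe_axes[0]), ext[0] - lobe_axes[0], n_lobes)
    else:
        cx = np.zeros(1)
    jitter = rng.uniform(-0.25, 0.25, size=(n_lobes, 2)) * ext[1:]
    centers = np.column_stack([cx, jitter])
    which = rng.integers(0, n_lobes, size=n_atoms)
    # uniform draw inside a unit ball, scaled to the lobe ellipsoid
    v = rng.standard_normal((n_atoms, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    v *= rng.uniform(0.0, 1.0, size=(n_atoms, 1)) ** (1.0 / 3.0)
    xyz = centers[which] + v * lobe_axes
    return AtomSet(xyz, np.full(n_atoms, atom_radius))


def generate_dataset(
    atoms: AtomSet,
    tip: InvertedTip,
    n_frames: int = 20,
    grid_shape: tuple[int, int] = (30, 30),
    pixel_size: float = 1.5,
    sigma: float = 0.3,
    seed: int | None = 0,
) -> AFMDataset:
    """Simulate a noisy pseudo-AFM movie from a structure and a known tip.

    Per frame: fresh uniform random orientation -> vdW surface rasterization
    -> dilation with ``tip`` -> i.i.d. Gaussian pixel noise N(0, sigma^2).
    Each frame has its own child RNG stream spawned from ``seed``, so frame k
    is reproducible independently of ``n_frames``.  The noise-free surfaces
    and the generating tip are stored in ``dataset.truth``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not np.isclose(tip.pixel_size, pixel_size):
        raise ValueError("tip pixel_size must match the requested image pixel_size")
    streams = np.random.SeedSequence(seed).spawn(n_frames)
    surfaces, clean, noisy = [], [], []
    for k, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        R = random_rotation(rng)
        surf = surface_from_atoms(atoms, R, grid_shape, pixel_size)
        surf.frame_id = k
        img = dilate(surf, tip)
        img.frame_id = k
        obs = HeightImage(
            img.heights + rng.normal(scale=sigma, size=img.shape) if sigma > 0 else img.heights.copy(),
            pixel_size,
            k,
        )
        surfaces.append(surf)
        clean.append(img)
        noisy.append(obs)
    truth = SimulationTruth(tip=tip.copy(), surfaces=surfaces, clean_images=clean)
    return AFMDataset(noisy, pixel_size, sigma, seed, truth)


def load_pdb_atoms(
    path,
    chains: list[str] | None = None,
    include_hydrogens: bool = False,
    radii: dict[str, float] | None = None,
) -> AtomSet:
    """Read atomic coordinates from a PDB file into an :class:`AtomSet`.

    Coordinates are converted from Angstrom to nm and element-wise vdW radii
    assigned from ``radii`` (defaults to :data:`VDW_RADII_NM`; unknown
    elements get the carbon radius with a warning).  ``chains`` selects chain
    identifiers to keep, e.g. to drop light chains from a motor-domain entry.
    """
    import biotite.structure.io.pdb as pdb

    table = dict(VDW_RADII_NM if radii is None else radii)
    structure = pdb.PDBFile.read(str(path)).get_structure(model=1)
    mask = np.ones(structure.array_length(), dtype=bool)
    if chains is not None:
        mask &= np.isin(structure.chain_id, list(chains))
    if not include_hydrogens:
        mask &= structure.element != "H"
    structure = structure[mask]
    if structure.array_length() == 0:
        raise ValueError("no atoms left after chain/element filtering")
    elements = np.char.capitalize(structure.element.astype(str))
    unknown = sorted(set(elements) - set(table))
    if unknown:
        warnings.warn(f"unknown elements {unknown}; using carbon vdW radius")
    rad = np.array([table.get(e, _DEFAULT_RADIUS_NM) for e in elements])
    return AtomSet(structure.coord * 0.1, rad)
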
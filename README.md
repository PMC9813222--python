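# blindtip

Blind tip reconstruction (BTR) for atomic force microscopy.

An AFM image is not the sample surface: it is the grayscale **dilation** of
the surface with the probe tip, `i(x,y) = max_{u,v}[s(x-u, y-v) + p(u,v)]`,
where `p(u,v) = -t(-u,-v) <= 0` is the inverted tip. Knowing `p`, the
surface can be approximately deconvolved by **erosion**,
`s_r(x,y) = min_{u,v}[i(x+u, y+v) - p(u,v)]`, which yields the least upper
bound on surfaces consistent with the image. Blind tip reconstruction
estimates `p` from the images alone, exploiting the opening identity
`I o P = I` that holds exactly for the generating tip.

The package implements two estimators over multi-frame height-image stacks
(heights in nm), in the statsmodels mold — a model object built from data
whose `fit()` returns a results object:

* **`OriginalBTR`** — Villarrubia-style iterative carving of a square-pillar
  tip, controlled by a tolerance `thresh` (nm). Exact on noise-free data;
  noise-sensitive and strongly `thresh`-dependent.
* **`DifferentiableBTR`** — minimizes the opening mean-square error plus an
  L2 tip penalty, `MSE(p) + lambda*||p||^2`, by AdamW with argmax/argmin
  subgradient routing, positivity clamping, and center-of-weight recentering.
  Robust over decades of `lambda` on noisy data and able to recover
  double-tip (contaminated probe) shapes that carving misses.

Around them: a pseudo-AFM **twin-experiment simulator** (random 3D
orientations of an atomic structure, van-der-Waals surface rasterization,
dilation by a hemisphere+cone model tip, Gaussian pixel noise), and an
**evaluation suite** (erosion deconvolution, leave-one-out cross-validated
`MSE(p)` curves, the one-standard-error rule for picking `lambda`, masked
tip/surface RMSD with exhaustive translation search, stage-tilt correction).

Intended for HS-AFM practitioners post-processing biomolecule movies and for
method developers who need a reproducible, fully synthetic test bed.

## Worked example

```python
import blindtip as bt

# twin experiment: simulate a noisy movie from a synthetic globular molecule
atoms = bt.make_blob_atoms(rng=7)                 # ~6500 vdW spheres, ~7 nm globule
truth = bt.make_tip(bt.TipSpec())                 # r=2.5 nm, theta=10 deg, 10x10 grid
ds = bt.generate_dataset(atoms, truth, n_frames=20, sigma=0.3, seed=11)

res = bt.DifferentiableBTR(ds, tip_shape=(10, 10)).fit(lam=1e-7, epochs=1000)
print(res.summary())
print("tip RMSD vs truth:", round(bt.tip_rmsd(res.tip, truth), 2), "nm")

surface = res.deconvolve(ds.frames[0])            # erosion with the fitted tip
```

prints (abridged):

```
Blind tip reconstruction results
======================================
method                    : differentiable blind tip reconstruction (AdamW)
frames                    : 20
image grid                : 30 x 30 px
pixel size (nm)           : 1.5
tip grid                  : 10 x 10 px
lambda                    : 1e-07
epochs                    : 1000
learning rate (nm)        : 0.1
final training MSE (nm^2) : 0.0705801
final penalty (nm^2)      : 0.00050817
MSE(p) on data (nm^2)     : 0.0681365
tip depth min p (nm)      : -10.44
tip volume (nm^3)         : 1477
tip RMSD vs truth: 1.79 nm
```

The training MSE (~0.07 nm^2, below sigma^2 = 0.09) shows the opening
residual has reached the noise floor; the masked tip RMSD compares the
estimate with the ground-truth tip near the apex (see `docs/methods.md` for
the mask and the known local-minimum caveat of the gradient estimator). The
same dataset with `OriginalBTR(ds, (10, 10)).fit(thresh=4.0)` gives a
blunter tip with larger tip RMSD (~2.3 nm), and its accuracy swings roughly
2x as `thresh` moves over 0.1-8 nm, while the gradient estimator stays
nearly flat for `lambda` anywhere in 1e-7..1e-4.

A command-line interface mirrors the library:

```sh
blindtip simulate --blob --frames 20 --sigma 0.3 --seed 1 --out ds/
blindtip reconstruct-diff --data ds/ --lambda 1e-7 --epochs 1000 --out tip.txt
blindtip deconvolve --data ds/ --tip tip.txt --out surfaces/
blindtip select-lambda --data ds/ --parameters 1e-7,1e-6,1e-5,1e-4
blindtip twin-experiment --realizations 3 --out results/
```

Real scanner data can be loaded from directories of plain-matrix text files
or float TIFF stacks (`read_image_stack`), tilt-corrected
(`tilt_correct`), and fed to either estimator; atomic structures load from
PDB files (`load_pdb_atoms`, with chain filtering to drop e.g. light
chains).

## Acceptance script

`scripts/acceptance.py` re-runs the package's core computation from scratch:
it simulates a 20-frame noisy (sigma = 0.3 nm) pseudo-AFM movie of the
synthetic globule, reconstructs the tip with both estimators at their
standard parameters (thresh = 4.0 nm; lambda = 1e-7, 1000 epochs),
deconvolves every frame, and prints masked tip and surface RMSDs against the
stored ground truth:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
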
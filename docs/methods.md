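# Methods

## The imaging model

An AFM height image is modelled as the grayscale **dilation** of the sample
surface `s(x, y)` with the inverted probe tip
`p(u, v) = -t(-u, -v) <= 0` (heights in nm, apex at the moving uv origin):

    i(x, y)   = max_{u,v} [ s(x - u, y - v) + p(u, v) ]        (dilation)
    s_r(x, y) = min_{u,v} [ i(x + u, y + v) - p(u, v) ]        (erosion)

Erosion is the approximate deconvolution; it returns the least upper bound on
surfaces reproducing the image, so `s_r >= s` always. The **opening**
`I o P` (erosion then dilation) satisfies `I o P = I` exactly when `P` is the
tip that produced `I` — the identity both estimators exploit.

**Boundary rule.** Reductions run only over tip offsets whose image index is
in range ("valid overlap"); no heights are invented outside the scanned
area. Zero padding at stage level was also evaluated during development and
did not change estimator behavior materially on simulated data.

**Ties.** argmax/argmin ties resolve to the smallest row-major tip index, so
traces and gradients are deterministic.

**Exactness.** The opening identities hold to float rounding (~1e-15 nm);
tests assert them at 1e-12.

## Carving estimator (`OriginalBTR`)

From a square pillar (`p = 0`, the bluntest admissible tip), every scan
position `c` of every frame contributes the constraint that the tip, touching
the image at `c` through some contact offset `d`, must fit under the image.
With `dill(u; c, d) = i(c + u - d) - i(c) + p(d)`:

* contact `d` is **admissible** at `c` iff the implied apex position stays
  under the image at the apex pixel: `i(c - d) - i(c) + p(d) >= -thresh`;
* the bound from `c` is `max_d dill` over admissible `d` (the contact is
  unknown, so the weakest bound is the safe one);
* the update takes the min of these bounds over all `c`, plus `thresh`, and
  lowers `p(u, v)` when that is smaller (Jacobi sweep; the apex pixel is
  pinned at 0).

Frames are processed sequentially, each refined to a frame-level fixed point,
and full sweeps repeat until a sweep carves nothing (hard cap
`max_sweeps = 50`; converges in 2-5 sweeps in practice). Carving is monotone
and, for noise-free data, keeps `p_est >= p_true` pixelwise.

A note on the carving rule: taking the *minimum* of `dill` over all contacts
(a reading the source description invites) collapses the tip to its minimum
on featureless image regions and destroys the upper-bound property; the
admissible-contact/max formulation above is the classical refinement, passes
the worked 1-D example (`[0,2,0]` carves a pillar to `[-2,0,-2]` at
`thresh = 0`), and recovers the generating tip essentially exactly from
noise-free simulated movies.

`thresh` (nm) is the tolerance for attributing a dent to tip geometry rather
than noise; it enters both the admissibility test and the carve level. Small
values overfit the tip to noise (thin spikes), large values leave it blunt;
2-4x the noise sd is the practical range, and `MSE(p)` grows monotonically
with it.

## Gradient estimator (`DifferentiableBTR`)

Minimizes `L(p) = MSE(p) + lambda * ||p||^2` with
`MSE(p) = (1/N) sum_xy (opening(i)(x,y) - i(x,y))^2`, starting from the same
square pillar. Subgradients route through the reductions max-pooling style:
each output pixel sends `+resid` to the tip pixel chosen by the dilation and
`-resid` to the tip pixel chosen by the erosion of the eroded value it
consumed. The routed gradient matches central finite differences to 1e-6 on
tie-free instances (tested).

Optimization is AdamW: `lr = 0.1` nm, `beta1 = 0.9`, `beta2 = 0.999`,
`eps = 1e-8` (our choice; unstated upstream), batch size 1 frame in dataset
order (deterministic; shuffling was evaluated and did not change outcomes),
default 1000 epochs (middle of the stated 100-2000 range). The L2 penalty is
applied as decoupled weight decay `p *= (1 - 2*lambda*lr)` per step — the
gradient-descent-consistent mapping of `lambda * ||p||^2`; other decay
conventions rescale the effective lambda axis, so lambda values are
comparable across this package but not necessarily to other
implementations. After every frame update the tip is clamped to `p <= 0` and
recentered: weights `p - min(p)`, integer shift of the weighted centroid
onto the uv origin, vacated pixels filled with `min(p)`. Per-frame (rather
than per-epoch) recentering follows the stepwise description; both cadences
were evaluated with similar results.

### Known limitation: local minima of the opening loss

The opening loss is piecewise quadratic with genuinely suboptimal local
minima. On this package's synthetic movies the gradient estimator
reproducibly converges (within ~50 epochs, and stably through 5000) to a
slightly *blunter* tip than the truth — masked tip RMSD ~1.5 nm where the
carving estimator reaches ~0 noise-free — and a measured loss barrier
separates that basin from the global minimum. This was verified not to be a
gradient defect (finite-difference agreement), and is insensitive to batch
mode, frame order, boundary padding, recentering cadence, and optimizer-state
handling. Published results for this algorithm report essentially exact
noise-free recovery on an all-atom myosin test case; the basin structure is
data dependent, and users should treat multi-start or data with sharp
isolated features as insurance. The estimator retains its two headline
advantages over carving on noisy data: its accuracy is nearly flat over four
decades of lambda (where carving swings ~2x with thresh), and it can recover
double-tip structure that carving never does — in this package's twin tests
the doubled apex appears in a majority of noise realizations for the
gradient estimator and in none for carving, whose off-origin apex is
irreversibly carved away by noise.

## Pseudo-AFM simulator

Per frame: a uniformly random SO(3) rotation (Gaussian quaternion) about the
center of mass, van-der-Waals sphere rasterization at pixel centers (height
`z_a + sqrt(r_a^2 - d^2)` over covering atoms, max over atoms, clipped at the
stage), dilation with the ground-truth tip, then i.i.d. Gaussian pixel noise.
Defaults follow the standard twin-experiment setup: 20 frames, 30x30 px at
1.5 nm, sigma = 0.3 nm (1.2 nm for the high-noise variant), ground-truth tip
a hemisphere (apex radius 2.5 nm) joined tangentially to a cone frustum
(half angle 10 deg) on a 10x10 grid; double tips are two such fields
`max`-combined 4 px apart along x on a 10x14 grid (apex spacing is not
specified upstream; 6 nm fits the grid and yields a clearly two-peaked
kernel).

**Vertical placement.** The rotated molecule rests on the stage (lowest vdW
sphere tangent to z = 0). Centering the molecule's mass at z = 0 would bury
half of it; resting contact matches the physical setup and the ~7 nm heights
the tip-RMSD mask presumes.

**The stand-in molecule** (`make_blob_atoms`): ~6500 spheres of radius
0.17 nm drawn uniformly from three overlapping ellipsoidal lobes inside an
8 x 5.6 x 4.4 nm envelope — a motor-domain-sized globule at all-atom packing
density, 4.5-8 nm tall depending on orientation. It reproduces the image
features that drive tip reconstruction (sharp rim against the stage, mildly
rough top, flat noisy background) but not any real fold's surface texture;
an all-atom structure read from PDB (`load_pdb_atoms`, chain filtering,
Bondi-style radii H 0.12 / C 0.17 / N 0.155 / O 0.152 / S 0.18 nm) is
preferred whenever available. Green twin-experiment tests therefore establish
correct mechanics and relative algorithm behavior on realistic geometry, not
agreement with any published molecule-specific RMSD value.

Randomness: one root seed spawns independent child streams per frame, so
frame k is bit-reproducible regardless of how many frames are requested.

## Evaluation

* `tip_rmsd`: RMSD over uv pixels where the *truth* tip is shallower than
  -7 nm (about the molecule height — deeper pixels are unconstrainable),
  minimized over all integer translations retaining >= 50% overlap (vacated
  pixels filled with the estimate's minimum). Translation search compensates
  the recentering's boundary drift; it can only lower the zero-shift value.
* `surface_rmsd`: RMSD over xy pixels where the *reconstructed* surface
  exceeds 1 nm (~3 sigma of typical noise; computed on the reconstruction
  per the source's wording, configurable). A very blunt tip can erode an
  entire frame below the mask floor; such frames have no defined value and
  are reported as skipped by the twin-experiment drivers.
* `loocv_mse` / `select_one_se`: leave-one-out CV of `MSE(p)` (one fold per
  frame; SE = sd/sqrt(K) by default, plain sd available) and the
  one-standard-error rule: the largest lambda whose mean CV error is within
  one SE of the minimum (a `slack` flag loosens the bound for the "around
  one SE" reading).
* `tilt_correct`: least-squares plane removal for real scanner data.

## Defaults that matter

| parameter | default | unit | why |
| --- | --- | --- | --- |
| `pixel_size` | 1.5 | nm | standard twin-experiment grid |
| `sigma` | 0.3 | nm | typical HS-AFM pixel noise |
| `thresh` | 4.0 (noisy) | nm | 2-4x sigma x sqrt-of-frames heuristic; MSE knee |
| `lambda` | 1e-7 | - | bottom of the flat accuracy plateau [1e-7, 1e-4] |
| `lr` | 0.1 | nm | stated optimizer step |
| `epochs` | 1000 | - | middle of the stated 100-2000 range |
| `max_sweeps` | 50 | - | carving always converges far earlier |
| tip mask floor | -7.0 | nm | molecule height; deeper tip pixels unconstrained |
| surface mask floor | 1.0 | nm | ~3 sigma; excludes bare stage |
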
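# Methods

`fibriltrace` quantifies the nanoscale geometry of cellulose elementary
fibrils (EFs) in electron tomograms of the wood cell wall, specifically the
thin S1-2 transition layer where the fibril helix flips handedness between
the S1 and S2 layers.  Because no tomograms from that study are publicly
deposited, the package pairs the analysis with a synthetic phantom generator
that plants known fibril geometry; every claim the test suite makes is a
recovery claim against planted ground truth.

## Curve model

A fibril centerline is a parametric space curve in a local frame,

```
C(t) = ( a·cos(ωt + φ) + Σ c_i t^i ,  a·sin(ωt + φ) + Σ d_i t^i ,  t ),
t ∈ [t0, t1]  (nm)
```

mapped to the volume by a rigid pose.  The helicoidal term (amplitude `a`,
angular rate `ω`, phase `φ`) captures winding; the polynomial term captures
deviations from a straight helix.  The curve is parameterized by the local
axial coordinate, not arclength — evaluation stays closed-form and the axial
derivative component is identically 1, so tangents never degenerate.
Arclength comes from adaptive trapezoid quadrature (relative tolerance
1e-4).  The transverse polynomial degree defaults to 2 during fitting
(offset + slope + curvature per transverse axis); degrees up to 5 are
supported.  A low degree is deliberate: a high-order polynomial can imitate
the helix and makes the fit ill-posed.

Distances between curves are sampled: each curve is discretized at ≤0.5 nm
arc spacing and per-sample nearest distances to the other curve's samples
are collected.  The *pair distance* used for nearest-neighbor statistics is
the symmetric mean of the two directional means of per-sample minima, which
is robust to partially overlapping extents; the plain minimum is kept for
contact/bundle detection.  Agreement with closed-form skew-line distances
and dense brute-force sampling is tested to within twice the sampling step.

## Synthetic scenes

The generator emulates what stained cryo-tomograms of the transition layer
show: bright tubes a few nm thick in a darker matrix, in three
architectures.

* **parallel** — a common direction with lattice nearest-neighbor spacing
  (default 10 nm; an optional mid-band override, e.g. 9.7 nm, tightens the
  middle third of the row).
* **crossed** — two families at ±θ (default 45°) to the tangential plane;
  each site hosts one fibril of each family offset slightly along the
  longitudinal axis (the common perpendicular of the two directions), so
  the families pass at near-contact distance as crossing fibrils do.
* **bundled** — a fraction of fibrils (default 40%) in groups of 2–3 placed
  at literal contact, i.e. center separation equal to one tube diameter
  (2 × 1.75 nm).  The bundled count is
  `bundle_size · round(fraction · n / bundle_size)`, so a planted 40% of 10
  fibrils is exactly 4.
* **mixed** — parallel row with alternating ±θ tangential tilt (used for
  the ±6° scenario) and optional bundles.

Tubes render with a raised-cosine radial profile (1 at the centerline, 0 at
1.5 radii; tube radius default 1.75 nm — "a few nm" thick, exact EF diameter
is not settled).  Crossing tubes compose by maximum, not sum, so junctions
saturate.  Noise is seeded additive Gaussian (optional Poisson), with the
generator reporting contrast/σ.  Demo scenes use contrast/σ = 3, a moderate
level at which recovery is reliable after 0.9 nm Gaussian denoising; the
single-fibril benchmark uses contrast/σ = 2.

Limited-tilt anisotropy is modeled as a Fourier wedge mask: single-axis
tilting about L with the beam along N samples, by the central-slice theorem,
all frequencies with `atan2(|k_N|, |k_T|)` inside the tilt range (default
±63°, the acquisition geometry); the rest are zeroed.  The mask is a
projection (idempotent), ±90° is the identity, and the point response
elongates along the beam axis — the hallmark of the missing wedge.  A full
project-then-reconstruct simulator was considered and rejected: the mask is
deterministic, fast, and sufficient for testing anisotropy-sensitivity.
Features of real data that the phantoms do **not** emulate: structured
matrix density (hemicellulose/lignin texture), stain granularity,
contrast-transfer-function oscillations, fibril diameter variability, and
alignment errors.  Passing recovery tests therefore demonstrates the
correctness of the machinery, not performance on real micrographs.

## Fitting

The fit is model-based: no segmentation.  A candidate curve is scored by the
negative mean of trilinearly interpolated density along it (optionally
averaged over a small Gaussian-weighted disk normal to the tangent).  This
cost is linear in intensity and scale-equivariant; samples falling outside
the volume contribute the median (background) intensity so curves are not
rewarded for escaping the box.  The exact functional is this package's own
choice, validated by the recovery experiments.

**Seeding.**  Transverse slices every 3 voxels are scanned for local
intensity maxima (threshold: background + 35% of the smoothed peak
contrast), which are linked into chains by nearest-neighbor tracking (link
radius 5 voxels, one missed slice tolerated — crossings can hide a peak for
a slice).  The slicing axis is chosen automatically by total chain support,
with fallback to other axes.  Chains spanning at least half the slices are
fitted by least-squares lines; each extent is then grown along the line
while the smoothed density stays above threshold (brief dips tolerated), and
seeds shorter than 10 nm are discarded as noise tracks.

**Optimization.**  A global-best particle swarm (30 particles, 60
iterations, constriction-type coefficients w = 0.7298, c1 = c2 = 1.49618)
explores a bounded box of deviations from the seed — transverse offsets
±4 nm, slopes ±0.45, curvature ±0.008 nm⁻¹, optionally helix parameters —
followed by a bounded Nelder–Mead polish.  Parameters are additive on the
seed's own coefficients, and the parameter interval is re-centered about its
midpoint first so slope terms pivot at the curve's middle.  The returned
cost never exceeds the swarm cost, the best-cost trace is non-increasing,
and on a 3-parameter straight-line restriction the optimizer matches an
exhaustive grid search within grid resolution.

**Multi-fibril extraction.**  Greedy peeling: fit the best seed, suppress
the fitted tube with a flat-top mask (full suppression inside the mask
radius, cosine roll-off to 1.5 radii; radius 2.7 nm covers the whole
rendered tube footprint), re-seed, repeat.  A fit is accepted when its mean
density exceeds background by at least 35% of the robust peak contrast
(99.9th percentile − median); several ranked seeds are tried per round so a
single weak candidate cannot end the extraction.  Afterwards every accepted
fit is finalized against the *unmasked* volume: its extent is re-derived
from its own density support (extend + trim), a small-box simplex polish
removes the bias that masking neighbors induces (important for bundles at
contact distance), fits without independent support on the original volume
are dropped, and near-duplicates (pair distance ≤ half the mask radius) are
collapsed keeping the better cost.

## Metrics

Orientation is measured on the mean unit tangent, sign-canonicalized to a
positive tangential component.  The tangential-plane angle is signed by the
side of the plane and lies in (−90°, 90°]; the longitudinal-axis angle lies
in [0°, 180°) so that symmetric oscillations about 90° (perpendicular
fibrils) keep their spread instead of folding; its SD switches to circular
statistics when the linear spread exceeds 30°.  Bundles are connected
components of the sustained-near-contact graph: an edge requires the
per-sample distance profile to stay within the contact threshold (default
2 × tube radius + 1 voxel = 4.4 nm) for at least 30% of samples in the more
favorable direction — crossing fibrils touch only briefly and are thus not
bundled.  Grid maps aggregate per-curve values over 40.5 nm tangential-plane
cells by curve midpoint; count-weighted cell means equal the global means
exactly.  Curves shorter than 15 nm carry a low-confidence flag on their
angle estimates, mirroring the difficulty of judging axis angles in very
thin sections.  Recovery against ground truth uses Hungarian assignment on
the pair-distance matrix with a 3 nm match radius; per-match centerline RMSD
pools both directional per-sample minima.

## Problem sizes and determinism

Phantom scenes use 8–10 fibrils in boxes of roughly 50–110 nm per side at
0.9 nm/voxel (the binned acquisition pixel), matching the density of the
analyzed subvolumes while keeping a full scenario run to a few seconds.
Three recorded tiling geometries (45-voxel windows, 50% overlap) reproduce
the 13-, 44- and 261-subvolume surveys of the three analyzed tomograms.
All randomness flows from one integer seed through `numpy` generators;
identical configuration and seed give byte-identical CSV outputs.  Across a
sweep of seeds the three demo scenarios recover every planted fibril with no
spurious fits in the large majority of runs; the residual failure mode is a
fibril of a crossing pair whose fit lands just past the match radius under
an unlucky noise realization.

## Known limitations

* The cost functional, optimizer hyperparameters and acceptance rule stand
  in for procedure details that the source study does not publish; they are
  validated only against phantoms.
* Greedy peeling is sequential: it cannot revise an early fit in light of a
  later one (no joint optimization across fibrils).
* The wedge simulator degrades volumes but the fitting stages are not
  wedge-aware; heavy anisotropy will bias radial (N) coordinates.
* Helix fitting is available (`fit_helix=True`) but off by default: over
  subvolume-scale windows the planted geometries are nearly straight, and
  the helix adds three poorly constrained parameters.
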
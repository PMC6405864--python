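# fibriltrace

Model-based tracing and quantification of cellulose elementary fibrils (EFs)
in electron tomograms of the wood cell wall.

In the S1-2 transition layer — the thin zone where the fibril helix flips
between the S1 and S2 secondary-wall layers — EFs are a few nanometers
thick and too tightly packed in matrix polymers for manual segmentation.
`fibriltrace` instead fits each fibril's centerline directly to the
tomographic density with a parametric space curve

```
C(t) = ( a·cos(ωt + φ) + Σ cᵢtⁱ ,  a·sin(ωt + φ) + Σ dᵢtⁱ ,  t )
```

(a helicoidal term plus a polynomial deviation, carried by a rigid pose),
minimizing the negative mean density along the curve with a particle-swarm
global search refined by a Nelder–Mead simplex.  Fibrils are extracted one
by one: fit, softly mask the fitted tube, re-seed, repeat.  From the fitted
curve set the package computes the layer's quantitative descriptors:
nearest-neighbor distances d_NN, signed angles to the tangential plane,
angles to the longitudinal axis, bundle membership (sustained near-contact
components), and spatial grid maps.

Because no tomograms of this layer are publicly deposited, the package
ships a synthetic phantom generator that renders tube phantoms with known
geometry — parallel lattices, ±45° crossed families, bundles at contact
distance — with seeded noise and an optional missing-wedge (limited tilt,
±63°) degradation.  All validation is recovery of planted ground truth.

## Worked example

```python
from fibriltrace import (make_scene, render_scene, apply_noise,
                         gaussian_denoise, fit_all, FitConfig,
                         compute_metrics, recovery_report)

scene = make_scene("bundled", n_fibrils=10, spacing_nm=10.0,
                   bundle_fraction=0.4, bundle_size=2,
                   box_nm=(110, 54, 18), noise_sigma=1/3, seed=1)
volume = gaussian_denoise(apply_noise(render_scene(scene, voxel_size_nm=0.9),
                                      scene), 0.9)
fits = fit_all(volume, FitConfig(rng_seed=1))
metrics = compute_metrics([f.curve for f in fits])
print(len(fits), round(metrics.summary["mean_nn_distance_nm"], 2),
      metrics.summary["bundle_fraction_percent"])
report = recovery_report(scene.truth_curves, [f.curve for f in fits])
print(report["n_matched"], report["n_missed"], round(max(report["rmsd_nm"]), 2))
```

prints

```
10 7.38 40.0
10 0 0.39
```

All 10 planted fibrils were recovered with no misses and a worst centerline
deviation of 0.39 nm (under half a voxel).  The mean nearest-neighbor
distance of 7.38 nm mixes the 10 nm lattice spacing of free fibrils with
the 3.5 nm contact distance of bundled pairs, and the bundle fraction of
40% equals the planted value exactly.

The same pipeline runs from the shell:

```
fibriltrace demo --scenario crossed --out run/ --seed 1
fibriltrace run --config run.yaml
fibriltrace prep --in vol.mrc --sigma-nm 1.0 --slab-nm 20 \
                 --grid-side 40.5 --grid-overlap 0.5 --out prep/
```

`demo` ships three scene archetypes: `crossed` (two families at ±45° to the
tangential plane), `bundled` (40% of fibrils in bundles of two, 10 nm
lattice), and `tilted` (±6° tangential tilt, spacing tightening to 9.7 nm
mid-band).  A run directory contains the rendered/loaded volumes (MRC), the
ground truth and fits (JSON), per-curve metrics (CSV), summary and recovery
reports (JSON), grid-map images (PNG), and a manifest with content hashes.

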
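"""Phantom tomogram generation with known fibril geometry.

Scenes emulate the architecture of the spruce S1-2 transition layer as seen
in stained cryo-electron tomograms: tube-like high-density fibrils a few nm
thick inside a lower-density matrix, arranged parallel, crossed at +/-45° to
the tangential plane, or partly gathered into bundles of 2-3 at near-contact
distance, within thin (< 20-150 nm) sections.  Ground-truth centerlines are
kept with every scene so that recovery tests can compare fits against truth.

Scene coordinates: component order follows the volume's data axes with the
default tagging (L, T, N).  Fibrils nominally run along T (perpendicular to
the longitudinal axis L, as in the transition layer); the tangential tilt
rotates them out of the L-T plane toward N, and the longitudinal deviation
rotates them toward L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .curve_model import SpaceCurve, line_curve, sample_points
from .volume_io import DensityVolume

# direction components are (L, T, N); tau = tangential-plane angle,
# delta = deviation of the longitudinal angle from 90°
def _direction(tangential_deg: float, longitudinal_deg: float = 90.0) -> np.ndarray:
    tau = np.deg2rad(tangential_deg)
    delta = np.deg2rad(90.0 - longitudinal_deg)
    return np.array([np.sin(delta),
                     np.cos(delta) * np.cos(tau),
                     np.cos(delta) * np.sin(tau)])


@dataclass
class SyntheticScene:
    """Ground-truth curves plus every parameter needed to render them."""

    truth_curves: list
    box_nm: tuple
    tube_radius_nm: float = 1.75
    fibril_intensity: float = 1.0
    matrix_intensity: float = 0.0
    noise_sigma: float = 0.0
    poisson_scaling: float | None = None
    wedge_model: dict | None = None        # {tilt_min_deg, tilt_max_deg, tilt_step_deg}
    rng_seed: int = 0
    arrangement: str = "parallel"
    bundle_ids: dict = field(default_factory=dict)   # curve index -> bundle id

    def __post_init__(self):
        if not self.fibril_intensity > self.matrix_intensity:
            raise ValueError("fibril_intensity must exceed matrix_intensity")
        box = np.asarray(self.box_nm, dtype=float)
        for i, c in enumerate(self.truth_curves):
            pts = sample_points(c, 1.0)
            if (pts < -1e-6).any() or (pts > box + 1e-6).any():
                raise ValueError(f"truth curve {i} leaves the scene box")

    @property
    def contrast(self) -> float:
        return self.fibril_intensity - self.matrix_intensity


def make_scene(arrangement: str = "parallel", n_fibrils: int = 9,
               spacing_nm: float = 10.0, angles: dict | None = None,
               bundle_fraction: float = 0.0, bundle_size: int = 2,
               seed: int = 0, box_nm: tuple = (100.0, 54.0, 18.0),
               tube_radius_nm: float = 1.75, noise_sigma: float = 0.0,
               wedge_model: dict | None = None,
               spacing_jitter_nm: float = 0.0, angle_jitter_deg: dict | None = None,
               bundle_offset_nm: float | None = None,
               midband_spacing_nm: float | None = None) -> SyntheticScene:
    """Build a scene with one of the layer's architectures.

    parallel  : common direction, fibrils on a line along L with nearest-
                neighbor spacing ``spacing_nm`` (optionally tightened to
                ``midband_spacing_nm`` in the middle third of the row).
    crossed   : two interleaved families with tangential angles +theta and
                -theta (theta from ``angles["tangential_deg"]``, default 45).
    bundled   : a ``bundle_fraction`` of fibrils placed in groups of
                ``bundle_size`` at near-contact offset; the bundled count is
                ``bundle_size * round(bundle_fraction * n / bundle_size)``.
    mixed     : parallel row with both bundles and alternating +/-tilt.

    Jitter (spacing and angle) is Gaussian with the stated SDs, seeded.
    """
    if n_fibrils < 1:
        raise ValueError("n_fibrils must be >= 1")
    if not 0.0 <= bundle_fraction <= 1.0:
        raise ValueError("bundle_fraction must be in [0, 1]")
    if spacing_nm <= 2 * tube_radius_nm:
        raise ValueError("spacing must exceed the fibril diameter")
    angles = dict(angles or {})
    tau = float(angles.get("tangential_deg", 0.0))
    lon = float(angles.get("longitudinal_deg", 90.0))
    jit = dict(angle_jitter_deg or {})
    rng = np.random.default_rng(seed)
    box = np.asarray(box_nm, dtype=float)
    margin = 2.0 * tube_radius_nm

    def row_positions(n, extra=None):
        """Centers along L with the requested nn spacing (midband override).
        ``extra[i]`` widens the gap after site i (room for a bundle)."""
        pos, x = [], margin + tube_radius_nm
        for i in range(n):
            pos.append(x)
            step = spacing_nm
            if midband_spacing_nm is not None and n >= 3:
                third = n // 3
                if third <= i < n - third:   # gaps inside the middle band
                    step = midband_spacing_nm
            x += step + (extra[i] if extra is not None else 0.0)
        pos = np.asarray(pos)
        if pos[-1] + margin + tube_radius_nm > box[0]:
            raise ValueError("impossible packing: spacing x count exceeds box")
        return pos

    curves, bundle_ids = [], {}

    def add_curve(center_L, center_N, tau_i, lon_i):
        d = _direction(tau_i + rng.normal(0, jit.get("tangential_deg", 0.0)),
                       lon_i + rng.normal(0, jit.get("longitudinal_deg", 0.0)))
        cL = center_L + rng.normal(0, spacing_jitter_nm)
        center = np.array([cL, box[1] / 2.0, center_N])
        # clip t so the segment stays inside the box with a tube-radius margin
        t_hi = np.inf
        for k in range(3):
            if abs(d[k]) > 1e-9:
                t_hi = min(t_hi, (box[k] - margin - center[k]) / d[k] if d[k] > 0
                           else (margin - center[k]) / d[k])
        t_lo = -np.inf
        for k in range(3):
            if abs(d[k]) > 1e-9:
                t_lo = max(t_lo, (margin - center[k]) / d[k] if d[k] > 0
                           else (box[k] - margin - center[k]) / d[k])
        curves.append(line_curve(center, d, (t_lo, t_hi)))

    midN = box[2] / 2.0
    if arrangement == "parallel":
        for x in row_positions(n_fibrils):
            add_curve(x, midN, tau, lon)
    elif arrangement == "crossed":
        # each site hosts a +theta / -theta pair; L is the common perpendicular
        # of the two line directions, so a small L offset makes the families
        # pass each other at near-contact distance
        theta = float(angles.get("tangential_deg", 45.0))
        cross_gap = 2 * tube_radius_nm + 0.5
        n_sites = (n_fibrils + 1) // 2
        for i, x in enumerate(row_positions(n_sites)):
            add_curve(x - cross_gap / 2.0, midN, theta, lon)
            if 2 * i + 1 < n_fibrils:
                add_curve(x + cross_gap / 2.0, midN, -theta, lon)
    elif arrangement in ("bundled", "mixed"):
        if bundle_offset_nm is None:
            # literal contact: touching tubes, center separation = diameter
            bundle_offset_nm = 2 * tube_radius_nm
        n_bundles = int(round(bundle_fraction * n_fibrils / bundle_size))
        n_bundled = min(n_fibrils, n_bundles * bundle_size)
        n_bundles = n_bundled // bundle_size if bundle_size else 0
        n_sites = n_fibrils - n_bundled + n_bundles
        extent = (bundle_size - 1) * bundle_offset_nm
        extra = [extent if s < n_bundles else 0.0 for s in range(n_sites)]
        sites = row_positions(n_sites, extra=extra)
        idx = 0
        for s, x in enumerate(sites):
            tau_s = tau if arrangement == "bundled" else (tau if s % 2 == 0 else -tau)
            if s < n_bundles:
                for m in range(bundle_size):
                    add_curve(x + m * bundle_offset_nm, midN, tau_s, lon)
                    bundle_ids[idx] = s
                    idx += 1
            else:
                add_curve(x, midN, tau_s, lon)
                idx += 1
    else:
        raise ValueError(f"unknown arrangement {arrangement!r}")

    return SyntheticScene(truth_curves=curves, box_nm=tuple(box),
                          tube_radius_nm=tube_radius_nm, noise_sigma=noise_sigma,
                          wedge_model=wedge_model, rng_seed=seed,
                          arrangement=arrangement, bundle_ids=bundle_ids)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def tube_profile(u: np.ndarray) -> np.ndarray:
    """Raised-cosine cross-section: 1 at the centerline, 0 beyond 1.5 radii."""
    u = np.asarray(u, dtype=float)
    out = 0.5 * (1.0 + np.cos(np.pi * np.minimum(u, 1.5) / 1.5))
    return np.where(u >= 1.5, 0.0, out)


def render_scene(scene: SyntheticScene, shape_vox: tuple | None = None,
                 voxel_size_nm: float = 0.9) -> DensityVolume:
    """Rasterize the scene: soft tubes of ``tube_radius_nm`` on the matrix.

    Voxel intensity is ``matrix + contrast * profile(d / r)`` where ``d`` is
    the distance to the nearest centerline (maximum over fibrils, so crossing
    tubes saturate rather than add).  Deterministic for fixed inputs.
    """
    if voxel_size_nm <= 0:
        raise ValueError("voxel size must be positive")
    if shape_vox is None:
        shape_vox = tuple(int(round(b / voxel_size_nm)) for b in scene.box_nm)
    grid = np.indices(shape_vox, dtype=float).reshape(3, -1).T * voxel_size_nm
    best = np.zeros(len(grid))
    reach = 1.5 * scene.tube_radius_nm
    for curve in scene.truth_curves:
        pts = sample_points(curve, 0.3 * voxel_size_nm)
        d, _ = cKDTree(pts).query(grid, distance_upper_bound=reach + voxel_size_nm)
        prof = tube_profile(np.where(np.isinf(d), np.inf, d) / scene.tube_radius_nm)
        np.maximum(best, prof, out=best)
    data = scene.matrix_intensity + scene.contrast * best
    return DensityVolume(data=data.reshape(shape_vox).astype(np.float32),
                         voxel_size_nm=(voxel_size_nm,) * 3, axes=("L", "T", "N"),
                         meta={"scene_seed": scene.rng_seed})


def apply_noise(volume: DensityVolume, scene: SyntheticScene) -> DensityVolume:
    """Additive Gaussian (and optional Poisson) noise, seeded from the scene.

    Attaches an SNR report ``meta["snr"] = contrast / sigma`` when sigma > 0.
    """
    if scene.noise_sigma == 0 and scene.poisson_scaling is None:
        return volume
    rng = np.random.default_rng(np.random.SeedSequence([scene.rng_seed, 7919]))
    data = np.asarray(volume.data, dtype=float)
    if scene.poisson_scaling:
        lam = np.clip(data, 0, None) * scene.poisson_scaling
        data = rng.poisson(lam) / scene.poisson_scaling
    if scene.noise_sigma > 0:
        data = data + rng.normal(0.0, scene.noise_sigma, size=data.shape)
    out = volume.with_data(data.astype(np.float32))
    if scene.noise_sigma > 0:
        out.meta["snr"] = scene.contrast / scene.noise_sigma
    return out


def apply_missing_wedge(volume: DensityVolume, wedge: dict) -> DensityVolume:
    """Limited-angle degradation as a Fourier wedge mask.

    Single-axis tilting about L with the beam along N samples, by the central
    slice theorem, all spatial frequencies whose (k_N, k_T) direction lies
    within the tilt range; frequencies closer to the beam axis than the
    maximum tilt are lost.  Zeroing that wedge reproduces the hallmark
    elongation of features along the beam (N) direction.  The mask is a
    projection, hence idempotent; a +/-90° range changes nothing.
    """
    tmin, tmax = float(wedge["tilt_min_deg"]), float(wedge["tilt_max_deg"])
    if tmin >= tmax:
        raise ValueError("degenerate wedge: tilt_min must be < tilt_max")
    half = max(abs(tmin), abs(tmax))
    if half >= 90.0:
        return volume
    axN = volume.axis_index("N")
    axT = volume.axis_index("T")
    data = np.asarray(volume.data, dtype=float)
    F = np.fft.fftn(data)
    kN = np.fft.fftfreq(data.shape[axN])
    kT = np.fft.fftfreq(data.shape[axT])
    shapeN = [1, 1, 1]; shapeN[axN] = -1
    shapeT = [1, 1, 1]; shapeT[axT] = -1
    ang = np.degrees(np.arctan2(np.abs(kN.reshape(shapeN)),
                                np.abs(kT.reshape(shapeT))))
    keep = ang <= half
    out = np.real(np.fft.ifftn(F * keep))
    res = volume.with_data(out.astype(np.float32))
    res.meta["wedge"] = dict(wedge)
    return res
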
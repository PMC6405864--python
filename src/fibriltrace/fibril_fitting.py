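"""Fitting space curves to tomographic density.

The fit is model-based rather than segmentation-based: a candidate centerline
is scored by the (negative) mean density interpolated along it, a particle
swarm explores a bounded parameter box around an initial straight-line seed,
and a Nelder-Mead simplex polishes the swarm's best point.  Multiple fibrils
in one subvolume are extracted greedily: fit, softly mask out the fitted
tube, re-seed, repeat.

Fit parameters live in the seed's local frame (the seed's axis is local z):
transverse offsets, slopes, optional higher polynomial terms and optional
helix amplitude/pitch/phase.  The parameter vector is

    [x0, y0, sx, sy, (c2x, c2y, ..., cDx, cDy), (a, w, phi)]
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize

from .curve_model import SpaceCurve, evaluate, frame_from_axis, pair_distance, \
    recenter_parameter, sample_points, tangent
from .synthetic_scenes import tube_profile
from .volume_io import DensityVolume


@dataclass
class FitConfig:
    """Knobs of the optimizer and the extraction loop (lengths in nm)."""

    n_particles: int = 30
    pso_iterations: int = 60
    inertia: float = 0.7298            # constriction-factor defaults
    cognitive: float = 1.49618
    social: float = 1.49618
    simplex_tol: float = 1e-4
    n_cost_samples: int = 41
    tube_sigma_nm: float = 1.2         # Gaussian width of the optional disk average
    disk_samples: int = 0              # 0 = centerline samples only
    poly_degree: int = 2               # transverse polynomial degree (1-5)
    fit_helix: bool = False
    offset_bound_nm: float = 4.0
    slope_bound: float = 0.45          # ~24 degrees about the seed axis
    curvature_bound: float = 0.008     # bound on t^2 coefficients (1/nm)
    helix_radius_bound_nm: float = 1.5
    helix_pitch_bound: float = 0.5     # rad/nm
    max_fibrils_per_subvolume: int = 20
    mask_radius_nm: float = 2.7
    accept_threshold: float = 0.35     # fraction of the robust peak contrast
    seed_axis: str = "auto"            # anatomical tag, or "auto"
    seed_slice_step_vox: int = 3
    seed_link_radius_vox: float = 5.0
    seed_min_span: float = 0.5         # chain must span this fraction of slices
    seed_min_length_nm: float = 10.0   # discard shorter seeds (noise blobs)
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_particles, self.pso_iterations, self.n_cost_samples) < 1:
            raise ValueError("counts must be >= 1")
        if not 1 <= self.poly_degree <= 5:
            raise ValueError("poly_degree must be in 1..5")

    def n_params(self) -> int:
        n = 4 + 2 * (self.poly_degree - 1)
        return n + 3 if self.fit_helix else n

    def param_bounds(self) -> np.ndarray:
        """(n, 2) box bounds for the relative parameter vector."""
        lo, hi = [], []
        for b in (self.offset_bound_nm, self.offset_bound_nm,
                  self.slope_bound, self.slope_bound):
            lo.append(-b); hi.append(b)
        for d in range(2, self.poly_degree + 1):
            b = self.curvature_bound / (4.0 ** (d - 2))
            lo += [-b, -b]; hi += [b, b]
        if self.fit_helix:
            lo += [0.0, -self.helix_pitch_bound, -np.pi]
            hi += [self.helix_radius_bound_nm, self.helix_pitch_bound, np.pi]
        return np.column_stack([lo, hi]).astype(float)


@dataclass
class FitResult:
    """One fitted fibril: the curve, its cost and the optimizer trace."""

    curve: SpaceCurve
    cost: float
    pso_cost: float
    history: list
    converged: bool
    subvolume_label: str = ""
    provenance: dict = field(default_factory=dict)


def params_to_curve(p: np.ndarray, seed: SpaceCurve, cfg: FitConfig) -> SpaceCurve:
    """Relative parameter vector -> SpaceCurve in the seed's frame.

    Parameters are ADDITIVE deviations from the seed's own coefficients, so a
    previously fitted curve can serve as the seed of a local refinement."""
    p = np.asarray(p, dtype=float)
    D = cfg.poly_degree
    base_x = np.zeros(D + 1)
    base_y = np.zeros(D + 1)
    base_x[:len(seed.poly_x)] = seed.poly_x[:D + 1]
    base_y[:len(seed.poly_y)] = seed.poly_y[:D + 1]
    delta_x = [p[0], p[2]] + [p[4 + 2 * (d - 2)] for d in range(2, D + 1)]
    delta_y = [p[1], p[3]] + [p[5 + 2 * (d - 2)] for d in range(2, D + 1)]
    if cfg.fit_helix:
        a = max(0.0, seed.helix_radius_nm + p[-3])
        w = seed.helix_pitch_rad_per_nm + p[-2]
        phi = seed.helix_phase_rad + p[-1]
    else:
        a, w, phi = (seed.helix_radius_nm, seed.helix_pitch_rad_per_nm,
                     seed.helix_phase_rad)
    return replace(seed, poly_x=tuple(base_x + delta_x),
                   poly_y=tuple(base_y + delta_y),
                   helix_radius_nm=float(a), helix_pitch_rad_per_nm=float(w),
                   helix_phase_rad=float(phi))


# ---------------------------------------------------------------------------
# Cost
# ---------------------------------------------------------------------------

class _CostContext:
    """Caches the interpolation-ready array and robust background stats."""

    def __init__(self, volume: DensityVolume):
        self.volume = volume
        self.data = np.asarray(volume.data, dtype=float)
        self.voxel = np.asarray(volume.voxel_size_nm)
        self.origin = np.asarray(volume.origin_nm)
        self.background = float(np.median(self.data))
        mad = float(np.median(np.abs(self.data - self.background)))
        self.noise_sd = 1.4826 * mad
        # robust peak contrast: a fitted curve must capture a substantial
        # fraction of this to be accepted as a fibril
        self.scale = max(float(np.percentile(self.data, 99.9)) - self.background,
                         1e-12)

    def sample(self, points_nm: np.ndarray) -> np.ndarray:
        """Trilinear interpolation; out-of-volume samples get the background."""
        idx = (points_nm - self.origin) / self.voxel
        vals = ndimage.map_coordinates(self.data, idx.T, order=1,
                                       mode="constant", cval=np.nan)
        return np.where(np.isnan(vals), self.background, vals)


def curve_cost(curve: SpaceCurve, volume: DensityVolume | _CostContext,
               cfg: FitConfig) -> float:
    """Negative mean density along the curve (lower = denser = better).

    With ``disk_samples > 0`` each centerline sample is replaced by a
    Gaussian-weighted average over a small disk normal to the local tangent
    (ring radius ``tube_sigma_nm``).  Linear in the volume intensities.
    """
    ctx = volume if isinstance(volume, _CostContext) else _CostContext(volume)
    t = np.linspace(*curve.t_range, cfg.n_cost_samples)
    pts = evaluate(curve, t)
    inside = ((pts - ctx.origin) / ctx.voxel >= -0.5).all(axis=1) & \
             ((pts - ctx.origin) / ctx.voxel <= np.array(ctx.data.shape) - 0.5).all(axis=1)
    if not inside.any():
        raise ValueError("curve lies entirely outside the volume")
    if cfg.disk_samples <= 0:
        return float(-ctx.sample(pts).mean())
    tans = tangent(curve, t)
    ref = np.where(np.abs(tans[:, [0]]) < 0.9, [[1.0, 0, 0]], [[0, 1.0, 0]])
    n1 = np.cross(tans, ref)
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tans, n1)
    vals = ctx.sample(pts)
    wsum = np.ones_like(vals)
    wring = np.exp(-0.5)
    for k in range(cfg.disk_samples):
        ang = 2 * np.pi * k / cfg.disk_samples
        off = cfg.tube_sigma_nm * (np.cos(ang) * n1 + np.sin(ang) * n2)
        vals = vals + wring * ctx.sample(pts + off)
        wsum += wring
    return float(-(vals / wsum).mean())


# ---------------------------------------------------------------------------
# Optimizer engine: PSO + simplex polish
# ---------------------------------------------------------------------------

def pso_minimize(fun, bounds: np.ndarray, cfg: FitConfig, rng,
                 x0: np.ndarray | None = None):
    """Global-best particle swarm over a box.  Returns (x, cost, history)."""
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    n, d = cfg.n_particles, len(lo)
    x = lo + rng.uniform(size=(n, d)) * span
    if x0 is not None:
        x[0] = np.clip(x0, lo, hi)
    v = rng.uniform(-0.25, 0.25, size=(n, d)) * span
    cost = np.array([fun(xi) for xi in x])
    pbest_x, pbest_c = x.copy(), cost.copy()
    g = int(np.argmin(cost))
    gbest_x, gbest_c = x[g].copy(), float(cost[g])
    history = [gbest_c]
    vmax = 0.5 * span
    for _ in range(cfg.pso_iterations):
        r1 = rng.uniform(size=(n, d))
        r2 = rng.uniform(size=(n, d))
        v = (cfg.inertia * v + cfg.cognitive * r1 * (pbest_x - x)
             + cfg.social * r2 * (gbest_x - x))
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, lo, hi)
        cost = np.array([fun(xi) for xi in x])
        better = cost < pbest_c
        pbest_x[better], pbest_c[better] = x[better], cost[better]
        g = int(np.argmin(pbest_c))
        if pbest_c[g] < gbest_c:
            gbest_x, gbest_c = pbest_x[g].copy(), float(pbest_c[g])
        history.append(gbest_c)
    return gbest_x, gbest_c, history


def refine_simplex(fun, x0: np.ndarray, bounds: np.ndarray, tol: float):
    """Nelder-Mead polish inside the box; never returns a worse point.

    The initial simplex spans 5% of each bound range (the default simplex is
    degenerate near a zero start and would terminate without moving)."""
    x0 = np.asarray(x0, dtype=float)
    span = bounds[:, 1] - bounds[:, 0]
    sim = np.vstack([x0, x0 + np.diag(0.05 * span)])
    sim = np.clip(sim, bounds[:, 0], bounds[:, 1])
    res = optimize.minimize(fun, x0, method="Nelder-Mead",
                            bounds=[tuple(b) for b in bounds],
                            options={"xatol": tol, "fatol": tol, "maxiter": 800,
                                     "initial_simplex": sim})
    f0 = fun(x0)
    if res.fun <= f0:
        return np.asarray(res.x), float(res.fun)
    return np.asarray(x0), float(f0)


def optimize_box(fun, bounds: np.ndarray, cfg: FitConfig, rng_key: int = 0,
                 x0: np.ndarray | None = None) -> dict:
    """Full PSO + simplex pipeline over a bounded box (generic engine)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, rng_key]))
    gx, gc, history = pso_minimize(fun, bounds, cfg, rng, x0=x0)
    fx, fc = refine_simplex(fun, gx, bounds, cfg.simplex_tol)
    history.append(fc)
    return {"x": fx, "cost": fc, "pso_cost": gc, "history": history}


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def _chains_along_axis(data: np.ndarray, axis: int, cfg: FitConfig,
                       threshold: float):
    """Link transverse-slice intensity peaks into chains along one axis."""
    from skimage.feature import peak_local_max
    n_slices = data.shape[axis]
    slice_pos = list(range(0, n_slices, cfg.seed_slice_step_vox))
    chains = []          # each: list of (slice_index, u, v)
    active = []          # entries: [chain, consecutive_misses]
    for s in slice_pos:
        sl = np.take(data, s, axis=axis)
        peaks = peak_local_max(sl, min_distance=2, threshold_abs=threshold)
        used = set()
        nxt = []
        for chain, misses in active:
            _, pu, pv = chain[-1]
            # one missed slice is tolerated, so search within a widened radius
            best, bestd = None, cfg.seed_link_radius_vox * (1 + misses)
            for i, (u, v) in enumerate(peaks):
                if i in used:
                    continue
                dd = np.hypot(u - pu, v - pv)
                if dd <= bestd:
                    best, bestd = i, dd
            if best is not None:
                used.add(best)
                chain.append((s, float(peaks[best][0]), float(peaks[best][1])))
                nxt.append([chain, 0])
            elif misses == 0:     # crossing fibrils can hide a peak for a slice
                nxt.append([chain, 1])
            else:
                chains.append(chain)
        for i, (u, v) in enumerate(peaks):
            if i not in used:
                nxt.append([[(s, float(u), float(v))], 0])
        active = nxt
    chains.extend(chain for chain, _ in active)
    min_len = max(3, int(cfg.seed_min_span * len(slice_pos)))
    return [c for c in chains if len(c) >= min_len]


def seed_candidates(volume: DensityVolume, cfg: FitConfig):
    """Straight-line seeds from linked density maxima in transverse slices.

    Slices are taken along the configured axis (or, with ``seed_axis="auto"``,
    along whichever axis yields the most linked chain points).  Each chain is
    least-squares fitted by a line; seeds are ranked by their cost (densest
    first).  A featureless volume yields an empty list.
    """
    data = ndimage.gaussian_filter(np.asarray(volume.data, dtype=float), 1.0)
    bg = float(np.median(data))
    peak = float(data.max())
    if peak - bg <= 1e-12:
        return []
    threshold = bg + 0.35 * (peak - bg)
    if cfg.seed_axis == "auto":
        cands = list(range(3))
    else:
        cands = [volume.axis_index(cfg.seed_axis)]
    scored = sorted(((sum(map(len, ch)), ax, ch) for ax, ch in
                     ((ax, _chains_along_axis(data, ax, cfg, threshold))
                      for ax in cands)), reverse=True)
    voxel = np.asarray(volume.voxel_size_nm)
    origin = np.asarray(volume.origin_nm)
    ctx = _CostContext(volume)
    shape = np.array(data.shape)

    def extend_extent(centroid, direction, t_lo, t_hi):
        """Grow the interval along the line while the smoothed density stays
        above the seed threshold (chains can under-cover a fibril when its
        flanks were dimmed by masking or noise)."""
        step = 0.5 * float(voxel.min())
        for sign in (+1, -1):
            t = t_hi if sign > 0 else t_lo
            good, misses = t, 0
            while misses <= 3:        # ride over brief noise dips
                t = t + sign * step
                p = centroid + t * direction
                idx = (p - origin) / voxel
                if (idx < 0).any() or (idx > shape - 1).any():
                    break
                val = ndimage.map_coordinates(data, idx[:, None], order=1)[0]
                if val >= threshold:
                    good, misses = t, 0
                else:
                    misses += 1
            if sign > 0:
                t_hi = max(t_hi, good)
            else:
                t_lo = min(t_lo, good)
        return t_lo, t_hi

    def seeds_for_axis(axis, chains):
        other = [a for a in range(3) if a != axis]
        seeds = []
        for chain in chains:
            arr = np.asarray(chain, dtype=float)       # (n, 3): slice, u, v
            pts_vox = np.zeros((len(arr), 3))
            pts_vox[:, axis] = arr[:, 0]
            pts_vox[:, other[0]] = arr[:, 1]
            pts_vox[:, other[1]] = arr[:, 2]
            pts_nm = pts_vox * voxel + origin
            centroid = pts_nm.mean(axis=0)
            # principal direction via least squares on the slice coordinate
            s = pts_nm[:, axis] - centroid[axis]
            direction = np.zeros(3)
            direction[axis] = 1.0
            denom = (s ** 2).sum()
            for a in other:
                direction[a] = ((pts_nm[:, a] - centroid[a]) * s).sum() / denom \
                    if denom else 0.0
            direction /= np.linalg.norm(direction)
            proj = (pts_nm - centroid) @ direction
            t_lo, t_hi = extend_extent(centroid, direction,
                                       float(proj.min()), float(proj.max()))
            if t_hi - t_lo < cfg.seed_min_length_nm:
                continue
            seeds.append(recenter_parameter(
                SpaceCurve(rotation=frame_from_axis(direction),
                           translation=centroid, t_range=(t_lo, t_hi))))
        return seeds

    # best-scoring axis first, but fall back: an axis can win on raw chain
    # points yet yield only seeds too short to keep
    for _score, axis, chains in scored:
        seeds = seeds_for_axis(axis, chains)
        if seeds:
            seeds.sort(key=lambda c: curve_cost(c, ctx, cfg))
            return seeds[: 2 * cfg.max_fibrils_per_subvolume]
    return []


# ---------------------------------------------------------------------------
# Single- and multi-fibril fitting
# ---------------------------------------------------------------------------

def fit_single(volume: DensityVolume, seed: SpaceCurve, cfg: FitConfig,
               rng_key: int = 0, label: str = "") -> FitResult:
    """PSO around a straight-line seed, then simplex refinement.

    The swarm explores the box ``cfg.param_bounds()`` of deviations from the
    seed; the returned cost is never above the swarm-stage cost and the best
    cost trace is non-increasing.
    """
    ctx = _CostContext(volume)
    bounds = cfg.param_bounds()

    def fun(p):
        try:
            return curve_cost(params_to_curve(p, seed, cfg), ctx, cfg)
        except ValueError:            # particle pushed the curve out of the box
            return -ctx.background

    out = optimize_box(fun, bounds, cfg, rng_key=rng_key,
                       x0=np.zeros(cfg.n_params()))
    curve = params_to_curve(out["x"], seed, cfg)
    signal = -out["cost"] - ctx.background
    converged = bool(signal > cfg.accept_threshold * ctx.scale)
    return FitResult(curve=curve, cost=out["cost"], pso_cost=out["pso_cost"],
                     history=out["history"], converged=converged,
                     subvolume_label=label,
                     provenance={"rng_seed": cfg.rng_seed, "rng_key": rng_key,
                                 "background": ctx.background,
                                 "accept_scale": ctx.scale})


def _mask_weight(u: np.ndarray) -> np.ndarray:
    """Flat-top suppression profile: 1 inside one radius, cosine roll-off to
    zero at 1.5 radii.  (A flat top is needed so the whole tube footprint is
    removed, not just its centerline.)"""
    u = np.asarray(u, dtype=float)
    roll = 0.5 * (1.0 + np.cos(np.pi * np.clip((u - 1.0) / 0.5, 0.0, 1.0)))
    return np.where(u <= 1.0, 1.0, np.where(u >= 1.5, 0.0, roll))


def _mask_curve(data: np.ndarray, volume_like: DensityVolume, curve: SpaceCurve,
                radius_nm: float, background: float) -> np.ndarray:
    """Blend a soft tube around the curve toward the background level."""
    from scipy.spatial import cKDTree
    voxel = np.asarray(volume_like.voxel_size_nm)
    origin = np.asarray(volume_like.origin_nm)
    pts = sample_points(curve, 0.3 * float(voxel.min()))
    reach_nm = 1.5 * radius_nm
    lo = np.maximum(np.floor((pts.min(axis=0) - reach_nm - origin) / voxel).astype(int), 0)
    hi = np.minimum(np.ceil((pts.max(axis=0) + reach_nm - origin) / voxel).astype(int) + 1,
                    data.shape)
    if (hi <= lo).any():
        return data
    sub = tuple(slice(l, h) for l, h in zip(lo, hi))
    grid = np.stack(np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                                indexing="ij"), axis=-1).reshape(-1, 3)
    grid_nm = grid * voxel + origin
    d, _ = cKDTree(pts).query(grid_nm, distance_upper_bound=reach_nm + voxel.max())
    w = _mask_weight(np.where(np.isinf(d), np.inf, d) / radius_nm)
    block = data[sub].reshape(-1)
    data[sub] = (background + (block - background) * (1.0 - w)).reshape(
        data[sub].shape)
    return data


def _adjust_extent(curve: SpaceCurve, smoothed: np.ndarray, threshold: float,
                   voxel: np.ndarray, origin: np.ndarray) -> SpaceCurve | None:
    """Re-derive the parameter interval from the curve's own density support:
    extend each end while the smoothed density along the (unclamped) model
    stays above threshold, and trim ends that lie below it.  Returns None if
    the supported extent collapses."""
    shape = np.array(smoothed.shape)
    step = 0.5 * float(voxel.min())

    def value_at(t):
        pts = curve._local(np.array([t])) @ curve.rotation.T + curve.translation
        idx = (pts[0] - origin) / voxel
        if (idx < 0).any() or (idx > shape - 1).any():
            return None
        return float(ndimage.map_coordinates(smoothed, idx[:, None], order=1)[0])

    t_lo, t_hi = curve.t_range
    # trim ends without support
    while t_hi - t_lo > step:
        v = value_at(t_hi)
        if v is not None and v >= threshold:
            break
        t_hi -= step
    while t_hi - t_lo > step:
        v = value_at(t_lo)
        if v is not None and v >= threshold:
            break
        t_lo += step
    if t_hi - t_lo <= step:
        return None
    # extend ends with support (tolerating brief dips)
    for sign, t_end in ((+1, t_hi), (-1, t_lo)):
        good, misses, t = t_end, 0, t_end
        while misses <= 3:
            t += sign * step
            v = value_at(t)
            if v is None:
                break
            if v >= threshold:
                good, misses = t, 0
            else:
                misses += 1
        if sign > 0:
            t_hi = good
        else:
            t_lo = good
    return replace(curve, t_range=(t_lo, t_hi))


def fit_all(volume: DensityVolume, cfg: FitConfig) -> list:
    """Greedy multi-fibril extraction by fit / soft-mask / re-seed cycles.

    Stops when no seed clears the acceptance threshold or the per-subvolume
    fibril cap is reached.  Accepted fits are pairwise non-duplicate (mean
    pair distance > mask_radius_nm / 2).
    """
    work = volume.with_data(np.asarray(volume.data, dtype=float).copy())
    base_ctx = _CostContext(volume)
    accepted: list[FitResult] = []
    attempts = 0
    while len(accepted) < cfg.max_fibrils_per_subvolume:
        attempts += 1
        if attempts > 3 * cfg.max_fibrils_per_subvolume:
            break
        seeds = seed_candidates(work, cfg)
        if not seeds:
            break
        # try a few ranked candidates: one weak seed (e.g. a shoulder track
        # near a fibril crossing) must not end the whole extraction
        progress = False
        for k, seed in enumerate(seeds[:4]):
            res = fit_single(work, seed, cfg, rng_key=10 * attempts + k,
                             label=f"peel_{attempts}")
            # signal in the peeled volume (already-extracted tubes are
            # flattened there), judged on the ORIGINAL volume's scale
            signal = -res.cost - base_ctx.background
            if signal <= cfg.accept_threshold * base_ctx.scale:
                continue
            _mask_curve(work.data, work, res.curve, cfg.mask_radius_nm,
                        base_ctx.background)
            progress = True
            dup = any(pair_distance(res.curve, a.curve, 0.5)
                      <= cfg.mask_radius_nm / 2 for a in accepted)
            if not dup:
                accepted.append(res)
            break
        if not progress:
            break
    # finalization against the UNMASKED volume.  First re-derive each fit's
    # extent from its own density support (seeds born near fibril crossings
    # can carry a truncated or shifted interval), then a local simplex polish:
    # peeling neighbors slightly biases a fit away from them and the polish
    # pulls it back.  The polish box is shrunk so the correction stays local
    # and cannot hop onto a neighboring fibril.
    smoothed = ndimage.gaussian_filter(base_ctx.data, 1.0)
    sm_bg = float(np.median(smoothed))
    ext_thr = sm_bg + 0.35 * (float(smoothed.max()) - sm_bg)
    polish_bounds = 0.3 * cfg.param_bounds()
    supported = []
    for res in accepted:
        adj = _adjust_extent(res.curve, smoothed, ext_thr,
                             base_ctx.voxel, base_ctx.origin)
        if adj is None or adj.t_range[1] - adj.t_range[0] < cfg.seed_min_length_nm:
            continue
        res.curve = adj
        try:
            cur_cost = curve_cost(adj, base_ctx, cfg)
        except ValueError:
            continue
        supported.append((res, cur_cost))
    accepted = [res for res, _ in supported]
    for res, cur_cost in supported:
        res.curve = recenter_parameter(res.curve)
        def fun(p, _seed=res.curve):
            try:
                return curve_cost(params_to_curve(p, _seed, cfg), base_ctx, cfg)
            except ValueError:
                return -base_ctx.background
        x, c = refine_simplex(fun, np.zeros(cfg.n_params()),
                              polish_bounds, cfg.simplex_tol)
        if c <= cur_cost:
            res.curve = params_to_curve(x, res.curve, cfg)
            cur_cost = c
        if cur_cost < res.cost:
            res.cost = cur_cost
            res.history = list(res.history) + [cur_cost]
    # re-check acceptance against the ORIGINAL volume: a track that skimmed
    # density belonging to fibrils extracted later has no support of its own
    kept = []
    for res in accepted:
        try:
            bcost = curve_cost(res.curve, base_ctx, cfg)
        except ValueError:
            continue
        if -bcost - base_ctx.background > cfg.accept_threshold * base_ctx.scale:
            kept.append(res)
    # a polish step could still merge two fits; keep the better of any pair
    unique: list[FitResult] = []
    for res in sorted(kept, key=lambda r: r.cost):
        if all(pair_distance(res.curve, u.curve, 0.5) > cfg.mask_radius_nm / 2
               for u in unique):
            unique.append(res)
    return unique
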
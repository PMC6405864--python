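"""Quantitative descriptors of a fibril curve set.

All statistics operate on lists of :class:`~fibriltrace.curve_model.SpaceCurve`
— fitted or ground truth — in scene coordinates whose components follow the
volume's anatomical axis tags (default order L, T, N):

* nearest-neighbor distances between curves (symmetric mean-of-minima pair
  distance, plus the plain minimum for contact detection),
* orientation angles of the mean tangent against the tangential plane
  (signed), the transverse plane, and the longitudinal axis,
* bundle detection as connected components of the near-contact graph,
* spatial grid maps over the tangential-plane footprint,
* a recovery report matching fits one-to-one against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .curve_model import SpaceCurve, curve_length, mean_tangent, sample_points


def _axis_vectors(axes=("L", "T", "N")):
    out = {}
    for tag in ("L", "T", "N"):
        e = np.zeros(3)
        e[axes.index(tag)] = 1.0
        out[tag] = e
    return out


def _canonical_tangent(m: np.ndarray, ax: dict) -> np.ndarray:
    """Fix the sign ambiguity of a line direction: positive T component
    (tie-break N, then L)."""
    for tag in ("T", "N", "L"):
        c = float(m @ ax[tag])
        if abs(c) > 1e-9:
            return m if c > 0 else -m
    return m


def orientation_angles(curve: SpaceCurve, axes=("L", "T", "N")) -> dict:
    """Angles of the curve's mean tangent (degrees).

    tangential_deg  : signed angle with the tangential (L-T) plane, in
                      (-90, 90]; the sign is the side of the plane (N > 0).
    transverse_deg  : unsigned angle with the transverse (T-N) plane.
    longitudinal_deg: angle with the +L axis of the sign-canonicalized
                      tangent, in [0, 180); perpendicular fibrils sit near 90.
    """
    ax = _axis_vectors(axes)
    m = _canonical_tangent(mean_tangent(curve), ax)
    sin_tan = np.clip(m @ ax["N"], -1.0, 1.0)
    sin_trv = np.clip(abs(m @ ax["L"]), 0.0, 1.0)
    cos_lon = np.clip(m @ ax["L"], -1.0, 1.0)
    return {
        "tangential_deg": float(np.degrees(np.arcsin(sin_tan))),
        "transverse_deg": float(np.degrees(np.arcsin(sin_trv))),
        "longitudinal_deg": float(np.degrees(np.arccos(cos_lon))),
    }


# ---------------------------------------------------------------------------
# Pairwise distances
# ---------------------------------------------------------------------------

def _pair_tables(curves, sampling_nm: float):
    """Per-curve sample clouds and the full symmetric pair-distance matrices."""
    pts = [sample_points(c, sampling_nm) for c in curves]
    trees = [cKDTree(p) for p in pts]
    n = len(curves)
    mean_of_min = np.zeros((n, n))
    minimum = np.zeros((n, n))
    frac_contact = None
    dmin_profiles = {}
    for i in range(n):
        for j in range(i + 1, n):
            dij = trees[j].query(pts[i])[0]
            dji = trees[i].query(pts[j])[0]
            mean_of_min[i, j] = mean_of_min[j, i] = 0.5 * (dij.mean() + dji.mean())
            minimum[i, j] = minimum[j, i] = min(dij.min(), dji.min())
            dmin_profiles[(i, j)] = (dij, dji)
    return pts, mean_of_min, minimum, dmin_profiles


def nearest_neighbor_distances(curves, sampling_nm: float = 0.5) -> pd.DataFrame:
    """Per-curve nearest-neighbor table.

    ``nn_distance_nm`` uses the symmetric mean-of-minima pair distance;
    ``nn_min_nm`` is the plain closest approach to the same partner.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves for nearest-neighbor distances")
    _, mom, mn, _ = _pair_tables(curves, sampling_nm)
    np.fill_diagonal(mom, np.inf)
    partner = mom.argmin(axis=1)
    rows = [{"curve_id": i, "nn_partner_id": int(partner[i]),
             "nn_distance_nm": float(mom[i, partner[i]]),
             "nn_min_nm": float(mn[i, partner[i]])}
            for i in range(len(curves))]
    return pd.DataFrame(rows)


def angle_summary(curves, axes=("L", "T", "N")) -> dict:
    """Population summary of orientation angles.

    The longitudinal-angle SD switches to circular statistics when the linear
    spread exceeds 30 degrees (angles near the 0/180 wrap would otherwise
    inflate the linear SD).
    """
    if not curves:
        raise ValueError("need at least 1 curve")
    tang = np.array([orientation_angles(c, axes)["tangential_deg"] for c in curves])
    lon = np.array([orientation_angles(c, axes)["longitudinal_deg"] for c in curves])
    if lon.std() > 30.0:
        rad = np.deg2rad(lon)
        R = np.hypot(np.sin(rad).mean(), np.cos(rad).mean())
        lon_sd = float(np.degrees(np.sqrt(-2.0 * np.log(max(R, 1e-12)))))
    else:
        lon_sd = float(lon.std(ddof=0))
    return {
        "n_curves": len(curves),
        "tangential_median_signed_deg": float(np.median(tang)),
        "tangential_median_abs_deg": float(np.median(np.abs(tang))),
        "tangential_sd_deg": float(tang.std(ddof=0)),
        "longitudinal_mean_deg": float(lon.mean()),
        "longitudinal_sd_deg": lon_sd,
        "n_positive_tangential": int((tang > 0).sum()),
        "n_negative_tangential": int((tang < 0).sum()),
    }


def detect_bundles(curves, contact_nm: float, min_overlap_fraction: float = 0.3,
                   sampling_nm: float = 0.5):
    """Bundles = connected components of the sustained-near-contact graph.

    Two curves are linked when the per-sample nearest-distance profile stays
    at or below ``contact_nm`` for at least ``min_overlap_fraction`` of the
    samples (in the more favorable direction — robust to unequal curve
    lengths).  Components of size >= 2 are bundles.

    Returns ``(table, bundle_fraction_percent)`` where the table has one row
    per curve with its ``bundle_id`` (or -1).
    """
    if contact_nm <= 0:
        raise ValueError("contact_nm must be positive")
    n = len(curves)
    if n == 0:
        return pd.DataFrame(columns=["curve_id", "bundle_id"]), 0.0
    _, _, _, profiles = _pair_tables(curves, sampling_nm) if n > 1 else (None, None, None, {})
    rows_i, rows_j = [], []
    for (i, j), (dij, dji) in profiles.items():
        frac = max((dij <= contact_nm).mean(), (dji <= contact_nm).mean())
        if frac >= min_overlap_fraction:
            rows_i.append(i); rows_j.append(j)
    adj = csr_matrix((np.ones(len(rows_i)), (rows_i, rows_j)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    bundle_id = np.where(sizes[labels] >= 2, labels, -1)
    # renumber bundles densely
    uniq = {b: k for k, b in enumerate(sorted(set(bundle_id[bundle_id >= 0])))}
    bundle_id = np.array([uniq.get(b, -1) for b in bundle_id])
    table = pd.DataFrame({"curve_id": np.arange(n), "bundle_id": bundle_id})
    fraction = 100.0 * (bundle_id >= 0).sum() / n
    return table, float(fraction)


@dataclass
class GridMap:
    """Per-cell means of fibril descriptors over the tangential-plane grid."""

    cell_side: float
    counts: np.ndarray
    mean_tangential_deg: np.ndarray
    mean_transverse_deg: np.ndarray
    mean_nn_distance_nm: np.ndarray

    def global_means(self) -> dict:
        """Count-weighted cell means; equals the plain global means."""
        w = self.counts.astype(float)
        tot = w.sum()
        out = {}
        for name in ("mean_tangential_deg", "mean_transverse_deg",
                     "mean_nn_distance_nm"):
            arr = getattr(self, name)
            valid = w > 0
            out[name] = float((arr[valid] * w[valid]).sum() / tot) if tot else np.nan
        return out


def grid_maps(curves, volume_extent_nm, cell_side: float,
              axes=("L", "T", "N"), nn_table: pd.DataFrame | None = None,
              sampling_nm: float = 0.5) -> GridMap:
    """Aggregate per-curve descriptors on a square grid in the L-T plane.

    Each curve is assigned to the cell containing its midpoint (curve
    midpoints outside the extent clip into the border cells).
    """
    if cell_side <= 0:
        raise ValueError("cell_side must be positive")
    iL, iT = axes.index("L"), axes.index("T")
    nL = max(1, int(np.ceil(volume_extent_nm[iL] / cell_side)))
    nT = max(1, int(np.ceil(volume_extent_nm[iT] / cell_side)))
    counts = np.zeros((nL, nT), dtype=int)
    sums = {k: np.zeros((nL, nT)) for k in ("tan", "trv", "nn")}
    if nn_table is None and len(curves) >= 2:
        nn_table = nearest_neighbor_distances(curves, sampling_nm)
    from .curve_model import evaluate
    for k, c in enumerate(curves):
        t0, t1 = c.t_range
        mid = evaluate(c, [(t0 + t1) / 2.0])[0]
        i = int(np.clip(mid[iL] // cell_side, 0, nL - 1))
        j = int(np.clip(mid[iT] // cell_side, 0, nT - 1))
        ang = orientation_angles(c, axes)
        counts[i, j] += 1
        sums["tan"][i, j] += ang["tangential_deg"]
        sums["trv"][i, j] += ang["transverse_deg"]
        if nn_table is not None:
            sums["nn"][i, j] += float(nn_table.loc[k, "nn_distance_nm"])
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = {k: np.where(counts > 0, v / np.maximum(counts, 1), np.nan)
                for k, v in sums.items()}
    return GridMap(cell_side=float(cell_side), counts=counts,
                   mean_tangential_deg=mean["tan"],
                   mean_transverse_deg=mean["trv"],
                   mean_nn_distance_nm=mean["nn"])


# ---------------------------------------------------------------------------
# Aggregate per-set metrics
# ---------------------------------------------------------------------------

@dataclass
class FibrilMetrics:
    per_curve: pd.DataFrame
    summary: dict


def compute_metrics(curves, axes=("L", "T", "N"), contact_nm: float = 4.4,
                    min_overlap_fraction: float = 0.3, sampling_nm: float = 0.5,
                    min_confident_length_nm: float = 15.0) -> FibrilMetrics:
    """One-stop per-curve table + population summary.

    Curves shorter than ``min_confident_length_nm`` get a low-confidence flag
    on their angle estimates (very thin sections truncate fibrils and make
    axis angles unreliable).
    """
    rows = []
    for i, c in enumerate(curves):
        ang = orientation_angles(c, axes)
        rows.append({"curve_id": i, "length_nm": curve_length(c), **ang,
                     "low_confidence_angles":
                         bool(curve_length(c) < min_confident_length_nm)})
    per = pd.DataFrame(rows)
    if len(curves) >= 2:
        nn = nearest_neighbor_distances(curves, sampling_nm)
        per = per.merge(nn, on="curve_id")
    btable, bfrac = detect_bundles(curves, contact_nm, min_overlap_fraction,
                                   sampling_nm) if len(curves) >= 2 else (
        pd.DataFrame({"curve_id": [0], "bundle_id": [-1]}), 0.0)
    per = per.merge(btable, on="curve_id")
    summary = angle_summary(curves, axes) if curves else {}
    summary.update({
        "bundle_fraction_percent": bfrac,
        "contact_nm": contact_nm,
        "mean_nn_distance_nm": float(per["nn_distance_nm"].mean())
        if "nn_distance_nm" in per else np.nan,
        "median_nn_distance_nm": float(per["nn_distance_nm"].median())
        if "nn_distance_nm" in per else np.nan,
    })
    return FibrilMetrics(per_curve=per, summary=summary)


def recovery_report(truth_curves, fit_curves, match_radius_nm: float = 3.0,
                    sampling_nm: float = 0.5) -> dict:
    """Match fits to ground truth one-to-one (Hungarian assignment on the
    pair-distance matrix) and report per-match centerline RMSD plus counts of
    missed truths and spurious fits.  Order-invariant in both inputs."""
    if not truth_curves or not fit_curves:
        raise ValueError("both curve sets must be nonempty")
    tp = [sample_points(c, sampling_nm) for c in truth_curves]
    fp = [sample_points(c, sampling_nm) for c in fit_curves]
    ttrees = [cKDTree(p) for p in tp]
    ftrees = [cKDTree(p) for p in fp]
    D = np.zeros((len(tp), len(fp)))
    R = np.zeros_like(D)
    for i in range(len(tp)):
        for j in range(len(fp)):
            dij = ftrees[j].query(tp[i])[0]
            dji = ttrees[i].query(fp[j])[0]
            D[i, j] = 0.5 * (dij.mean() + dji.mean())
            R[i, j] = float(np.sqrt(np.concatenate([dij, dji]).__pow__(2).mean()))
    ri, ci = linear_sum_assignment(D)
    matches = [(int(i), int(j), float(R[i, j])) for i, j in zip(ri, ci)
               if D[i, j] <= match_radius_nm]
    matched_t = {m[0] for m in matches}
    matched_f = {m[1] for m in matches}
    return {
        "matches": matches,
        "rmsd_nm": [m[2] for m in matches],
        "n_truth": len(tp),
        "n_fits": len(fp),
        "n_matched": len(matches),
        "n_missed": len(tp) - len(matched_t),
        "n_spurious": len(fp) - len(matched_f),
        "fraction_matched": len(matches) / len(tp),
    }
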
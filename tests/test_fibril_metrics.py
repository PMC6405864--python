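"""Nearest-neighbor, orientation, bundle and grid-map statistics."""

import numpy as np
import pytest

from fibriltrace.curve_model import line_curve, rotation_about_axis
from fibriltrace.fibril_metrics import (angle_summary, compute_metrics,
                                        detect_bundles, grid_maps,
                                        nearest_neighbor_distances,
                                        orientation_angles, recovery_report)
from fibriltrace.synthetic_scenes import make_scene


def axial_lines(positions_L, direction=(0, 1, 0), t=(-20.0, 20.0)):
    return [line_curve((x, 27.0, 9.0), direction, t) for x in positions_L]


class TestNearestNeighbor:
    def test_three_parallel_lines(self):
        nn = nearest_neighbor_distances(axial_lines([0, 10, 20]))
        assert np.allclose(nn["nn_distance_nm"], [10, 10, 10])
        assert nn["nn_distance_nm"].mean() == pytest.approx(10.0)

    def test_planted_11nm_lattice(self):
        sc = make_scene("parallel", n_fibrils=8, spacing_nm=11.0,
                        box_nm=(110, 54, 18), seed=0)
        nn = nearest_neighbor_distances(sc.truth_curves)
        assert nn["nn_distance_nm"].mean() == pytest.approx(11.0, abs=1e-6)

    def test_crossing_pair_contact(self):
        c1 = line_curve((20, 27, 9), (0, np.cos(np.pi / 4), np.sin(np.pi / 4)),
                        (-10, 10))
        c2 = line_curve((20.5, 27, 9), (0, np.cos(np.pi / 4), -np.sin(np.pi / 4)),
                        (-10, 10))
        nn = nearest_neighbor_distances([c1, c2])
        assert nn["nn_min_nm"].min() <= 0.9  # within one voxel of contact

    def test_needs_two_curves(self):
        with pytest.raises(ValueError):
            nearest_neighbor_distances(axial_lines([5.0]))

    def test_permutation_and_rigid_invariance(self, rng):
        curves = axial_lines([0, 9, 21, 34])
        base = nearest_neighbor_distances(curves)["nn_distance_nm"].to_numpy()
        perm = [2, 0, 3, 1]
        permuted = nearest_neighbor_distances([curves[i] for i in perm])
        assert np.allclose(permuted["nn_distance_nm"].to_numpy(), base[perm])
        R = rotation_about_axis(rng.normal(size=3), 1.1)
        moved = [c.transformed(R, (4.0, -2.0, 7.0)) for c in curves]
        assert np.allclose(
            nearest_neighbor_distances(moved)["nn_distance_nm"], base)


class TestOrientationAngles:
    def test_longitudinal_line(self):
        c = line_curve((0, 0, 0), (1, 0, 0), (0, 20))
        ang = orientation_angles(c)
        assert ang["longitudinal_deg"] == pytest.approx(0.0, abs=1e-9)
        assert ang["tangential_deg"] == pytest.approx(0.0, abs=1e-9)

    def test_six_degree_tilt(self):
        d = (0.0, np.cos(np.deg2rad(6)), np.sin(np.deg2rad(6)))
        ang = orientation_angles(line_curve((0, 0, 0), d, (0, 20)))
        assert ang["tangential_deg"] == pytest.approx(6.0, abs=1e-9)
        assert ang["longitudinal_deg"] == pytest.approx(90.0, abs=1e-9)

    def test_45_between_T_and_N(self):
        d = (0.0, np.cos(np.deg2rad(45)), np.sin(np.deg2rad(45)))
        ang = orientation_angles(line_curve((0, 0, 0), d, (0, 20)))
        assert ang["longitudinal_deg"] == pytest.approx(90.0)
        assert ang["tangential_deg"] == pytest.approx(45.0)

    def test_sign_is_side_of_tangential_plane(self):
        up = (0.0, np.cos(np.deg2rad(6)), np.sin(np.deg2rad(6)))
        dn = (0.0, np.cos(np.deg2rad(6)), -np.sin(np.deg2rad(6)))
        assert orientation_angles(line_curve((0, 0, 0), up, (0, 20)))[
            "tangential_deg"] > 0
        assert orientation_angles(line_curve((0, 0, 0), dn, (0, 20)))[
            "tangential_deg"] < 0


class TestAngleSummary:
    def test_identical_curves_zero_sd(self):
        s = angle_summary(axial_lines([0, 10, 20]))
        assert s["tangential_sd_deg"] == 0.0
        assert s["longitudinal_sd_deg"] == 0.0

    def test_planted_gaussian_longitudinal_sd(self):
        rng = np.random.default_rng(42)
        longs = rng.normal(90.0, 10.0, size=200)
        curves = []
        for lo in longs:
            delta = np.deg2rad(90.0 - lo)
            d = (np.sin(delta), np.cos(delta), 0.0)
            curves.append(line_curve((0, 0, 0), d, (0, 20)))
        s = angle_summary(curves)
        assert s["longitudinal_sd_deg"] == pytest.approx(10.0, abs=1.5)

    def test_symmetric_pair_medians(self):
        up = (0.0, np.cos(np.deg2rad(6)), np.sin(np.deg2rad(6)))
        dn = (0.0, np.cos(np.deg2rad(6)), -np.sin(np.deg2rad(6)))
        curves = [line_curve((0, 0, 0), up, (0, 20)),
                  line_curve((10, 0, 0), dn, (0, 20))]
        s = angle_summary(curves)
        assert s["tangential_median_signed_deg"] == pytest.approx(0.0)
        assert s["tangential_median_abs_deg"] == pytest.approx(6.0)


class TestBundles:
    def test_planted_forty_percent(self):
        sc = make_scene("bundled", n_fibrils=10, bundle_fraction=0.4,
                        bundle_size=2, spacing_nm=10.0, box_nm=(110, 54, 18),
                        seed=0)
        _, frac = detect_bundles(sc.truth_curves, contact_nm=4.4)
        assert frac == pytest.approx(40.0)

    def test_all_far_apart(self):
        _, frac = detect_bundles(axial_lines([0, 10, 20]), contact_nm=4.4)
        assert frac == 0.0

    def test_three_touching_form_one_bundle(self):
        table, frac = detect_bundles(axial_lines([0, 3, 6]), contact_nm=3.5)
        assert frac == pytest.approx(100.0)
        assert table["bundle_id"].nunique() == 1

    def test_monotone_in_contact_threshold(self):
        curves = axial_lines([0, 4, 11, 30])
        fracs = [detect_bundles(curves, contact_nm=c)[1]
                 for c in (2.0, 4.5, 12.0, 35.0)]
        assert fracs == sorted(fracs)


class TestGridMaps:
    def test_single_cell_equals_global(self):
        curves = axial_lines([5, 15, 25])
        gm = grid_maps(curves, (40, 54, 18), cell_side=60.0)
        assert gm.counts.sum() == 3
        nn = nearest_neighbor_distances(curves)["nn_distance_nm"].mean()
        assert gm.global_means()["mean_nn_distance_nm"] == pytest.approx(nn)

    def test_two_cells_split_means(self):
        up = (0.0, np.cos(np.deg2rad(10)), np.sin(np.deg2rad(10)))
        dn = (0.0, np.cos(np.deg2rad(10)), -np.sin(np.deg2rad(10)))
        curves = [line_curve((5, 10, 9), up, (-9, 9)),
                  line_curve((5, 12, 9), up, (-9, 9)),
                  line_curve((35, 10, 9), dn, (-9, 9)),
                  line_curve((35, 12, 9), dn, (-9, 9))]
        gm = grid_maps(curves, (40, 22, 18), cell_side=20.0)
        filled = gm.mean_tangential_deg[gm.counts > 0]
        assert sorted(np.round(filled, 6)) == [-10.0, 10.0]
        assert gm.global_means()["mean_tangential_deg"] == pytest.approx(0.0)

    def test_count_weighted_conservation(self):
        sc = make_scene("mixed", n_fibrils=9, spacing_nm=10.0,
                        angles={"tangential_deg": 6.0}, box_nm=(110, 54, 18),
                        seed=1, angle_jitter_deg={"tangential_deg": 2.0})
        curves = sc.truth_curves
        gm = grid_maps(curves, (110, 54, 18), cell_side=40.5)
        want = np.mean([orientation_angles(c)["tangential_deg"] for c in curves])
        assert gm.global_means()["mean_tangential_deg"] == pytest.approx(want)


class TestRecoveryReport:
    def test_identity_zero_rmsd(self):
        curves = axial_lines([0, 10, 20])
        rec = recovery_report(curves, list(curves))
        assert rec["n_matched"] == 3 and rec["n_missed"] == 0
        assert max(rec["rmsd_nm"]) == 0.0

    def test_missing_fit_counted(self):
        truth = axial_lines([0, 10, 20, 30, 40])
        fits = axial_lines([0, 10, 20, 30])
        rec = recovery_report(truth, fits)
        assert rec["n_matched"] == 4
        assert rec["n_missed"] == 1 and rec["n_spurious"] == 0

    def test_order_invariance(self):
        truth = axial_lines([0, 10, 20, 30])
        fits = axial_lines([30.2, 0.3, 20.1, 9.8])
        a = recovery_report(truth, fits)
        b = recovery_report(truth[::-1], fits)
        assert a["n_matched"] == b["n_matched"] == 4
        assert sorted(np.round(a["rmsd_nm"], 9)) == sorted(np.round(b["rmsd_nm"], 9))

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            recovery_report([], axial_lines([0]))


def test_compute_metrics_closed_loop():
    """Metrics on truth curves reproduce the construction parameters."""
    sc = make_scene("bundled", n_fibrils=10, bundle_fraction=0.4,
                    bundle_size=2, spacing_nm=10.0, box_nm=(110, 54, 18),
                    seed=9)
    fm = compute_metrics(sc.truth_curves)
    assert fm.summary["bundle_fraction_percent"] == pytest.approx(40.0)
    assert fm.summary["tangential_median_signed_deg"] == pytest.approx(0.0)
    assert len(fm.per_curve) == 10
    # bundle members sit at contact distance (one tube diameter)
    bundled = fm.per_curve[fm.per_curve.bundle_id >= 0]
    assert np.allclose(bundled["nn_distance_nm"], 3.5, atol=1e-6)
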
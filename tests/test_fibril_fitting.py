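"""Cost function, seeding, PSO+simplex fitting and multi-fibril extraction."""

import numpy as np
import pytest

from fibriltrace.curve_model import SpaceCurve, evaluate, line_curve
from fibriltrace.fibril_fitting import (FitConfig, curve_cost, fit_all,
                                        fit_single, optimize_box,
                                        seed_candidates)
from fibriltrace.fibril_metrics import orientation_angles, recovery_report
from fibriltrace.synthetic_scenes import (apply_noise, make_scene, render_scene)
from fibriltrace.volume_io import DensityVolume, gaussian_denoise


@pytest.fixture(scope="module")
def cfg():
    return FitConfig(rng_seed=7)


class TestCurveCost:
    def test_uniform_volume_cost_is_minus_value(self, cfg):
        v = DensityVolume(np.full((30, 30, 30), 3.5), voxel_size_nm=1.0)
        c = line_curve((15, 15, 15), (0, 1, 0), (-10, 10))
        assert curve_cost(c, v, cfg) == pytest.approx(-3.5)
        helix = SpaceCurve(translation=np.array([15.0, 15, 15]),
                           helix_radius_nm=2.0, helix_pitch_rad_per_nm=0.5,
                           t_range=(-8.0, 8.0))
        assert curve_cost(helix, v, cfg) == pytest.approx(-3.5)

    def test_truth_beats_shifted_curve(self, single_tube_volume, cfg):
        scene, vol = single_tube_volume
        truth = scene.truth_curves[0]
        shifted = truth.transformed(np.eye(3), (5.0, 0.0, 0.0))
        assert curve_cost(truth, vol, cfg) < curve_cost(shifted, vol, cfg)

    def test_linearity_in_intensity(self, single_tube_volume, cfg):
        scene, vol = single_tube_volume
        truth = scene.truth_curves[0]
        doubled = vol.with_data(2.0 * np.asarray(vol.data))
        assert curve_cost(truth, doubled, cfg) == pytest.approx(
            2.0 * curve_cost(truth, vol, cfg))

    def test_fully_outside_curve_rejected(self, single_tube_volume, cfg):
        scene, vol = single_tube_volume
        far = line_curve((500, 500, 500), (0, 1, 0), (-5, 5))
        with pytest.raises(ValueError):
            curve_cost(far, vol, cfg)


class TestSeeding:
    def test_three_tubes_seeded_near_truth(self, three_tube_volume, cfg):
        scene, vol = three_tube_volume
        seeds = seed_candidates(vol, cfg)
        assert len(seeds) >= 3
        from fibriltrace.curve_model import pair_distance
        matched = set()
        for i, t in enumerate(scene.truth_curves):
            for s in seeds:
                if pair_distance(s, t, 0.5) <= 2 * 0.9:
                    matched.add(i)
                    break
        assert matched == {0, 1, 2}

    def test_uniform_volume_gives_no_seeds(self, cfg):
        v = DensityVolume(np.full((40, 40, 20), 1.0), voxel_size_nm=0.9)
        assert seed_candidates(v, cfg) == []

    def test_seeds_reproducible(self, three_tube_volume, cfg):
        _, vol = three_tube_volume
        a = seed_candidates(vol, cfg)
        b = seed_candidates(vol, cfg)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert np.allclose(evaluate(ca, [0.0]), evaluate(cb, [0.0]))


class TestFitSingle:
    def test_noiseless_recovery_subvoxel(self, single_tube_volume, cfg):
        scene, vol = single_tube_volume
        seeds = seed_candidates(vol, cfg)
        res = fit_single(vol, seeds[0], cfg)
        rec = recovery_report(scene.truth_curves, [res.curve])
        assert rec["rmsd_nm"][0] / 0.9 < 0.5
        assert res.converged

    def test_optimizer_contracts(self, single_tube_volume, cfg):
        scene, vol = single_tube_volume
        seed = seed_candidates(vol, cfg)[0]
        res = fit_single(vol, seed, cfg)
        assert res.cost <= res.pso_cost + 1e-12
        assert res.cost <= curve_cost(seed, vol, cfg) + 1e-12
        assert (np.diff(res.history) <= 1e-12).all()

    def test_deterministic(self, single_tube_volume, cfg):
        _, vol = single_tube_volume
        seed = seed_candidates(vol, cfg)[0]
        a = fit_single(vol, seed, cfg, rng_key=3)
        b = fit_single(vol, seed, cfg, rng_key=3)
        assert a.cost == b.cost
        assert np.allclose(evaluate(a.curve, [0.0]), evaluate(b.curve, [0.0]))


class TestFitAll:
    def test_five_fibrils_recovered_one_to_one(self):
        scene = make_scene("parallel", n_fibrils=5, spacing_nm=10.0,
                           box_nm=(60, 54, 18), seed=3, noise_sigma=1 / 3)
        vol = apply_noise(render_scene(scene, voxel_size_nm=0.9), scene)
        vol = gaussian_denoise(vol, 0.9)
        fits = fit_all(vol, FitConfig(rng_seed=1))
        assert len(fits) == 5
        rec = recovery_report(scene.truth_curves, [f.curve for f in fits])
        assert rec["n_matched"] == 5 and rec["n_spurious"] == 0
        assert max(rec["rmsd_nm"]) / 0.9 < 1.0

    def test_uniform_volume_gives_no_fits(self):
        v = DensityVolume(np.full((40, 40, 20), 2.0), voxel_size_nm=0.9)
        assert fit_all(v, FitConfig(rng_seed=0)) == []

    def test_crossed_families_both_signs_recovered(self):
        scene = make_scene("crossed", n_fibrils=4, spacing_nm=11.0,
                           angles={"tangential_deg": 45.0},
                           box_nm=(40, 60, 45), seed=2)
        vol = render_scene(scene, voxel_size_nm=0.9)
        fits = fit_all(vol, FitConfig(rng_seed=2))
        angs = [orientation_angles(f.curve)["tangential_deg"] for f in fits]
        assert any(a > 0 for a in angs) and any(a < 0 for a in angs)
        assert all(min(abs(a - 45), abs(a + 45)) < 5 for a in angs)

    def test_no_duplicate_fits(self):
        scene = make_scene("bundled", n_fibrils=6, spacing_nm=10.0,
                           bundle_fraction=0.34, bundle_size=2,
                           box_nm=(70, 54, 18), seed=5)
        vol = render_scene(scene, voxel_size_nm=0.9)
        cfg = FitConfig(rng_seed=5)
        fits = fit_all(vol, cfg)
        from fibriltrace.curve_model import pair_distance
        for i, a in enumerate(fits):
            for b in fits[i + 1:]:
                assert pair_distance(a.curve, b.curve, 0.5) > cfg.mask_radius_nm / 2


class TestOptimizerEngine:
    def test_pso_plus_simplex_matches_grid_search(self):
        """On a 3-parameter straight-line restriction the swarm+simplex finds
        the exhaustive grid-search optimum (within grid resolution)."""
        from fibriltrace.fibril_fitting import _CostContext
        from fibriltrace.synthetic_scenes import SyntheticScene
        for seed in range(2):
            rng = np.random.default_rng(seed)
            off = rng.uniform(-2.5, 2.5, size=2)
            ang = rng.uniform(-0.2, 0.2)
            truth = line_curve((27 + off[0], 27, 27 + off[1]),
                               (np.sin(ang), np.cos(ang), 0.0), (-24, 24))
            vol = render_scene(SyntheticScene([truth], box_nm=(54, 54, 54)),
                               voxel_size_nm=0.9)
            ctx = _CostContext(vol)
            cfg3 = FitConfig(rng_seed=seed, n_particles=20, pso_iterations=40)

            def fun(p):
                c = line_curve((27 + p[0], 27, 27 + p[1]),
                               (np.sin(p[2]), np.cos(p[2]), 0.0), (-24, 24))
                return curve_cost(c, ctx, cfg3)

            xs = np.linspace(-4, 4, 21)
            ths = np.linspace(-0.3, 0.3, 21)
            grid_best, grid_x = np.inf, None
            for a in xs:
                for b in xs:
                    for th in ths:
                        c = fun((a, b, th))
                        if c < grid_best:
                            grid_best, grid_x = c, np.array([a, b, th])
            out = optimize_box(fun, np.array([(-4, 4), (-4, 4), (-0.3, 0.3)]),
                               cfg3)
            assert out["cost"] <= grid_best + 1e-9
            assert np.all(np.abs(out["x"] - grid_x) <= [0.4, 0.4, 0.03])
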
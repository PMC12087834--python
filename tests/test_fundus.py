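import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oculoshape.fundus import (
    FundusScene,
    MagnificationConfig,
    Vessel,
    arcade_concavity,
    crae,
    crve,
    extract_features,
    foveal_pixel_intensity,
    magnification_factor,
    mirror_scene,
    od_fovea_angle,
    od_fovea_distance,
    od_metrics,
    rasterize_vessels,
    vessel_caliber_equivalent,
    vessel_fd,
    vessel_tortuosity,
)


def brute_force_pairing(widths, k):
    """Independent oracle for the iterative big-six reduction."""
    vals = sorted(widths)
    while len(vals) > 1:
        carry = []
        if len(vals) % 2 == 1:
            carry.append(vals[len(vals) // 2])
            vals = vals[: len(vals) // 2] + vals[len(vals) // 2 + 1 :]
        combined = [
            k * math.sqrt(vals[i] ** 2 + vals[len(vals) - 1 - i] ** 2)
            for i in range(len(vals) // 2)
        ]
        vals = sorted(combined + carry)
    return vals[0]


def simple_scene(vessels=(), laterality="right", fovea=(350.0, 241.0), intensity=None):
    return FundusScene(
        od_center=(50.0, 256.0),
        od_semi_major=40.0,
        od_semi_minor=40.0,
        od_angle=0.0,
        fovea=fovea,
        vessels=list(vessels),
        laterality=laterality,
        intensity=intensity,
    )


def straight_vessel(width=10.0, kind="arteriole", y=100.0, n=10):
    x = np.linspace(100, 200, n)
    pts = np.column_stack([x, np.full(n, y)])
    return Vessel(points=pts, widths=np.full(n, width), kind=kind)


class TestMagnification:
    def test_reference_anchor_is_one(self):
        assert magnification_factor(0.0, 7.8) == pytest.approx(1.0)
        assert magnification_factor(0.0, None) == pytest.approx(1.0)

    def test_monotone_in_ser(self):
        assert magnification_factor(-6.0, 7.8) > magnification_factor(0.0, 7.8)
        sers = np.linspace(-10, 5, 20)
        factors = [magnification_factor(s, 7.8) for s in sers]
        assert all(f1 > f2 for f1, f2 in zip(factors, factors[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            magnification_factor(-25.0, 7.8)
        with pytest.raises(ValueError):
            magnification_factor(0.0, 10.0)

    def test_factor_scales_distance_and_area(self):
        scene = simple_scene()
        base_d = od_fovea_distance(scene)
        base_area = od_metrics(scene)[0]
        scene_myopic = simple_scene()
        scene_myopic.ser = -6.0
        f = magnification_factor(-6.0)
        assert od_fovea_distance(scene_myopic) == pytest.approx(f * base_d)
        assert od_metrics(scene_myopic)[0] == pytest.approx(f * f * base_area)


class TestOdFoveaGeometry:
    def test_345_triangle(self):
        scene = simple_scene(fovea=(53.0, 260.0))  # offset (3, 4)
        assert od_fovea_distance(scene) == pytest.approx(5.0)

    def test_distance_with_factor(self):
        scene = simple_scene(fovea=(53.0, 260.0))
        cfg = MagnificationConfig()
        scene.ser = 0.0
        base = od_fovea_distance(scene, cfg)
        scene.ser = -6.0
        assert od_fovea_distance(scene, cfg) == pytest.approx(
            base * magnification_factor(-6.0, None, cfg)
        )

    def test_coincident_rejected(self):
        scene = simple_scene(fovea=(50.0, 256.0))
        with pytest.raises(ValueError, match="coincide"):
            od_fovea_distance(scene)
        with pytest.raises(ValueError, match="coincide"):
            od_fovea_angle(scene)

    def test_level_fovea_angle_zero(self):
        scene = simple_scene(fovea=(350.0, 256.0))
        assert od_fovea_angle(scene) == pytest.approx(0.0)

    def test_right_eye_temporal_inferior_minus_45(self):
        scene = simple_scene(fovea=(51.0, 255.0))  # +1 temporal, -1 (up in y)
        assert od_fovea_angle(scene) == pytest.approx(-45.0)

    def test_left_eye_mirror_same_angle(self):
        right = simple_scene(fovea=(51.0, 255.0))
        left = mirror_scene(right)
        assert left.laterality == "left"
        assert od_fovea_angle(left) == pytest.approx(od_fovea_angle(right))


class TestOdMetrics:
    def test_circle_tiebreak(self):
        scene = simple_scene()
        scene.od_semi_major = scene.od_semi_minor = 10.0
        area, orientation, ovality = od_metrics(scene)
        assert area == pytest.approx(100 * math.pi)
        assert ovality == pytest.approx(1.0)
        assert orientation == 90.0

    def test_horizontal_ellipse(self):
        scene = simple_scene()
        scene.od_semi_major, scene.od_semi_minor, scene.od_angle = 6.0, 4.0, 0.0
        area, orientation, ovality = od_metrics(scene)
        assert area == pytest.approx(math.pi * 24)
        assert ovality == pytest.approx(1.5)
        assert orientation == pytest.approx(0.0)

    def test_axis_folding(self):
        scene = simple_scene()
        scene.od_semi_major, scene.od_semi_minor, scene.od_angle = 6.0, 4.0, 120.0
        _, orientation, _ = od_metrics(scene)
        assert orientation == pytest.approx(60.0)


class TestCaliber:
    def test_two_equal_arterioles_closed_form(self):
        assert vessel_caliber_equivalent([10, 10], 0.88) == pytest.approx(
            0.88 * math.sqrt(200), abs=1e-12
        )

    def test_six_equal_matches_oracle(self):
        for k in (0.88, 0.95):
            got = vessel_caliber_equivalent([10.0] * 6, k)
            assert got == pytest.approx(brute_force_pairing([10.0] * 6, k), abs=1e-9)

    @given(st.lists(st.floats(1.0, 50.0), min_size=1, max_size=9))
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle_any_count(self, widths):
        got = vessel_caliber_equivalent(widths, 0.88)
        assert got == pytest.approx(brute_force_pairing(widths, 0.88), rel=1e-12)

    @given(
        st.lists(st.floats(1.0, 40.0), min_size=2, max_size=6),
        st.integers(0, 5),
        st.floats(0.1, 5.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_widths(self, widths, idx, bump):
        bigger = list(widths)
        bigger[idx % len(widths)] += bump
        assert vessel_caliber_equivalent(bigger, 0.88) >= vessel_caliber_equivalent(
            widths, 0.88
        )

    def test_scene_crae_uses_six_widest(self):
        vessels = [straight_vessel(w, "arteriole", y=60 + 10 * i)
                   for i, w in enumerate([12, 11, 10, 9, 8, 7, 3, 2])]
        scene = simple_scene(vessels)
        assert crae(scene) == pytest.approx(
            brute_force_pairing([12, 11, 10, 9, 8, 7], 0.88), abs=1e-9
        )

    def test_median_width_summary(self):
        # per-vessel width summary is the median of per-point widths
        pts = np.column_stack([np.linspace(0, 100, 5), np.full(5, 50.0)])
        v = Vessel(points=pts, widths=np.array([1.0, 9.0, 10.0, 11.0, 50.0]), kind="venule")
        scene = simple_scene([v])
        assert crve(scene) == pytest.approx(10.0)

    def test_no_vessels_gives_nan(self):
        scene = simple_scene([straight_vessel(10, "venule")])
        assert math.isnan(crae(scene))
        assert crve(scene) > 0


class TestTortuosity:
    def test_straight_is_zero(self):
        scene = simple_scene([straight_vessel()])
        assert vessel_tortuosity(scene) == pytest.approx(0.0, abs=1e-12)

    def test_semicircle(self):
        theta = np.linspace(0, np.pi, 1000)
        pts = np.column_stack([100 + 50 * np.cos(theta), 200 + 50 * np.sin(theta)])
        v = Vessel(points=pts, widths=np.full(1000, 5.0), kind="venule")
        scene = simple_scene([v])
        assert vessel_tortuosity(scene) == pytest.approx(np.pi / 2 - 1, abs=1e-3)

    def test_length_weighted_mean(self):
        # straight (arc 10) + semicircle (arc ~10): weights ~ equal
        straight = Vessel(
            points=np.column_stack([np.linspace(0, 10, 200), np.zeros(200)]),
            widths=np.full(200, 5.0),
            kind="arteriole",
        )
        r = 10 / np.pi
        theta = np.linspace(0, np.pi, 2000)
        semi = Vessel(
            points=np.column_stack([50 + r * np.cos(theta), 50 + r * np.sin(theta)]),
            widths=np.full(2000, 5.0),
            kind="venule",
        )
        scene = simple_scene([straight, semi])
        expected = 0.5 * 0.0 + 0.5 * (np.pi / 2 - 1)
        assert vessel_tortuosity(scene) == pytest.approx(expected, abs=1e-3)

    def test_closed_loop_excluded_with_warning(self):
        theta = np.linspace(0, 2 * np.pi, 100)
        loop = Vessel(
            points=np.column_stack([100 + 10 * np.cos(theta), 100 + 10 * np.sin(theta)]),
            widths=np.full(100, 5.0),
            kind="venule",
        )
        scene = simple_scene([loop, straight_vessel()])
        with pytest.warns(UserWarning, match="zero chord"):
            assert vessel_tortuosity(scene) == pytest.approx(0.0, abs=1e-12)


class TestFractalDimension:
    def test_straight_line_dim_one(self):
        grid = np.zeros((512, 512), dtype=bool)
        grid[256, :] = True
        assert vessel_fd(grid) == pytest.approx(1.0, abs=0.05)

    def test_filled_square_dim_two(self):
        grid = np.zeros((512, 512), dtype=bool)
        grid[:256, :256] = True
        assert vessel_fd(grid) == pytest.approx(2.0, abs=0.1)

    def test_line_matches_manual_box_count_oracle(self):
        grid = np.zeros((512, 512), dtype=bool)
        grid[256, :] = True
        sizes = [128, 64, 32, 16, 8, 4, 2]
        counts = [512 // s for s in sizes]  # exact for an axis-aligned line
        slope = np.polyfit(np.log([1 / s for s in sizes]), np.log(counts), 1)[0]
        assert vessel_fd(grid) == pytest.approx(slope, abs=1e-9)

    def test_sparse_map_sentinel(self):
        grid = np.zeros((128, 128), dtype=bool)
        grid[5, 5] = True
        assert math.isnan(vessel_fd(grid))

    def test_empty_map_sentinel(self):
        assert math.isnan(vessel_fd(np.zeros((128, 128), dtype=bool)))

    def test_small_map_rejected(self):
        with pytest.raises(ValueError, match="64"):
            vessel_fd(np.ones((32, 32), dtype=bool))


class TestArcadeConcavity:
    def _arcade_scene(self, coeff, noise_sd=0.0, seed=0):
        scene = simple_scene()
        od = np.asarray(scene.od_center)
        u = np.asarray(scene.fovea) - od
        u = u / np.linalg.norm(u)
        v = np.array([-u[1], u[0]])
        rng = np.random.default_rng(seed)
        vessels = []
        for sign in (+1, -1):
            y = sign * np.linspace(10, 150, 60)
            x = coeff * y**2
            pts = od + np.outer(x, u) + np.outer(y, v)
            if noise_sd > 0:
                pts = pts + rng.normal(0, noise_sd, pts.shape)
            flag = "superior-temporal" if sign > 0 else "inferior-temporal"
            vessels.append(
                Vessel(points=pts, widths=np.full(60, 8.0), kind="arteriole", arcade=flag)
            )
        scene.vessels = vessels
        return scene

    def test_straight_arcade_zero(self):
        scene = self._arcade_scene(0.0)
        assert arcade_concavity(scene, "arteriole") == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_parabola_exact(self):
        scene = self._arcade_scene(0.05)
        assert arcade_concavity(scene, "arteriole") == pytest.approx(0.05, abs=1e-9)

    def test_noisy_recovery_monte_carlo(self):
        errs = [
            arcade_concavity(self._arcade_scene(0.05, noise_sd=0.5, seed=s), "arteriole") - 0.05
            for s in range(100)
        ]
        assert abs(np.mean(errs)) < 0.01
        assert np.max(np.abs(errs)) < 0.01

    def test_missing_arcade_sentinel(self):
        scene = simple_scene([straight_vessel(kind="venule")])
        assert math.isnan(arcade_concavity(scene, "arteriole"))

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            arcade_concavity(simple_scene(), "capillary")


class TestFpi:
    def test_uniform_grid(self):
        grid = np.full((512, 512), 100.0)
        scene = simple_scene(intensity=grid)
        assert foveal_pixel_intensity(scene) == pytest.approx(100.0)

    def test_half_and_half_boundary(self):
        grid = np.zeros((512, 512))
        grid[:, 350:] = 200.0  # fovea x=350 on the boundary
        scene = simple_scene(intensity=grid)
        got = foveal_pixel_intensity(scene, radius=10)
        # pixel-counting oracle on the same disc
        yy, xx = np.mgrid[0:512, 0:512]
        disc = (xx - 350) ** 2 + (yy - 241) ** 2 <= 100
        assert got == pytest.approx(grid[disc].mean())
        assert got == pytest.approx(100.0, abs=11.0)

    def test_no_grid_sentinel(self):
        assert math.isnan(foveal_pixel_intensity(simple_scene()))

    def test_border_clip_warns(self):
        grid = np.full((512, 512), 50.0)
        scene = simple_scene(intensity=grid, fovea=(3.0, 241.0))
        with pytest.warns(UserWarning, match="border"):
            assert foveal_pixel_intensity(scene) == pytest.approx(50.0)


class TestExtractFeatures:
    def test_no_intensity_only_fpi_missing(self, default_scene):
        scene, _ = default_scene
        scene.intensity = None
        vec = extract_features(scene).as_dict()
        assert math.isnan(vec["fpi"])
        for name, value in vec.items():
            if name != "fpi":
                assert not math.isnan(value), name

    def test_mirrored_scene_pair_identical(self, default_scene):
        scene, _ = default_scene
        a = extract_features(scene).as_dict()
        b = extract_features(mirror_scene(scene)).as_dict()
        for name in a:
            assert b[name] == pytest.approx(a[name], abs=1e-9), name

    def test_homogeneity_under_scaling(self, default_scene):
        scene, _ = default_scene
        scene.intensity = None
        f = 1.25

        def scale_pt(p):
            return (p[0] * f, p[1] * f)

        scaled = FundusScene(
            od_center=scale_pt(scene.od_center),
            od_semi_major=scene.od_semi_major * f,
            od_semi_minor=scene.od_semi_minor * f,
            od_angle=scene.od_angle,
            fovea=scale_pt(scene.fovea),
            vessels=[
                Vessel(points=v.points * f, widths=v.widths * f, kind=v.kind, arcade=v.arcade)
                for v in scene.vessels
            ],
            laterality=scene.laterality,
            frame_size=(int(scene.frame_size[0] * f) + 1, int(scene.frame_size[1] * f) + 1),
        )
        a = extract_features(scene).as_dict()
        b = extract_features(scaled).as_dict()
        assert b["od_fovea_distance"] == pytest.approx(f * a["od_fovea_distance"], rel=1e-9)
        assert b["od_area"] == pytest.approx(f * f * a["od_area"], rel=1e-9)
        assert b["crae"] == pytest.approx(f * a["crae"], rel=1e-9)
        assert b["crve"] == pytest.approx(f * a["crve"], rel=1e-9)
        for invariant in ("od_fovea_angle", "od_orientation", "od_ovality", "tortuosity"):
            assert b[invariant] == pytest.approx(a[invariant], abs=1e-9), invariant
        # concavity scales as 1/f (curvature of a scaled parabola)
        assert b["arterial_concavity"] == pytest.approx(a["arterial_concavity"] / f, rel=1e-9)
        assert b["fd"] == pytest.approx(a["fd"], abs=0.1)

    def test_scene_json_round_trip(self, tmp_path, default_scene):
        scene, _ = default_scene
        p = tmp_path / "scene.json"
        scene.to_json(p)
        loaded = FundusScene.from_json(p)
        a = extract_features(scene).as_dict()
        b = extract_features(loaded).as_dict()
        for name in a:
            assert b[name] == pytest.approx(a[name], nan_ok=True), name
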
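"""Displacement metrics, the active-cargo filter, radial profiles, areas."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

import cargokin as ck
from cargokin.motility import UndefinedMetricError, is_active

from conftest import straight_traj


def square_loop(side=2.0):
    xs = [0, side, side, 0, 0]
    ys = [0, 0, side, side, 0]
    return ck.Trajectory(0, np.arange(5.0), xs, ys)


class TestDisplacement:
    def test_closed_loop_has_zero_net_displacement(self):
        tr = square_loop()
        assert ck.net_displacement(tr) == 0
        assert ck.total_travel(tr) == pytest.approx(8.0)

    def test_straight_path_net_equals_total(self):
        tr = straight_traj(0, np.arange(11.0), 0.0, 0.0, vx=0.5)
        assert ck.net_displacement(tr) == pytest.approx(5.0)
        assert ck.total_travel(tr) == pytest.approx(5.0)

    def test_single_point_is_undefined(self):
        tr = ck.Trajectory(0, [0.0], [1.0], [1.0])
        with pytest.raises(UndefinedMetricError):
            ck.net_displacement(tr)

    def test_net_recomputes_as_endpoint_distance(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 10, size=(30, 2))
        tr = ck.Trajectory(0, np.arange(30.0), xy[:, 0], xy[:, 1])
        assert ck.net_displacement(tr) == pytest.approx(
            float(np.hypot(*(xy[-1] - xy[0])))
        )

    def test_total_at_least_net_on_simulated_tracks(self):
        p = ck.NuclearTrackParams(drift_speed=1e-3, sigma_step=0.3, dt=30, duration=900)
        for tr in ck.simulate_nucleus(p, 1000, seed=7):
            assert ck.total_travel(tr) >= ck.net_displacement(tr) - 1e-12


class TestRadialAlignment:
    def test_pure_radial_motion_scores_zero(self, circle_geom):
        tr = straight_traj(0, np.arange(5.0), 25.0, 20.0, vx=1.0)  # outward on +x
        assert ck.radial_alignment_angle(tr, circle_geom) == pytest.approx(0.0)

    def test_tangential_motion_scores_ninety(self, circle_geom):
        tr = straight_traj(0, np.arange(5.0), 25.0, 20.0, vy=1.0)
        assert ck.radial_alignment_angle(tr, circle_geom) == pytest.approx(90.0)

    def test_axis_symmetry_for_inward_motion(self, circle_geom):
        # 30° off the inward radial direction still reads 30°
        ang = np.radians(180 + 30)  # mostly inward
        tr = straight_traj(
            0, np.arange(5.0), 30.0, 20.0, vx=np.cos(ang), vy=np.sin(ang)
        )
        assert ck.radial_alignment_angle(tr, circle_geom) == pytest.approx(30.0)


class TestActiveFilter:
    def test_travel_threshold_is_strict(self, circle_geom):
        mp = ck.MotilityParams(window=10.0)
        short = straight_traj(0, np.arange(0, 10.0), 25.0, 20.0, vx=2.9 / 9)
        long = straight_traj(1, np.arange(0, 10.0), 25.0, 20.0, vx=3.1 / 9)
        assert not is_active(short, circle_geom, mp)
        assert is_active(long, circle_geom, mp)

    def test_tangential_travel_not_counted(self, circle_geom):
        mp = ck.MotilityParams(window=10.0)
        tang = straight_traj(0, np.arange(0, 10.0), 25.0, 20.0, vy=5.0 / 9)
        assert not is_active(tang, circle_geom, mp)

    def test_counts_match_brute_force_filter(self, circle_geom):
        # 20 mixed trajectories vs an exhaustive manual filter
        rng = np.random.default_rng(3)
        mp = ck.MotilityParams(window=60.0, edge_margin=1.0)
        trajs = []
        t = np.arange(0, 60.0, 5.0)
        for i in range(20):
            x0 = rng.uniform(10, 30)
            y0 = rng.uniform(10, 30)
            ang = rng.uniform(0, 2 * np.pi)
            speed = rng.uniform(0, 0.12)
            trajs.append(
                straight_traj(i, t, x0, y0, vx=speed * np.cos(ang), vy=speed * np.sin(ang))
            )
        got = ck.count_active(trajs, circle_geom, mp, t_total=60.0)
        # brute force: shapely distance for edge, direct angle + travel
        poly = Polygon(circle_geom.boundary)
        n_manual = 0
        for tr in trajs:
            if poly.exterior.distance(Point(tr.x.mean(), tr.y.mean())) <= mp.edge_margin:
                continue
            travel = float(np.hypot(np.diff(tr.x), np.diff(tr.y)).sum())
            if not travel > mp.d_min:
                continue
            d = np.array([tr.x[-1] - tr.x[0], tr.y[-1] - tr.y[0]])
            r = np.array([tr.x[0] - 20.0, tr.y[0] - 20.0])
            cosang = abs(np.dot(d, r)) / (np.linalg.norm(d) * np.linalg.norm(r))
            if np.degrees(np.arccos(np.clip(cosang, 0, 1))) <= mp.theta_max:
                n_manual += 1
        assert got["n_active"].iloc[0] == n_manual

    def test_normalization_uses_first_window(self, circle_geom):
        mp = ck.MotilityParams(window=10.0)
        t1 = np.arange(0, 10.0)
        t2 = np.arange(10.0, 20.0)
        fast = [straight_traj(i, t1, 24.0 + i, 20.0, vx=0.5) for i in range(2)]
        slow = [straight_traj(9, t2, 24.0, 20.0, vx=0.5)]
        df = ck.count_active(fast + slow, circle_geom, mp, t_total=20.0)
        assert list(df["n_active"]) == [2, 1]
        assert list(df["normalized"]) == [1.0, 0.5]

    def test_monotone_in_thresholds(self, circle_geom):
        rng = np.random.default_rng(8)
        t = np.arange(0, 30.0)
        trajs = [
            straight_traj(
                i, t, rng.uniform(12, 28), rng.uniform(12, 28),
                vx=rng.uniform(-0.2, 0.2), vy=rng.uniform(-0.2, 0.2),
            )
            for i in range(15)
        ]

        def count(d_min, theta_max):
            mp = ck.MotilityParams(theta_max=theta_max, d_min=d_min, window=30.0)
            return sum(is_active(tr, circle_geom, mp) for tr in trajs)

        assert count(2.0, 45) >= count(4.0, 45)  # non-increasing in d_min
        assert count(2.0, 60) >= count(2.0, 30)  # non-decreasing in theta_max


class TestEdgeExclusion:
    def test_zero_margin_is_identity(self, circle_geom):
        trajs = [straight_traj(0, np.arange(3.0), 25.0, 20.0)]
        assert ck.exclude_edge(trajs, circle_geom, 0.0) == trajs

    def test_boundary_hugger_removed(self, circle_geom):
        hug = straight_traj(0, np.arange(3.0), 39.4, 20.0)  # ~0.5 µm from edge
        inner = straight_traj(1, np.arange(3.0), 25.0, 20.0)
        kept = ck.exclude_edge([hug, inner], circle_geom, 1.0)
        assert [tr.id for tr in kept] == [1]

    def test_matches_point_to_segment_oracle(self, circle_geom):
        rng = np.random.default_rng(5)
        trajs = [
            straight_traj(i, np.arange(3.0), rng.uniform(5, 35), rng.uniform(5, 35))
            for i in range(30)
        ]
        kept = {tr.id for tr in ck.exclude_edge(trajs, circle_geom, 2.0)}

        def seg_dist(p, a, b):
            ab = b - a
            t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
            return np.linalg.norm(p - (a + t * ab))

        verts = circle_geom.boundary
        for tr in trajs:
            p = np.array([tr.x.mean(), tr.y.mean()])
            d = min(
                seg_dist(p, verts[k], verts[(k + 1) % len(verts)])
                for k in range(len(verts))
            )
            assert (tr.id in kept) == (d > 2.0)


class TestRadialProfile:
    def test_uniform_image_matches_annulus_pixel_counts(self, circle_geom):
        img = np.ones((401, 401))
        prof = ck.radial_profile(img, circle_geom, bin_width=5.0, pixel_size=0.1)
        # oracle: per-pixel distances inside the polygon mask
        from skimage.draw import polygon2mask

        mask = polygon2mask(img.shape, circle_geom.boundary[:, ::-1] / 0.1)
        rr, cc = np.nonzero(mask)
        d = np.hypot(cc * 0.1 - 20.0, rr * 0.1 - 20.0)
        counts = [
            ((d >= lo) & (d < hi)).sum()
            for lo, hi in zip(prof.bin_edges[:-1], prof.bin_edges[1:])
        ]
        # final bin also holds d == last edge by closure
        assert prof.summed_intensity.sum() == mask.sum()
        np.testing.assert_allclose(prof.summed_intensity[:-1], counts[:-1])

    def test_point_mass_lands_in_its_distance_bin(self, circle_geom):
        img = np.zeros((401, 401))
        img[200, 300] = 7.0  # 10 µm right of the centre
        prof = ck.radial_profile(img, circle_geom, bin_width=3.0, pixel_size=0.1)
        nz = np.nonzero(prof.summed_intensity)[0]
        assert list(nz) == [3]  # 10 µm falls in bin [9, 12)
        assert prof.summed_intensity[3] == 7.0

    def test_total_intensity_conserved_exactly(self, circle_geom):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 10, (401, 401))
        prof = ck.radial_profile(img, circle_geom, bin_width=2.0, pixel_size=0.1)
        from skimage.draw import polygon2mask

        mask = polygon2mask(img.shape, circle_geom.boundary[:, ::-1] / 0.1)
        assert prof.total == pytest.approx(img[mask].sum(), rel=1e-12)

    def test_oversized_bin_gives_single_bin_with_warning(self, circle_geom):
        img = np.ones((401, 401))
        with pytest.warns(UserWarning, match="single-bin"):
            prof = ck.radial_profile(img, circle_geom, bin_width=100.0, pixel_size=0.1)
        assert len(prof.summed_intensity) == 1


class TestAreaRatio:
    def test_identical_images_give_unity(self, clean_render):
        img, _ = ck.render_size_population([0.8] * 10, clean_render, seed=0)
        assert ck.area_ratio(img, img, 0.1) == 1.0

    def test_sqrt2_radius_scaling_doubles_area(self, clean_render):
        A = np.pi * 0.5**2
        ref, _ = ck.render_size_population([A] * 40, clean_render, seed=1)
        test, _ = ck.render_size_population([2 * A] * 40, clean_render, seed=2)
        assert ck.area_ratio(test, ref, 0.1) == pytest.approx(2.0, abs=0.05)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="no connected components"):
            ck.area_ratio(np.zeros((10, 10)), np.ones((10, 10)), 0.1)
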
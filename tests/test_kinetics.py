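"""Kymographs, run segmentation, and kinetics statistics vs oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cargokin as ck
from cargokin.kinetics import processive_runs

from conftest import straight_traj


@pytest.fixture
def sp_clean():
    return ck.SegmentationParams(L_min=1.0, v_pause=0.1, eps_v=0.2, min_dur=0.3)


class TestKymograph:
    def test_uniform_image_gives_constant_matrix(self):
        stack = np.full((4, 50, 50), 7.0)
        path = ck.KymographPath(np.array([[0.5, 2.0], [4.0, 2.0]]), width=0.6)
        kymo = ck.extract_kymograph(stack, path, 0.1)
        assert np.allclose(kymo, 7.0)

    def test_moving_spot_traces_ridge_of_slope_v(self, clean_render):
        dt, v = 0.5, 0.8
        t = np.arange(0, 5.0 + 1e-9, dt)
        tr = straight_traj(0, t, 1.0, 3.0, vx=v)
        stack, _ = ck.render_stack([tr], clean_render, (60, 80))
        path = ck.KymographPath(np.array([[0.0, 3.0], [7.9, 3.0]]), width=1.0)
        kymo = ck.extract_kymograph(stack, path, 0.1)
        ridge = kymo.argmax(axis=0) * 0.1
        slope = np.polyfit(t, ridge, 1)[0]
        assert slope == pytest.approx(v, rel=0.05)

    def test_static_spot_gives_vertical_ridge(self, clean_render):
        t = np.arange(0, 3.0, 0.5)
        tr = straight_traj(0, t, 2.0, 3.0)
        stack, _ = ck.render_stack([tr], clean_render, (60, 60))
        path = ck.KymographPath(np.array([[0.0, 3.0], [5.9, 3.0]]), width=1.0)
        kymo = ck.extract_kymograph(stack, path, 0.1)
        assert len(set(kymo.argmax(axis=0))) == 1

    def test_path_outside_image_rejected(self):
        stack = np.zeros((2, 20, 20))
        path = ck.KymographPath(np.array([[0.0, 1.0], [5.0, 1.0]]), width=0.5)
        with pytest.raises(ValueError, match="exits the image"):
            ck.extract_kymograph(stack, path, 0.1)


class TestProjection:
    def test_traversal_of_the_path_is_monotone_to_length(self):
        path = ck.KymographPath(np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 4.0]]))
        t = np.linspace(0, 1, 8)
        # walk along the two legs
        xs = np.concatenate([np.linspace(0, 3, 4), np.full(4, 3.0)])
        ys = np.concatenate([np.zeros(4), np.linspace(1, 4, 4)])
        tr = ck.Trajectory(0, np.arange(8.0), xs, ys)
        s = ck.project_trajectory(tr, path)
        assert np.all(np.diff(s) > 0)
        assert s[-1] == pytest.approx(7.0)

    def test_static_point_has_constant_s(self):
        path = ck.KymographPath(np.array([[0.0, 0.0], [5.0, 0.0]]))
        tr = straight_traj(0, np.arange(4.0), 2.0, 0.1)
        s = ck.project_trajectory(tr, path)
        assert np.allclose(s, 2.0)

    def test_off_path_point_rejected(self):
        path = ck.KymographPath(np.array([[0.0, 0.0], [5.0, 0.0]]), width=0.5)
        tr = straight_traj(0, np.arange(2.0), 2.0, 1.0)
        with pytest.raises(ValueError, match="off-path"):
            ck.project_trajectory(tr, path)

    def test_matches_dense_discretization_oracle(self):
        path = ck.KymographPath(
            np.array([[0.0, 0.0], [2.0, 1.0], [4.0, 0.5], [6.0, 2.0]]), width=1.0
        )
        rng = np.random.default_rng(6)
        # jittered points near the polyline
        base = np.linspace(0.2, 5.8, 15)
        xs = base + rng.uniform(-0.1, 0.1, 15)
        ys = np.interp(base, [0, 2, 4, 6], [0, 1, 0.5, 2]) + rng.uniform(-0.2, 0.2, 15)
        tr = ck.Trajectory(0, np.arange(15.0), xs, ys)
        s = ck.project_trajectory(tr, path)
        # oracle: nearest of 20001 densely sampled path points
        from shapely.geometry import LineString

        line = LineString(path.polyline)
        sg = np.linspace(0, line.length, 20001)
        pg = np.array([line.interpolate(v).coords[0] for v in sg])
        for k in range(15):
            d = np.hypot(pg[:, 0] - xs[k], pg[:, 1] - ys[k])
            assert abs(s[k] - sg[d.argmin()]) < 2 * line.length / 20000 + 1e-6


class TestSegmentation:
    def test_constant_velocity_is_one_run(self, sp_clean):
        t = np.arange(0, 5.0 + 1e-9, 0.1)
        segs = ck.segment_runs(1.0 * t, sp_clean, dt=0.1)
        runs = processive_runs(segs)
        assert len(segs) == 1 and len(runs) == 1
        assert runs[0].velocity == pytest.approx(1.0)
        assert runs[0].length == pytest.approx(5.0)
        assert runs[0].direction == "plus"

    def test_reversal_splits_into_two_opposite_runs(self, sp_clean):
        t = np.arange(0, 2.0, 0.1)
        s = np.concatenate([t, 2.0 - 0.1 - t])  # +1 then −1 µm/s
        segs = ck.segment_runs(s, sp_clean, dt=0.1)
        runs = processive_runs(segs)
        assert [r.direction for r in runs] == ["plus", "minus"]
        for r in runs:
            assert r.length == pytest.approx(1.9, abs=0.01)
            assert np.sign(r.velocity) == (1 if r.direction == "plus" else -1)

    def test_boundaries_match_exhaustive_changepoint_fit(self, sp_clean):
        # noisy 3-phase series, <= 60 samples: boundaries within 1 sample of
        # the RSS-optimal two-change-point piecewise-constant velocity fit
        rng = np.random.default_rng(13)
        dt = 0.1
        v_true = np.concatenate([np.full(20, 1.0), np.full(20, -0.8), np.full(19, 0.0)])
        v_noisy = v_true + rng.normal(0, 0.05, 59)
        s = np.concatenate([[0.0], np.cumsum(v_noisy) * dt])
        best, best_rss = None, np.inf
        for c1, c2 in itertools.combinations(range(1, 59), 2):
            rss = 0.0
            for lo, hi in ((0, c1), (c1, c2), (c2, 59)):
                seg = v_noisy[lo:hi]
                rss += ((seg - seg.mean()) ** 2).sum()
            if rss < best_rss:
                best_rss, best = rss, (c1, c2)
        segs = ck.segment_runs(s, sp_clean, dt=dt)
        got = [int(round(sg.t_end / dt)) for sg in segs[:-1]]
        assert len(got) == 2
        assert abs(got[0] - best[0]) <= 1
        assert abs(got[1] - best[1]) <= 1

    def test_segments_partition_time_axis(self, sp_clean):
        (track,) = ck.simulate_cargo(ck.MotorModelParams(), 1, 60, 0.1, seed=17)
        segs = ck.segment_runs(track.s, sp_clean, dt=0.1)
        assert segs[0].t_start == 0.0
        assert segs[-1].t_end == pytest.approx(60.0)
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.t_end == pytest.approx(b.t_start)
        for sg in segs:
            assert sg.velocity == pytest.approx(
                (sg.s_end - sg.s_start) / sg.duration
            )
            assert sg.length == pytest.approx(abs(sg.velocity) * sg.duration)

    def test_non_uniform_sampling_rejected(self, sp_clean):
        t = np.array([0.0, 0.1, 0.3, 0.4])
        with pytest.raises(ValueError, match="non-uniform"):
            ck.segment_runs(np.zeros(4), sp_clean, t=t)


class TestStatistics:
    def _run(self, v, dur=3.0, t0=0.0):
        return ck.RunSegment(
            t0, t0 + dur, 0.0, v * dur, v,
            "plus" if v > 0 else "minus", True,
        )

    def test_velocity_stats_by_direction(self):
        segs = [self._run(1.0), self._run(1.0), self._run(-1.0)]
        vs = ck.velocity_stats(segs, L_min=1.0)
        assert vs["plus"]["mean"] == pytest.approx(1.0)
        assert vs["minus"]["mean"] == pytest.approx(-1.0)
        assert vs["plus"]["n"] == 2 and vs["minus"]["n"] == 1

    def test_single_direction_leaves_other_empty(self):
        vs = ck.velocity_stats([self._run(0.8)], L_min=1.0)
        assert vs["plus"]["mean"] == pytest.approx(0.8)
        assert vs["minus"]["n"] == 0

    def test_fraction_minus_simple_counts(self):
        segs = [self._run(-1.0)] * 3 + [self._run(1.0)] * 2
        f, ci = ck.fraction_minus(segs)
        assert f == pytest.approx(0.6)
        assert ci[0] < 0.6 < ci[1]
        f_all, _ = ck.fraction_minus([self._run(-1.0)] * 4)
        assert f_all == 1.0

    def test_fraction_minus_needs_runs(self):
        with pytest.raises(ValueError):
            ck.fraction_minus([])

    def test_runlength_mle_closed_form(self):
        fit = ck.fit_runlength(np.array([1.5, 2.0, 2.5]), L_min=1.0)
        assert fit["mu"] == pytest.approx(1.0)
        assert not fit["degenerate"]

    def test_degenerate_fit_flagged(self):
        fit = ck.fit_runlength(np.array([1.0, 1.0, 1.0]), L_min=1.0)
        assert fit["mu"] == pytest.approx(0.0)
        assert fit["degenerate"]

    def test_runlength_recovery_from_truncated_exponential(self):
        # 1e3 draws, mu=2, truncation at 1: MLE CI covers the truth
        rng = np.random.default_rng(19)
        x = 1.0 + rng.exponential(2.0, 1000)
        fit = ck.fit_runlength(x, L_min=1.0)
        assert fit["ci"][0] < 2.0 < fit["ci"][1]
        lsq = ck.fit_runlength(x, L_min=1.0, method="lsq")
        assert lsq["mu"] == pytest.approx(fit["mu"], rel=0.15)

    @given(
        st.lists(st.floats(min_value=1.0, max_value=50.0), min_size=3, max_size=40)
    )
    @settings(max_examples=50, deadline=None)
    def test_mle_equals_mean_minus_threshold(self, lengths):
        fit = ck.fit_runlength(np.array(lengths), L_min=1.0)
        assert fit["mu"] == pytest.approx(np.mean(lengths) - 1.0, abs=1e-12)

    def test_simulated_cargo_velocities_recovered(self):
        p = ck.MotorModelParams()
        tracks = ck.simulate_cargo(p, 20, 120, 0.1, seed=23)
        segs = []
        for tr in tracks:
            segs += ck.segment_runs(tr.s, ck.SegmentationParams(), dt=0.1)
        vs = ck.velocity_stats(segs, L_min=1.0)
        for lab, sign in (("plus", 1), ("minus", -1)):
            m, sd, n = vs[lab]["mean"], vs[lab]["sd"], vs[lab]["n"]
            assert abs(m - sign * 1.0) < 3 * sd / np.sqrt(n) + 0.05
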
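"""Movement metrics: path length, rediscretization, sinuosity, edge affinity."""
import math

import numpy as np
import pytest
from scipy.special import i0, i1

import tribomove as tm
from tribomove.exceptions import (
    DegenerateArenaError,
    DegeneratePathError,
    MissingScaleError,
)
from tribomove.metrics import (
    rediscretize,
    sinuosity_from_stats,
    turning_stats,
    wrap_angle,
)
from tribomove.simulate import CrwParams, gen_crw_track

from conftest import make_track_xy


def track_from_xy(xy, frames=None):
    xy = np.asarray(xy, dtype=float)
    if frames is None:
        frames = np.arange(len(xy))
    return tm.Track("t", frames, xy)


def oracle_rediscretize(xy, p, factor=10_000):
    """Dense-resampling oracle: oversample the polyline at p/factor arc
    steps, then greedily take the first dense interval where the distance
    from the previous anchor crosses p, interpolating the crossing."""
    seg = np.diff(xy, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    ds = p / factor
    si = np.arange(0.0, s[-1], ds)
    dx = np.interp(si, s, xy[:, 0])
    dy = np.interp(si, s, xy[:, 1])
    anchors = [(dx[0], dy[0])]
    start = 1
    while True:
        ax, ay = anchors[-1]
        d = np.hypot(dx[start:] - ax, dy[start:] - ay)
        hits = d >= p
        if not hits.any():
            break
        k = int(np.argmax(hits))
        j = start + k
        if k == 0:
            anchors.append((dx[j], dy[j]))
        else:
            d0, d1 = d[k - 1], d[k]
            w = (p - d0) / (d1 - d0)
            anchors.append(
                (dx[j - 1] + w * (dx[j] - dx[j - 1]), dy[j - 1] + w * (dy[j] - dy[j - 1]))
            )
        start = j
    return np.array(anchors)


class TestPathLength:
    def test_three_four_five_over_one_second(self):
        t = track_from_xy([[0.0, 0.0], [3.0, 4.0]], frames=[0, 25])
        assert tm.path_length_rate(t, fps=25.0) == pytest.approx(5.0)

    def test_stationary_track(self):
        t = track_from_xy([[2.0, 2.0]] * 5)
        assert tm.path_length_rate(t, fps=25.0) == 0.0

    def test_short_track_undefined(self):
        with pytest.raises(DegeneratePathError):
            tm.path_length_rate(track_from_xy([[0.0, 0.0]]), fps=25.0)

    def test_matches_brute_force(self, rng):
        xy = rng.normal(size=(50, 2))
        t = track_from_xy(xy)
        brute = math.fsum(
            math.hypot(xy[i + 1, 0] - xy[i, 0], xy[i + 1, 1] - xy[i, 1])
            for i in range(49)
        )
        assert tm.path_length_rate(t, fps=25.0) == pytest.approx(brute / (49 / 25.0), rel=1e-12)

    def test_gap_contributes_chord_and_elapsed_time(self):
        # frames 0 and 50: one 2 s gap spanned by a straight chord
        t = track_from_xy([[0.0, 0.0], [10.0, 0.0]], frames=[0, 50])
        assert tm.path_length_rate(t, fps=25.0) == pytest.approx(5.0)


class TestRediscretize:
    def test_straight_segment(self):
        rp = rediscretize(np.array([[0.0, 0.0], [10.0, 0.0]]), p=2.0)
        np.testing.assert_allclose(rp.points[:, 0], [0, 2, 4, 6, 8, 10], atol=1e-12)
        np.testing.assert_allclose(rp.points[:, 1], 0.0, atol=1e-12)

    def test_right_angle_three_four_five(self):
        # the 3-4-5 circle-segment intersection lands on the vertical leg
        rp = rediscretize(np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 5.0]]), p=5.0)
        np.testing.assert_allclose(rp.points[1], [3.0, 4.0], atol=1e-12)

    def test_too_short_path_undefined(self):
        with pytest.raises(DegeneratePathError):
            rediscretize(np.array([[0.0, 0.0], [1.0, 0.0]]), p=5.0)

    def test_constant_chords_and_oracle_agreement(self, rng):
        p = 5.0
        for _ in range(6):
            xy = make_track_xy(rng, n_points=200, step=p / 3)
            rp = rediscretize(xy, p)
            chords = np.hypot(*np.diff(rp.points, axis=0).T)
            np.testing.assert_allclose(chords, p, rtol=1e-9)
            oracle = oracle_rediscretize(xy, p)
            m = min(len(oracle), rp.n)
            assert m >= rp.n - 1
            np.testing.assert_allclose(rp.points[:m], oracle[:m], atol=1e-6 * p)

    def test_idempotent_on_constant_step_path(self, rng):
        xy = make_track_xy(rng, n_points=100, step=4.0)
        rp = rediscretize(xy, 4.0)
        again = rediscretize(rp, 4.0)
        m = min(rp.n, again.n)
        np.testing.assert_allclose(again.points[:m], rp.points[:m], atol=1e-8)


class TestTurningStats:
    def test_collinear_points(self):
        ts = turning_stats(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]))
        np.testing.assert_allclose(ts.angles, 0.0, atol=1e-12)
        assert ts.c == pytest.approx(1.0)

    def test_square_spiral_left_turns(self):
        # unit steps turning +90 deg each time: all angles +pi/2, c = 0
        xy, h = [[0.0, 0.0]], 0.0
        for _ in range(12):
            xy.append([xy[-1][0] + math.cos(h), xy[-1][1] + math.sin(h)])
            h += math.pi / 2
        ts = turning_stats(np.array(xy))
        np.testing.assert_allclose(ts.angles, math.pi / 2, atol=1e-12)
        assert ts.c == pytest.approx(0.0, abs=1e-12)
        assert ts.b == 0.0

    def test_wrap_angle_interval(self):
        a = wrap_angle([math.pi, -math.pi, 3 * math.pi / 2, 0.0, -3.0, 3.0])
        assert np.all((a > -math.pi) & (a <= math.pi))
        np.testing.assert_allclose(a, [math.pi, math.pi, -math.pi / 2, 0.0, -3.0, 3.0])

    def test_von_mises_mean_cosine_matches_bessel_ratio(self, rng):
        kappa, n = 2.0, 40_000
        angles = rng.vonmises(0.0, kappa, size=n)
        # build a path whose turning angles are exactly `angles`
        headings = np.concatenate([[0.0], np.cumsum(angles)])
        xy = np.zeros((n + 2, 2))
        xy[1:, 0] = np.cumsum(np.cos(headings))
        xy[1:, 1] = np.cumsum(np.sin(headings))
        ts = turning_stats(xy)
        expected = i1(kappa) / i0(kappa)
        se = np.std(np.cos(angles), ddof=1) / math.sqrt(n)
        assert abs(ts.c - expected) < 3 * se


class TestSinuosity:
    def test_straight_path_is_zero(self):
        assert tm.sinuosity(np.array([[0.0, 0.0], [50.0, 0.0]]), p=2.0) == 0.0

    def test_alternating_right_angles_gives_two(self):
        xy, h = [[0.0, 0.0]], 0.0
        for i in range(40):
            h += math.pi / 2 * (1 if i % 2 == 0 else -1)
            xy.append([xy[-1][0] + math.cos(h), xy[-1][1] + math.sin(h)])
        assert tm.sinuosity(np.array(xy), p=1.0) == pytest.approx(2.0, rel=1e-9)

    def test_formula_limits(self):
        assert sinuosity_from_stats(4.0, c=1.0) == 0.0
        with pytest.raises(DegeneratePathError):
            sinuosity_from_stats(4.0, c=-1.0, b=0.0)
        # c=-1 with b>0 stays finite: S = 2/sqrt(p b^2)
        assert sinuosity_from_stats(4.0, c=-1.0, b=0.5) == pytest.approx(
            2.0 / math.sqrt(4.0 * 0.25)
        )

    def test_crw_recovery_small_scale(self, rng):
        kappa, p = 1.0, 2.0
        c = i1(kappa) / i0(kappa)
        s_true = 2.0 / math.sqrt(p * (1 + c) / (1 - c))
        params = CrwParams(kappa=kappa, step_mm_per_frame=p, step_cv=0.0,
                           arena_mm=3000.0, mm_per_px=1.0, duration_s=120.0,
                           n_individuals=1)
        ests = [tm.sinuosity(gen_crw_track(params, rng).xy, p) for _ in range(50)]
        se = np.std(ests, ddof=1) / math.sqrt(len(ests))
        assert abs(np.mean(ests) - s_true) < 3 * se

    def test_p10_p20_consistency_on_long_smooth_crw(self, rng):
        # doubling the rediscretization distance must not change the
        # estimate qualitatively when the path is well resolved (sampling
        # step well below both p values)
        params = CrwParams(kappa=50.0, step_mm_per_frame=2.0, step_cv=0.0,
                           arena_mm=30000.0, mm_per_px=1.0, duration_s=1200.0,
                           n_individuals=1)
        t = gen_crw_track(params, rng)
        s10 = tm.sinuosity(t.xy, 10.0)
        s20 = tm.sinuosity(t.xy, 20.0)
        assert s20 == pytest.approx(s10, rel=0.05)


class TestEdgeAffinity:
    @staticmethod
    def _rec(xy, mm_per_px=0.5):
        return tm.ReplicateRecording(
            "r", "L01", "low", "1", "1", mm_per_px=mm_per_px,
            tracks=[tm.Track("t", np.arange(len(xy)), np.asarray(xy, float))],
        )

    def test_all_on_bounding_box(self):
        xy = [[0.0, 0.0], [100.0, 0.0], [100.0, 100.0], [0.0, 100.0]]
        assert tm.edge_affinity(self._rec(xy), margin_mm=10.0) == 1.0

    def test_degenerate_bounds_error(self):
        with pytest.raises(DegenerateArenaError):
            tm.edge_affinity(self._rec([[5.0, 5.0], [5.0, 5.0]]), margin_mm=10.0)

    def test_missing_scale_error(self):
        rec = self._rec([[0.0, 0.0], [100.0, 100.0]], mm_per_px=None)
        with pytest.raises(MissingScaleError, match="mm_per_px"):
            tm.edge_affinity(rec)

    def test_uniform_grid_matches_brute_force(self):
        # 20x20 grid over a 100 mm square at 0.5 mm/px, margin 10 mm
        g = np.linspace(0.0, 200.0, 20)  # px; 200 px = 100 mm
        xx, yy = np.meshgrid(g, g)
        xy = np.column_stack([xx.ravel(), yy.ravel()])
        rec = self._rec(xy, mm_per_px=0.5)
        m_px = 10.0 / 0.5
        brute = sum(
            1
            for x, y in xy
            if x <= m_px or x >= 200 - m_px or y <= m_px or y >= 200 - m_px
        )
        assert tm.edge_affinity(rec, margin_mm=10.0) == pytest.approx(brute / 400)


class TestSummarize:
    def test_single_track_identity(self, rng):
        params = CrwParams(duration_s=20.0, n_individuals=1)
        rec = tm.gen_crw_replicate(
            params,
            {"replicate_id": "r", "line_id": "H01", "regime": "high",
             "block_id": "1", "camera_id": "1"},
            rng,
        )
        s = tm.summarize_replicate(rec, p_values=(10.0,))
        t = rec.tracks[0]
        assert s.path_length_px_per_s == pytest.approx(tm.path_length_rate(t, rec.fps))
        assert s.sinuosity[10.0] == pytest.approx(tm.sinuosity(t.xy, 10.0))
        assert s.edge_affinity == pytest.approx(tm.edge_affinity(rec))

    def test_equal_duration_rates_average(self):
        t1 = tm.Track("a", [0, 25], [[0.0, 0.0], [10.0, 0.0]])   # 10 px/s
        t2 = tm.Track("b", [0, 25], [[0.0, 0.0], [0.0, 20.0]])   # 20 px/s
        rec = tm.ReplicateRecording("r", "L01", "low", "1", "1", tracks=[t1, t2])
        s = tm.summarize_replicate(rec, p_values=())
        assert s.path_length_px_per_s == pytest.approx(15.0)

    def test_duration_weighted_oracle(self, small_replicate):
        s = tm.summarize_replicate(small_replicate, p_values=())
        total_d = sum(
            np.hypot(*np.diff(t.xy, axis=0).T).sum() for t in small_replicate.tracks
        )
        total_t = sum(t.duration_s(small_replicate.fps) for t in small_replicate.tracks)
        assert s.path_length_px_per_s == pytest.approx(total_d / total_t, rel=1e-12)

    def test_undefined_components_are_missing_not_fatal(self):
        rec = tm.ReplicateRecording(
            "r", "L01", "low", "1", "1",
            tracks=[tm.Track("t", [0, 1], [[0.0, 0.0], [1.0, 0.0]])],
        )
        s = tm.summarize_replicate(rec, p_values=(50.0,))
        assert s.sinuosity[50.0] is None
        assert s.edge_affinity is None  # no mm_per_px
        assert s.path_length_px_per_s is not None
        assert s.notes


class TestRigidMotionInvariance:
    @staticmethod
    def _transform(xy, theta, shift):
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        return xy @ rot.T + shift

    def test_path_rate_and_sinuosity_under_rotation_translation(self, rng):
        xy = make_track_xy(rng, n_points=300, step=4.0)
        t0 = track_from_xy(xy)
        rate0 = tm.path_length_rate(t0, 25.0)
        s0 = tm.sinuosity(xy, 10.0)
        for _ in range(20):
            theta = rng.uniform(0, 2 * math.pi)
            shift = rng.uniform(-500, 500, size=2)
            xyt = self._transform(xy, theta, shift)
            assert tm.path_length_rate(track_from_xy(xyt), 25.0) == pytest.approx(rate0, rel=1e-9)
            assert tm.sinuosity(xyt, 10.0) == pytest.approx(s0, rel=1e-6)

    def test_scaling_laws(self, rng):
        xy = make_track_xy(rng, n_points=200, step=4.0)
        rate0 = tm.path_length_rate(track_from_xy(xy), 25.0)
        s0 = tm.sinuosity(xy, 10.0)
        for s in (0.5, 2.0, 7.3):
            assert tm.path_length_rate(track_from_xy(xy * s), 25.0) == pytest.approx(
                s * rate0, rel=1e-9
            )
            assert tm.sinuosity(xy * s, 10.0 * s) == pytest.approx(
                s0 / math.sqrt(s), rel=1e-9
            )


class TestGroundTruth:
    def test_identical_vectors(self):
        g = tm.ground_truth_agreement([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert g.r == pytest.approx(1.0)

    def test_anti_ordered_linear(self):
        g = tm.ground_truth_agreement([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert g.r == pytest.approx(-1.0)

    def test_matches_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 6.0, 9.0])
        cov = np.sum((x - x.mean()) * (y - y.mean()))
        r_oracle = cov / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        g = tm.ground_truth_agreement(x, y)
        assert g.r == pytest.approx(r_oracle, rel=1e-12)
        assert g.ci_low < g.r < g.ci_high

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError, match="zero variance"):
            tm.ground_truth_agreement([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
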
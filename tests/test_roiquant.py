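import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ulmpipe.maps import accumulate
from ulmpipe.roiquant import (FitError, ROIPolygon, fit_parabola, hobby_curve,
                              median_velocity, rasterize_roi, roi_metrics,
                              roi_soam, soam, split_arteriole_venule,
                              track_in_roi, vascularity, vessel_profile)
from ulmpipe.phantom import make_vessel_tree, simulate_tracks
from ulmpipe.track import Track

SP = 4.928


def _segments_intersect(p, q, a, b):
    def ccw(u, v, w):
        return (w[1] - u[1]) * (v[0] - u[0]) > (v[1] - u[1]) * (w[0] - u[0])
    return (ccw(p, a, b) != ccw(q, a, b)) and (ccw(p, q, a) != ccw(p, q, b))


class TestHobbyCurve:
    def test_square_symmetric_under_input_rotation(self):
        sq = np.array([[0.0, 0.0], [0.0, 100.0], [100.0, 100.0], [100.0, 0.0]])
        c1 = hobby_curve(sq)[:-1]
        c2 = hobby_curve(np.roll(sq, -1, axis=0))[:-1]
        s1 = {tuple(p) for p in np.round(c1, 6)}
        s2 = {tuple(p) for p in np.round(c2, 6)}
        assert s1 == s2

    def test_passes_through_all_vertices(self):
        rng = np.random.default_rng(3)
        verts = rng.uniform(50, 450, size=(6, 2))
        curve = hobby_curve(verts)
        for v in verts:
            assert np.min(np.hypot(*(curve - v).T)) < 1e-9

    def test_circle_deviation_below_1pct(self):
        theta = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        R = 150.0
        verts = np.stack([300 + R * np.sin(theta), 300 + R * np.cos(theta)], 1)
        curve = hobby_curve(verts)
        r = np.hypot(curve[:, 0] - 300, curve[:, 1] - 300)
        assert np.abs(r - R).max() < 0.01 * R

    def test_collinear_triple_no_self_intersection(self):
        verts = np.array([[0.0, 0.0], [0.0, 50.0], [0.0, 100.0], [80.0, 50.0]])
        curve = hobby_curve(verts, samples_per_segment=25)
        segs = list(zip(curve[:-1], curve[1:]))
        for i in range(len(segs)):
            for j in range(i + 2, len(segs)):
                if i == 0 and j == len(segs) - 1:
                    continue  # closing joint shares an endpoint
                assert not _segments_intersect(*segs[i], *segs[j])

    def test_errors(self):
        with pytest.raises(ValueError):
            hobby_curve(np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValueError, match="duplicate"):
            hobby_curve(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))


class TestRasterize:
    def test_square_area(self):
        # square spanning exactly 10x10 pixel centres (half-pixel inset avoids
        # the on-boundary ambiguity of the even-odd rule)
        lo, hi = -0.5 * SP, 9.5 * SP
        curve = np.array([[lo, lo], [lo, hi], [hi, hi], [hi, lo], [lo, lo]])
        mask = rasterize_roi(curve, (20, 20), SP)
        assert mask.sum() == 100

    def test_translation(self):
        lo, hi = -0.5 * SP, 7.5 * SP
        sq = np.array([[lo, lo], [lo, hi], [hi, hi], [hi, lo], [lo, lo]])
        m1 = rasterize_roi(sq, (32, 32), SP)
        m2 = rasterize_roi(sq + 5 * SP, (32, 32), SP)
        assert np.array_equal(np.roll(np.roll(m1, 5, 0), 5, 1), m2)

    def test_circle_area_within_2pct(self):
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        R = 40 * SP
        verts = np.stack([60 * SP + R * np.sin(theta), 60 * SP + R * np.cos(theta)], 1)
        mask = rasterize_roi(hobby_curve(verts), (120, 120), SP)
        assert mask.sum() * SP ** 2 == pytest.approx(np.pi * R ** 2, rel=0.02)

    def test_open_curve_rejected(self):
        with pytest.raises(ValueError, match="closed"):
            rasterize_roi(np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 10.0]]), (8, 8), SP)


def _straight_track(z_px, x0_px, x1_px, speed_um=5.0):
    n = int(abs(x1_px - x0_px) * SP / speed_um) + 1
    xs = x0_px * SP + speed_um * np.arange(n)     # exact step length
    pts = np.stack([np.full(n, z_px * SP), xs], 1)
    return Track(np.arange(n), pts, 1000.0)


class TestVascularity:
    def test_no_tracks_zero(self):
        vmap = accumulate([], (32, 32), SP)
        roi = ROIPolygon(np.array([[2 * SP, 2 * SP], [2 * SP, 28 * SP],
                                   [28 * SP, 28 * SP], [28 * SP, 2 * SP]]))
        assert vascularity(vmap, roi.mask((32, 32), SP)) == 0.0

    def test_full_density_100(self):
        t = [_straight_track(z, 1, 30) for z in range(32)]
        vmap = accumulate(t, (32, 32), SP)
        mask = np.zeros((32, 32), bool)
        mask[5:20, 5:20] = True
        assert vascularity(vmap, mask) == 100.0

    def test_empty_mask_error(self):
        vmap = accumulate([], (16, 16), SP)
        with pytest.raises(ValueError):
            vascularity(vmap, np.zeros((16, 16), bool))


class TestMedianVelocity:
    def test_uniform(self):
        t = [_straight_track(z, 1, 30, speed_um=5.0) for z in range(5, 10)]
        vmap = accumulate(t, (32, 32), SP)
        mask = np.ones((32, 32), bool)
        assert median_velocity(vmap, mask) == pytest.approx(5.0)

    def test_two_halves_median(self):
        slow = [_straight_track(z, 1, 30, speed_um=4.0) for z in range(4, 8)]
        fast = [_straight_track(z, 1, 30, speed_um=6.0) for z in range(20, 24)]
        vmap = accumulate(slow + fast, (32, 32), SP)
        mask = np.ones((32, 32), bool)
        assert median_velocity(vmap, mask) == pytest.approx(5.0)

    def test_no_perfused_error(self):
        vmap = accumulate([], (16, 16), SP)
        with pytest.raises(ValueError):
            median_velocity(vmap, np.ones((16, 16), bool))


class TestSOAM:
    def test_straight_zero(self):
        pts = np.stack([np.linspace(0, 900, 40), np.linspace(0, 400, 40)], 1)
        assert soam(pts) < 1e-6

    def test_semicircle_inverse_radius(self):
        R = 500.0
        th = np.linspace(0, np.pi, 150)
        pts = np.stack([R * np.sin(th), -R * np.cos(th)], 1) + 600
        assert soam(pts) == pytest.approx(1.0 / (R / 1e3), rel=0.02)

    def test_right_angle_two_steps(self):
        pts = np.array([[0.0, 0.0], [1000.0, 0.0], [1000.0, 1000.0]])
        assert soam(pts) == pytest.approx((np.pi / 2) / 2.0)

    def test_zero_step_dropped_with_warning(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [100.0, 0.0], [100.0, 100.0]])
        with pytest.warns(UserWarning):
            val = soam(pts)
        assert val == pytest.approx((np.pi / 2) / 0.2)

    def test_too_short(self):
        with pytest.raises(ValueError):
            soam(np.array([[0.0, 0.0], [1.0, 1.0]]))

    @settings(max_examples=25, deadline=None)
    @given(st.floats(-np.pi, np.pi), st.floats(-500, 500), st.floats(-500, 500))
    def test_rigid_invariance(self, angle, tz, tx):
        rng = np.random.default_rng(7)
        pts = np.cumsum(rng.uniform(-20, 25, size=(12, 2)), axis=0) + 1000
        base = soam(pts)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = pts @ rot.T + [tz, tx]
        assert soam(moved) == pytest.approx(base, rel=1e-9, abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(0.1, 10.0))
    def test_inverse_scaling(self, s):
        rng = np.random.default_rng(8)
        pts = np.cumsum(rng.uniform(-20, 25, size=(12, 2)), axis=0) + 1000
        assert soam(pts * s) == pytest.approx(soam(pts) / s, rel=1e-9)


class TestROISoam:
    def _mask(self):
        m = np.zeros((64, 64), bool)
        m[:, :] = True
        return m

    def test_all_straight_zero(self):
        tracks = [_straight_track(z, 2, 40) for z in (10, 20, 30)]
        assert roi_soam(tracks, self._mask(), SP) == pytest.approx(0.0, abs=1e-9)

    def test_single_track_is_its_soam(self):
        pts = np.array([[50.0, 50.0], [80.0, 50.0], [80.0, 90.0], [120.0, 90.0]])
        t = Track(np.arange(4), pts, 1000.0)
        assert roi_soam([t], self._mask(), SP) == pytest.approx(soam(pts))

    def test_mixed_set_arithmetic_mean(self):
        pts = np.array([[50.0, 50.0], [80.0, 50.0], [80.0, 90.0]])
        bent = Track(np.arange(3), pts, 1000.0)
        straight = _straight_track(10, 2, 40)
        expected = (soam(pts) + 0.0) / 2
        assert roi_soam([bent, straight], self._mask(), SP) == pytest.approx(expected)


class TestSplit:
    def test_descending_is_arteriole(self):
        down = Track(np.arange(10), np.stack([np.linspace(100, 500, 10),
                                              np.full(10, 300.0)], 1), 1000.0)
        art, ven, excl = split_arteriole_venule([down], (1.0, 0.0))
        assert art == [down] and ven == [] and excl == []

    def test_reversed_is_venule(self):
        up = Track(np.arange(10), np.stack([np.linspace(500, 100, 10),
                                            np.full(10, 300.0)], 1), 1000.0)
        art, ven, excl = split_arteriole_venule([up], (1.0, 0.0))
        assert ven == [up] and art == []

    def test_zero_mean_excluded(self):
        osc = Track(np.arange(3), np.array([[100.0, 100.0], [110.0, 100.0],
                                            [100.0, 100.0]]), 1000.0)
        art, ven, excl = split_arteriole_venule([osc], (1.0, 0.0))
        assert excl == [osc]

    def test_partition_is_disjoint_and_complete(self):
        rng = np.random.default_rng(9)
        tracks = []
        for _ in range(20):
            pts = np.cumsum(rng.uniform(-10, 10, size=(6, 2)), axis=0) + 500
            tracks.append(Track(np.arange(6), pts, 1000.0))
        art, ven, excl = split_arteriole_venule(tracks, (1.0, 0.0))
        assert len(art) + len(ven) + len(excl) == len(tracks)
        ids = [id(t) for t in art + ven + excl]
        assert len(set(ids)) == len(ids)

    def test_cortical_column_balanced(self):
        geom = make_vessel_tree("cortical_column")
        truth = simulate_tracks(geom, 1.0, 1000.0, 0.5, seed=12)
        tracks = [t for t in truth.to_tracks() if len(t) >= 10]
        art, ven, excl = split_arteriole_venule(tracks, (1.0, 0.0))
        n = len(art) + len(ven)
        assert abs(len(art) - len(ven)) <= 0.1 * n + 2


class TestVesselProfile:
    def _poiseuille_tracks(self, n=600, R=25.0, vpk=8.0, seed=13):
        rng = np.random.default_rng(seed)
        tracks = []
        for _ in range(n):
            r = R * np.sqrt(rng.uniform())
            off = r * np.cos(rng.uniform(0, 2 * np.pi))
            v = vpk * (1 - (r / R) ** 2)
            if v <= 0:
                continue
            step = v  # um per frame at 1 kHz
            xs = np.arange(200.0, 800.0, step)
            pts = np.stack([np.full(len(xs), 500.0 + off), xs], 1)
            if len(pts) >= 2:
                tracks.append(Track(np.arange(len(pts)), pts, 1000.0))
        return tracks

    def test_single_crossing(self):
        t = _straight_track(10, 2, 40)
        seg = np.array([[10 * SP - 30, 20 * SP], [10 * SP + 30, 20 * SP]])
        prof = vessel_profile([t], seg, SP)
        assert prof.n_crossings == 1

    def test_poiseuille_monotone_toward_center(self):
        tracks = self._poiseuille_tracks()
        seg = np.array([[500.0 - 30, 500.0], [500.0 + 30, 500.0]])
        prof = vessel_profile(tracks, seg, SP)
        sel = prof.counts > 3
        centers = prof.bin_centers_um[sel]
        peaks = prof.peak_mms[sel]
        mid = 30.0
        left = peaks[centers < mid - 2]
        right = peaks[centers > mid + 2]
        assert np.all(np.diff(left) >= -0.5)       # rising toward the axis
        assert np.all(np.diff(right) <= 0.5)       # falling past the axis

    def test_no_crossing_error(self):
        t = _straight_track(10, 2, 40)
        seg = np.array([[40 * SP, 2 * SP], [40 * SP, 45 * SP]])  # parallel, far away
        with pytest.raises(ValueError, match="cross"):
            vessel_profile([t], seg, SP)

    def test_parabola_exact_recovery(self):
        from ulmpipe.roiquant import VesselProfile
        centers = np.linspace(2.0, 58.0, 12)
        vpk, c0, R = 8.0, 30.0, 27.0
        v = vpk * (1 - ((centers - c0) / R) ** 2)
        prof = VesselProfile(np.zeros((2, 2)), centers, v, v, np.ones(12, int))
        fit = fit_parabola(prof)
        assert fit.v_peak_mms == pytest.approx(vpk, abs=1e-6)
        assert fit.center_um == pytest.approx(c0, abs=1e-6)
        assert fit.radius_um == pytest.approx(R, abs=1e-6)

    def test_parabola_poiseuille_phantom(self):
        tracks = self._poiseuille_tracks()
        seg = np.array([[500.0 - 35, 500.0], [500.0 + 35, 500.0]])
        prof = vessel_profile(tracks, seg, SP)
        assert prof.n_crossings >= 300
        fit = fit_parabola(prof)
        assert fit.v_peak_mms == pytest.approx(8.0, rel=0.1)
        assert fit.radius_um == pytest.approx(25.0, rel=0.2)

    def test_flat_profile_flagged(self):
        from ulmpipe.roiquant import VesselProfile
        centers = np.linspace(0, 50, 11)
        prof = VesselProfile(np.zeros((2, 2)), centers, np.full(11, 5.0),
                             np.full(11, 5.0), np.ones(11, int))
        with pytest.raises(FitError):
            fit_parabola(prof)


class TestVascularityMonotonicity:
    def test_more_bubbles_never_fewer_pixels(self, straight_geom):
        mask = np.zeros((512, 512), bool)
        mask[150:260, 100:400] = True
        prev = -1.0
        for rate in (0.02, 0.05, 0.1):
            truth = simulate_tracks(straight_geom, 0.5, 1000.0, rate, seed=14)
            tracks = [t for t in truth.to_tracks() if len(t) >= 10]
            vmap = accumulate(tracks, (512, 512), SP)
            v = vascularity(vmap, mask)
            assert v >= prev
            prev = v


def test_roi_metrics_table(straight_geom):
    truth = simulate_tracks(straight_geom, 0.5, 1000.0, 0.1, seed=15)
    tracks = [t for t in truth.to_tracks() if len(t) >= 10]
    vmap = accumulate(tracks, (512, 512), SP)
    fov = 128 * 19.712
    roi = ROIPolygon(np.array([[0.1, 0.1], [0.1, 0.9], [0.9, 0.9], [0.9, 0.1]]) * fov,
                     label="IC", surface_normal=(1.0, 0.0))
    df = roi_metrics(vmap, tracks, roi, SP)
    assert set(df.subset) == {"all", "arteriole", "venule"}
    assert (df.vascularity_pct.between(0, 100)).all()
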
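"""Flock membership, robust centroid, heading and position decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flocktrace import flock_geometry as fg

coord = st.floats(-500.0, 500.0, allow_nan=False)
angle = st.floats(0.0, 2 * np.pi, allow_nan=False)


class TestCohesiveMembers:
    def test_line_with_outlier(self):
        pos = {"a": (0, 0), "b": (5, 0), "c": (9, 0), "d": (50, 0)}
        assert fg.cohesive_members(pos) == {"a", "b", "c"}

    def test_chain_connectivity(self):
        pos = {"a": (0, 0), "b": (8, 0), "c": (16, 0)}
        assert fg.cohesive_members(pos) == {"a", "b", "c"}

    def test_all_isolated(self):
        pos = {"a": (0, 0), "b": (20, 0), "c": (40, 0)}
        assert fg.cohesive_members(pos) == set()

    def test_tie_broken_by_previous_centroid(self):
        pos = {"a": (0, 0), "b": (5, 0), "c": (100, 0), "d": (105, 0)}
        near_right = fg.cohesive_members(pos, prev_centroid=(102, 0))
        near_left = fg.cohesive_members(pos, prev_centroid=(2, 0))
        assert near_right == {"c", "d"}
        assert near_left == {"a", "b"}


class TestRobustCentroid:
    def test_plain_mean_no_exclusions(self):
        pos = {"a": (0, 0), "b": (10, 0), "c": (5, 9)}
        centroid, members = fg.robust_centroid(pos, set(pos))
        assert centroid == pytest.approx((5.0, 3.0))
        assert members == set(pos)

    def test_hand_iterated_exclusion(self):
        pos = {"a": (0, 0), "b": (2, 0), "c": (100, 0)}
        centroid, members = fg.robust_centroid(pos, set(pos))
        # initial centroid (34, 0): c is 66 m away -> excluded; recompute
        assert members == {"a", "b"}
        assert centroid == pytest.approx((1.0, 0.0))

    def test_single_member(self):
        centroid, members = fg.robust_centroid({"a": (7, 7)}, {"a"})
        assert centroid == pytest.approx((7.0, 7.0))

    def test_final_centroid_is_plain_mean_of_final_set(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(2, 10)
            pts = rng.uniform(-60, 60, size=(n, 2))
            pos = {f"b{i}": tuple(p) for i, p in enumerate(pts)}
            centroid, members = fg.robust_centroid(pos, set(pos))
            if not members:
                continue
            mean = np.mean([pos[m] for m in members], axis=0)
            np.testing.assert_allclose(centroid, mean, atol=1e-12)
            dists = [np.hypot(pos[m][0] - centroid[0], pos[m][1] - centroid[1])
                     for m in members]
            assert max(dists) < 40.0

    def test_larger_subgroup_dominates_on_split(self):
        """With subgroups far beyond the exclusion radius, iterative
        exclusion keeps exactly the larger one."""
        rng = np.random.default_rng(13)
        for _ in range(30):
            n1, n2 = int(rng.integers(3, 7)), 2
            g1 = rng.normal(0, 3, size=(n1, 2))
            g2 = rng.normal(0, 3, size=(n2, 2)) + np.array([200.0, 0.0])
            pos = {f"a{i}": tuple(p) for i, p in enumerate(g1)}
            pos.update({f"z{i}": tuple(p) for i, p in enumerate(g2)})
            _, members = fg.robust_centroid(pos, set(pos))
            assert members == {k for k in pos if k.startswith("a")}


class TestTravelHeading:
    def test_normalised_displacement(self):
        h = fg.travel_heading((0, 0), (3, 4), None, (0, 1))
        assert h == pytest.approx((0.6, 0.8))

    def test_carry_forward_when_stationary(self):
        h = fg.travel_heading((0, 0), (0.1, 0), (0, 1), (1, 0))
        assert h == (0, 1)

    def test_first_frame_uses_release_home_axis(self):
        h = fg.travel_heading((0, 0), None, None, (0, 2))
        assert h == pytest.approx((0.0, 1.0))


class TestDecompose:
    def test_derived_example_right_side(self):
        fb, lr, d, pos = fg.decompose_position((3, -4), (0, 0), (1, 0))
        assert (fb, lr, d, pos) == (3.0, 4.0, 5.0, "front")

    def test_bird_at_centroid_ties_front(self):
        fb, lr, d, pos = fg.decompose_position((0, 0), (0, 0), (1, 0))
        assert (fb, lr, d, pos) == (0.0, 0.0, 0.0, "front")

    def test_heading_north_left_side(self):
        fb, lr, d, pos = fg.decompose_position((-2, 0), (0, 0), (0, 1))
        assert fb == 0.0 and lr == -2.0 and pos == "front"

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(px=coord, py=coord, cx=coord, cy=coord, ang=angle)
    def test_decomposition_identity_property(self, px, py, cx, cy, ang):
        """fb^2 + lr^2 = d^2 and heading flips negate both components,
        for arbitrary positions, centroids and headings."""
        h = (np.cos(ang), np.sin(ang))
        fb, lr, d, _ = fg.decompose_position((px, py), (cx, cy), h)
        assert fb ** 2 + lr ** 2 == pytest.approx(d ** 2, abs=1e-6, rel=1e-9)
        fb2, lr2, d2, _ = fg.decompose_position((px, py), (cx, cy),
                                                (-h[0], -h[1]))
        assert fb2 == pytest.approx(-fb, abs=1e-9)
        assert lr2 == pytest.approx(-lr, abs=1e-9)
        assert d2 == pytest.approx(d, abs=1e-9)

    def test_pythagoras_and_heading_flip(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            p = tuple(rng.normal(0, 20, 2))
            c = tuple(rng.normal(0, 20, 2))
            ang = rng.uniform(0, 2 * np.pi)
            h = (np.cos(ang), np.sin(ang))
            fb, lr, d, _ = fg.decompose_position(p, c, h)
            assert fb ** 2 + lr ** 2 == pytest.approx(d ** 2, abs=1e-6)
            fb2, lr2, d2, _ = fg.decompose_position(p, c, (-h[0], -h[1]))
            assert fb2 == pytest.approx(-fb) and lr2 == pytest.approx(-lr)
            assert d2 == pytest.approx(d)


class TestAbsoluteSpread:
    def test_hand_projected_example(self):
        pos = {"a": (0, 0), "b": (10, 2), "c": (4, -3)}
        assert fg.absolute_spread(pos, pos, (1, 0)) == pytest.approx(15.0)

    def test_coincident_members(self):
        pos = {"a": (5, 5), "b": (5, 5)}
        assert fg.absolute_spread(pos, pos, (1, 0)) == 0.0

    def test_two_members_along_heading(self):
        pos = {"a": (0, 0), "b": (6, 0)}
        assert fg.absolute_spread(pos, pos, (1, 0)) == pytest.approx(6.0)

    def test_single_member_undefined(self):
        assert np.isnan(fg.absolute_spread({"a": (0, 0)}, {"a"}, (1, 0)))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(19)
        for _ in range(100):
            n = rng.integers(2, 9)
            pts = rng.normal(0, 15, size=(n, 2))
            pos = {f"b{i}": tuple(p) for i, p in enumerate(pts)}
            ang = rng.uniform(0, 2 * np.pi)
            h = (np.cos(ang), np.sin(ang))
            base = fg.absolute_spread(pos, pos, h)
            # translation
            shift = rng.normal(0, 100, 2)
            pos_t = {k: (v[0] + shift[0], v[1] + shift[1]) for k, v in pos.items()}
            assert fg.absolute_spread(pos_t, pos_t, h) == pytest.approx(base, abs=1e-9)
            # joint rotation of positions and heading
            rot = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
            pos_r = {k: tuple(R @ np.asarray(v)) for k, v in pos.items()}
            h_r = tuple(R @ np.asarray(h))
            assert fg.absolute_spread(pos_r, pos_r, h_r) == pytest.approx(base, abs=1e-9)


class TestBruteForceOracle:
    """Centroid, spread and decomposition agree with direct recomputation
    on 1000 random flock configurations."""

    @staticmethod
    def brute_centroid(pos, members, excl=40.0):
        current = sorted(members)
        while current:
            pts = np.array([pos[m] for m in current])
            c = pts.mean(axis=0)
            dists = {m: np.hypot(p[0] - c[0], p[1] - c[1])
                     for m, p in zip(current, pts)}
            worst = max(current, key=dists.get)
            if dists[worst] < excl:
                return tuple(c), set(current)
            current.remove(worst)
        return None, set()

    def test_thousand_random_configurations(self):
        rng = np.random.default_rng(23)
        for _ in range(1000):
            n = int(rng.integers(2, 11))
            scale = rng.choice([5.0, 30.0, 80.0])
            pts = rng.normal(0, scale, size=(n, 2))
            pos = {f"b{i}": tuple(p) for i, p in enumerate(pts)}
            c1, m1 = fg.robust_centroid(pos, set(pos))
            c2, m2 = self.brute_centroid(pos, set(pos))
            assert m1 == m2
            if c1 is None:
                assert c2 is None
                continue
            np.testing.assert_allclose(c1, c2, atol=1e-9)
            ang = rng.uniform(0, 2 * np.pi)
            h = (np.cos(ang), np.sin(ang))
            if len(m1) >= 2:
                fb = [np.dot(np.asarray(pos[m]), h) for m in m1]
                lr = [pos[m][0] * h[1] - pos[m][1] * h[0] for m in m1]
                expect = (max(fb) - min(fb)) + (max(lr) - min(lr))
                got = fg.absolute_spread(pos, m1, h)
                assert got == pytest.approx(expect, abs=1e-9)
            for m in m1:
                fb1, lr1, d1, _ = fg.decompose_position(pos[m], c1, h)
                dx, dy = pos[m][0] - c1[0], pos[m][1] - c1[1]
                assert fb1 == pytest.approx(dx * h[0] + dy * h[1], abs=1e-9)
                assert lr1 == pytest.approx(dx * h[1] - dy * h[0], abs=1e-9)
                assert d1 == pytest.approx(np.hypot(dx, dy), abs=1e-9)


class TestComputeFlockFrames:
    def test_per_second_frames(self):
        rows = []
        for t in range(5):
            for i, x in enumerate([0.0, 4.0, 8.0]):
                rows.append({"bird_id": f"b{i}", "t": float(t),
                             "x": x + 15.0 * t, "y": 0.0})
        per_second = pd.DataFrame(rows)
        frames = fg.compute_flock_frames(per_second, "L", (1.0, 0.0))
        assert set(frames["t"]) == {0.0, 1.0, 2.0, 3.0, 4.0}
        assert (frames["group_size"] == 3).all()
        # flock moves east at 15 m/s -> heading (1, 0)
        np.testing.assert_allclose(frames["heading_x"], 1.0, atol=1e-9)
        np.testing.assert_allclose(frames["absolute_spread"], 8.0, atol=1e-9)

    def test_lone_second_yields_no_frame(self):
        per_second = pd.DataFrame(
            [{"bird_id": "a", "t": 0.0, "x": 0.0, "y": 0.0},
             {"bird_id": "b", "t": 0.0, "x": 100.0, "y": 0.0}])
        frames = fg.compute_flock_frames(per_second, "L", (1.0, 0.0))
        assert len(frames) == 0
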
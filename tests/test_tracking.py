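"""Trajectory linking and the feeding/division mass-budget analyses."""

import itertools

import numpy as np
import pytest

from holomass.detect import Detection
from holomass.tracking import (
    DivisionParams,
    FeedingParams,
    LinkParams,
    Track,
    detect_division_events,
    detect_feeding_events,
    link_tracks,
    regress_event_pairs,
)

PITCH = 3.6


def det(frame, x_px, y_px, z=800.0, mass=100.0):
    return Detection(frame, x_px, y_px, z, mass, support=10, confidence=1.0)


def make_track(tid, frames, xs_px, ys_px, masses, z=800.0):
    t = Track(
        id=tid,
        detections=[
            det(f, x, y, z, m) for f, x, y, m in zip(frames, xs_px, ys_px, masses)
        ],
    )
    t.mass_series = np.asarray(masses, dtype=float)
    t.mass_frames = np.asarray(frames)
    t.window = 1
    return t


class TestLinking:
    def test_stationary_particle_single_track(self):
        per_frame = [[det(f, 30.0, 30.0)] for f in range(50)]
        tracks = link_tracks(per_frame, PITCH)
        assert len(tracks) == 1
        assert len(tracks[0].detections) == 50

    def test_mass_keeps_identities_through_crossing(self):
        # two particles crossing laterally; masses 50 vs 400 pg separate them
        per_frame = []
        for f in range(21):
            a = det(f, 10.0 + f, 30.0, mass=50.0)  # left-to-right, light
            b = det(f, 30.0 - f, 30.0, mass=400.0)  # right-to-left, heavy
            per_frame.append([a, b] if f % 2 == 0 else [b, a])
        tracks = link_tracks(per_frame, PITCH)
        assert len(tracks) == 2
        for t in tracks:
            masses = {d.mass_pg for d in t.detections}
            assert len(masses) == 1  # identities never swapped

    def test_gap_bridging(self):
        per_frame = [[det(f, 20.0, 20.0)] for f in range(10)]
        per_frame[4] = []
        per_frame[5] = []
        tracks = link_tracks(per_frame, PITCH, LinkParams(max_gap=3))
        assert len(tracks) == 1
        tracks = link_tracks(per_frame, PITCH, LinkParams(max_gap=1))
        assert len(tracks) == 2

    def test_matches_brute_force_assignment(self):
        rng = np.random.default_rng(0)
        p = LinkParams()
        for _ in range(20):
            n = int(rng.integers(1, 5))
            prev = [
                det(0, rng.uniform(5, 60), rng.uniform(5, 60),
                    rng.uniform(600, 1000), rng.uniform(20, 500))
                for _ in range(n)
            ]
            # jitter each previous detection into the next frame
            nxt = [
                det(
                    1,
                    d.x_px + rng.uniform(-2, 2),
                    d.y_px + rng.uniform(-2, 2),
                    d.z_um + rng.uniform(-20, 20),
                    d.mass_pg * rng.uniform(0.95, 1.05),
                )
                for d in prev
            ]
            shuffled = list(nxt)
            rng.shuffle(shuffled)
            tracks = link_tracks([prev, shuffled], PITCH, p)

            def cost(a, b):
                dx = (b.x_px - a.x_px) * PITCH
                dy = (b.y_px - a.y_px) * PITCH
                dz = (b.z_um - a.z_um) * p.w_z
                return (
                    np.sqrt(dx**2 + dy**2 + dz**2)
                    + p.lambda_mass_um * abs(b.mass_pg - a.mass_pg) / abs(a.mass_pg)
                )

            best_perm = min(
                itertools.permutations(range(n)),
                key=lambda perm: sum(cost(prev[i], shuffled[perm[i]]) for i in range(n)),
            )
            expected = {
                (prev[i].x_px, shuffled[best_perm[i]].x_px) for i in range(n)
            }
            got = {
                (t.detections[0].x_px, t.detections[1].x_px)
                for t in tracks
                if len(t.detections) == 2
            }
            assert got == expected

    def test_within_frame_order_irrelevant(self):
        rng = np.random.default_rng(1)
        base = [
            [det(f, 10.0 + 2 * f, 10.0, mass=50.0), det(f, 50.0 - f, 40.0, mass=300.0)]
            for f in range(10)
        ]
        shuffled = [list(frame) for frame in base]
        for frame in shuffled:
            rng.shuffle(frame)
        t1 = link_tracks(base, PITCH)
        t2 = link_tracks(shuffled, PITCH)
        sig1 = sorted(tuple(d.x_px for d in t.detections) for t in t1)
        sig2 = sorted(tuple(d.x_px for d in t.detections) for t in t2)
        assert sig1 == sig2


class TestFeedingEvents:
    def _encounter(self, rng, prey_mass=25.0, noise=2.0):
        """Predator at rest; prey approaches, disappears; predator mass steps up."""
        frames = np.arange(300)
        pred_mass = 200.0 + np.where(frames >= 150, prey_mass, 0.0)
        pred_mass = pred_mass + rng.normal(0, noise, size=300)
        pred = make_track(0, frames, np.full(300, 50.0), np.full(300, 50.0), pred_mass)
        prey_frames = np.arange(150)
        prey_x = 50.0 + (145 - prey_frames) * 0.2  # walks toward the predator
        prey = make_track(
            1, prey_frames, prey_x, np.full(150, 50.0),
            prey_mass + rng.normal(0, 1.0, size=150),
        )
        return pred, prey

    def test_programmed_step_recovered(self):
        rng = np.random.default_rng(3)
        pred, prey = self._encounter(rng)
        events = detect_feeding_events([pred, prey], PITCH, FeedingParams())
        assert len(events) == 1
        ev = events[0]
        assert ev.predator_track == 0 and ev.prey_track == 1
        pooled = np.hypot(ev.pre_stats[1], ev.post_stats[1])
        assert abs(ev.increment_pg - 25.0) <= 2 * pooled

    def test_reported_increment_is_mean_difference(self):
        # constant series: post 234 pg, pre 204 pg -> increment 30 pg exactly
        frames = np.arange(300)
        mass = np.where(frames >= 150, 234.0, 204.0)
        pred = make_track(0, frames, np.full(300, 50.0), np.full(300, 50.0), mass)
        prey_frames = np.arange(150)
        prey_x = np.where(prey_frames < 100, 80.0, 52.0)  # approaches at frame 100
        prey = make_track(
            1, prey_frames, prey_x, np.full(150, 50.0), np.full(150, 30.0)
        )
        events = detect_feeding_events([pred, prey], PITCH, FeedingParams())
        assert len(events) == 1
        assert events[0].increment_pg == pytest.approx(30.0, abs=1e-9)
        assert events[0].pre_stats[0] == pytest.approx(204.0)
        assert events[0].post_stats[0] == pytest.approx(234.0)

    def test_no_contact_no_events(self):
        a = make_track(0, np.arange(100), np.full(100, 10.0), np.full(100, 10.0),
                       np.full(100, 200.0))
        b = make_track(1, np.arange(100), np.full(100, 80.0), np.full(100, 80.0),
                       np.full(100, 30.0))
        assert detect_feeding_events([a, b], PITCH) == []

    def test_surviving_prey_not_an_event(self):
        frames = np.arange(300)
        pred = make_track(0, frames, np.full(300, 50.0), np.full(300, 50.0),
                          np.full(300, 200.0))
        prey = make_track(1, frames, np.full(300, 52.0), np.full(300, 50.0),
                          np.full(300, 30.0))
        assert detect_feeding_events([pred, prey], PITCH) == []


class TestRegression:
    def test_perfect_line(self):
        pairs = [(10.0, 10.0), (20.0, 20.0), (30.0, 30.0)]
        slope, rho = regress_event_pairs(pairs)
        assert slope == pytest.approx(1.0)
        assert rho == pytest.approx(1.0)

    def test_half_slope(self):
        pairs = [(x, 0.5 * x + 3.0) for x in (5.0, 10.0, 40.0, 80.0)]
        slope, _ = regress_event_pairs(pairs)
        assert slope == pytest.approx(0.5)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(5, 50, size=12)
        y = 0.9 * x + rng.normal(0, 2, size=12)
        slope, rho = regress_event_pairs(np.column_stack([x, y]))
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert slope == pytest.approx(beta[0], abs=1e-9)
        r_manual = np.corrcoef(x, y)[0, 1]
        assert rho == pytest.approx(r_manual, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            regress_event_pairs([(1.0, 1.0)])


class TestDivisionEvents:
    def _division(self, parent_mass=400.0, f1=0.7, noise=0.0, rng=None):
        """Parent splits at frame 100; daughters drift apart at 1 px/frame."""
        pf = np.arange(100)
        masses_p = np.full(100, parent_mass)
        if rng is not None:
            masses_p = masses_p + rng.normal(0, noise, 100)
        parent = make_track(0, pf, np.full(100, 60.0), np.full(100, 60.0), masses_p)
        d_frames = np.arange(101, 200)
        steps = (d_frames - 100) * 0.5
        m1 = np.full(99, parent_mass * f1)
        m2 = np.full(99, parent_mass * (1 - f1))
        if rng is not None:
            m1 = m1 + rng.normal(0, noise, 99)
            m2 = m2 + rng.normal(0, noise, 99)
        d1 = make_track(1, d_frames, 60.0 + steps, np.full(99, 60.0), m1)
        d2 = make_track(2, d_frames, 60.0 - steps, np.full(99, 60.0), m2)
        return parent, d1, d2

    def test_conservative_split_ratio_one(self):
        parent, d1, d2 = self._division()
        events = detect_division_events([parent, d1, d2], PITCH, DivisionParams())
        assert len(events) == 1
        assert events[0].conservation_ratio == pytest.approx(1.0, abs=1e-9)
        assert set(events[0].daughter_tracks) == {1, 2}

    def test_noisy_split_within_pooled_sem(self):
        rng = np.random.default_rng(5)
        parent, d1, d2 = self._division(noise=4.0, rng=rng)
        events = detect_division_events([parent, d1, d2], PITCH)
        assert len(events) == 1
        ev = events[0]
        rel_sem = np.sqrt(
            (ev.parent_mass[1] / ev.parent_mass[0]) ** 2
            + (ev.daughter_masses[0][1] / ev.parent_mass[0]) ** 2
            + (ev.daughter_masses[1][1] / ev.parent_mass[0]) ** 2
        )
        assert abs(ev.conservation_ratio - 1.0) <= 3 * rel_sem + 1e-3

    def test_isolation_required_before_measurement(self):
        parent, d1, d2 = self._division()
        events = detect_division_events([parent, d1, d2], PITCH)
        # daughters separate at 1 px/frame relative: 40 px apart -> frame 140
        _, f1, f2 = events[0].measurement_frames
        assert f1 >= 140 and f2 >= 140

    def test_three_way_split_skipped(self):
        parent, d1, d2 = self._division()
        d3 = make_track(
            3, np.arange(101, 200), np.full(99, 61.0), 60.0 + np.arange(99) * 0.5,
            np.full(99, 50.0),
        )
        events = detect_division_events([parent, d1, d2, d3], PITCH)
        assert events == []

    @pytest.mark.parametrize(
        "parent,daughters,expected",
        [
            (433.0, (326.0, 110.0), 436.0 / 433.0),
            (326.0, (225.0, 93.0), 318.0 / 326.0),
        ],
    )
    def test_measured_generation_ratios(self, parent, daughters, expected):
        """Mass budgets of two successive diatom generations: the daughters'
        summed dry mass over the parent's."""
        p, d1, d2 = self._division(parent_mass=parent, f1=daughters[0] / sum(daughters))
        scale = sum(daughters) / parent
        d1.mass_series = np.full(99, daughters[0])
        d2.mass_series = np.full(99, daughters[1])
        events = detect_division_events([p, d1, d2], PITCH)
        assert len(events) == 1
        assert events[0].conservation_ratio == pytest.approx(expected, abs=1e-9)
        del scale
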
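import numpy as np
import pandas as pd
import pytest

from ethospike.behavior import (
    behavior_peth,
    clean_tracking,
    compute_features,
    food_interaction_mask,
    interaction_response_score,
    nonsocial_contact_threshold,
    postprocess_bouts,
    speed_correlation,
    train_behavior_classifier,
)
from ethospike.io_core import EventBlock, Unit


def _table(rows):
    return pd.DataFrame(rows, columns=["frame", "agent", "bodypart", "x", "y",
                                       "likelihood"])


class TestCleanTracking:
    def test_perfect_tracks_pass_through(self):
        rows = [(f, "implanted", "head", float(f), 0.0, 1.0) for f in range(10)]
        out = clean_tracking(_table(rows))
        np.testing.assert_allclose(out["x"], np.arange(10.0))
        assert not out["interpolated"].any()

    def test_dropped_point_linearly_interpolated(self):
        rows = [
            (0, "implanted", "head", 0.0, 0.0, 1.0),
            (1, "implanted", "head", 5.0, 5.0, 0.2),  # below threshold
            (2, "implanted", "head", 2.0, 2.0, 1.0),
        ]
        out = clean_tracking(_table(rows))
        assert out.loc[1, "x"] == pytest.approx(1.0)
        assert out.loc[1, "y"] == pytest.approx(1.0)
        assert out.loc[1, "interpolated"]

    def test_colored_parts_use_stricter_threshold(self):
        rows = [
            (0, "implanted", "tailbase", 0.0, 0.0, 0.995),  # colored: < 0.999
            (1, "implanted", "tailbase", 2.0, 2.0, 1.0),
        ]
        out = clean_tracking(_table(rows))
        assert out.loc[0, "interpolated"]

    def test_mostly_missing_part_warns(self):
        rows = [(f, "implanted", "head", 0.0, 0.0, 0.1) for f in range(9)]
        rows.append((9, "implanted", "head", 1.0, 1.0, 1.0))
        with pytest.warns(UserWarning, match="low-quality"):
            clean_tracking(_table(rows))


def _two_agent_frame(f, imp_head, con_head, imp_base=None, con_base=None):
    imp_base = imp_base or (imp_head[0] - 5.0, imp_head[1])
    con_base = con_base or (con_head[0] + 5.0, con_head[1])
    rows = []
    for agent, head_name, head, base in (
        ("implanted", "head", imp_head, imp_base),
        ("conspecific", "nose", con_head, con_base),
    ):
        rows.append((f, agent, head_name, head[0], head[1], 1.0))
        rows.append((f, agent, "nape_c", base[0], base[1], 1.0))
        rows.append((f, agent, "back_c", base[0], base[1], 1.0))
        rows.append((f, agent, "tailbase", base[0] - 3.0, base[1], 1.0))
    return rows


class TestComputeFeatures:
    def test_stationary_agents_have_zero_velocity(self):
        rows = []
        for f in range(20):
            rows += _two_agent_frame(f, (10.0, 10.0), (40.0, 10.0))
        feats = compute_features(_table(rows), frame_rate=30.0)
        assert np.allclose(feats["imp_head_vel"], 0.0)
        assert np.allclose(feats["con_tail_vel"], 0.0)

    def test_three_four_five_head_distance(self):
        rows = []
        for f in range(3):
            rows += _two_agent_frame(f, (0.0, 0.0), (3.0, 4.0))
        feats = compute_features(_table(rows), frame_rate=30.0)
        assert np.allclose(feats["dist_head_head"], 5.0)

    def test_head_direction_angle_to_conspecific(self):
        # implanted at origin facing +x (nape behind head), target at (1, 1)
        rows = []
        for f in range(3):
            rows += _two_agent_frame(
                f, (0.0, 0.0), (1.0, 1.0), imp_base=(-5.0, 0.0),
            )
        feats = compute_features(_table(rows), frame_rate=30.0)
        assert np.allclose(feats["imp_headdir_to_con_head"], np.pi / 4)

    def test_distance_features_invariant_to_rigid_motion(self):
        rng = np.random.default_rng(2)
        # one fixed skeleton per agent, every point transformed together
        skel = {
            ("implanted", "head"): rng.uniform(0, 50, 2),
            ("implanted", "nape_c"): rng.uniform(0, 50, 2),
            ("implanted", "back_c"): rng.uniform(0, 50, 2),
            ("implanted", "tailbase"): rng.uniform(0, 50, 2),
            ("conspecific", "nose"): rng.uniform(0, 50, 2),
            ("conspecific", "nape_c"): rng.uniform(0, 50, 2),
            ("conspecific", "back_c"): rng.uniform(0, 50, 2),
            ("conspecific", "tailbase"): rng.uniform(0, 50, 2),
        }

        def build(transform):
            rows = []
            for f in range(4):
                for (agent, part), p in skel.items():
                    q = transform(p)
                    rows.append((f, agent, part, q[0], q[1], 1.0))
            return compute_features(_table(rows), frame_rate=30.0)

        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        f0 = build(lambda p: p)
        f1 = build(lambda p: R @ p + np.array([7.0, -3.0]))
        for col in ["dist_head_head", "dist_imphead_contail", "head_angle_diff",
                    "imp_spine_len", "imp_headdir_to_con_head",
                    "imp_head_vel", "con_tail_vel"]:
            np.testing.assert_allclose(f0[col], f1[col], atol=1e-9,
                                       err_msg=col)


class TestClassifier:
    def test_memorizes_separable_training_data(self, tracked_bouts):
        table, labels = tracked_bouts
        feats = compute_features(clean_tracking(table))
        model = train_behavior_classifier(feats, labels)
        acc = np.mean(model.predict(feats.to_numpy()) == labels)
        assert acc > 0.99

    def test_missing_class_raises(self, tracked_bouts):
        table, labels = tracked_bouts
        feats = compute_features(clean_tracking(table))
        bad = labels.copy()
        bad[bad == "head-tail"] = "head-head"
        with pytest.raises(ValueError, match="head-tail"):
            train_behavior_classifier(feats, bad)


class TestPostprocessBouts:
    def test_short_isolated_run_deleted(self):
        y = ["non-social"] * 20 + ["head-head"] * 4 + ["non-social"] * 20
        bouts = postprocess_bouts(np.array(y, dtype=object))
        assert all(b.label == "non-social" for b in bouts)

    def test_short_gap_merged_into_one_bout(self):
        # 10 + 3-frame gap + 10 at 30 Hz: 0.1 s < 0.25 s, merged to 23 frames
        y = ["head-head"] * 10 + ["non-social"] * 3 + ["head-head"] * 10
        bouts = postprocess_bouts(np.array(y, dtype=object), frame_rate=30.0)
        hh = [b for b in bouts if b.label == "head-head"]
        assert len(hh) == 1 and hh[0].n_frames == 23

    def test_long_gaps_left_alone(self):
        y = (["head-head"] * 10 + ["non-social"] * 8) * 3  # 8 frames > 0.25 s
        bouts = postprocess_bouts(np.array(y, dtype=object), frame_rate=30.0)
        assert sum(b.label == "head-head" for b in bouts) == 3

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        y = np.array(
            [rng.choice(["a", "b", "c"]) for _ in range(40) for _ in
             range(rng.integers(1, 12))], dtype=object,
        )
        once = postprocess_bouts(y, frame_rate=30.0)
        relabel = np.array(["__gap__"] * len(y), dtype=object)
        for b in once:
            relabel[b.start_frame : b.end_frame] = b.label
        twice = postprocess_bouts(relabel, frame_rate=30.0)
        twice = [b for b in twice if b.label != "__gap__"]
        assert [(b.label, b.start_frame, b.end_frame) for b in once] == [
            (b.label, b.start_frame, b.end_frame) for b in twice
        ]


class TestNonsocialContact:
    def test_separated_distributions_fully_resolved(self):
        d = np.concatenate([np.full(50, 2.0), np.full(50, 30.0)])
        y = np.concatenate([np.ones(50, bool), np.zeros(50, bool)])
        r = nonsocial_contact_threshold(d, y)
        assert 2.0 < r["threshold"] < 30.0
        assert r["balanced_accuracy"] == 1.0

    def test_equal_variance_gaussians_split_at_midpoint(self):
        rng = np.random.default_rng(0)
        d = np.concatenate([rng.normal(5, 2, 4000), rng.normal(15, 2, 4000)])
        y = np.concatenate([np.ones(4000, bool), np.zeros(4000, bool)])
        r = nonsocial_contact_threshold(d, y)
        assert abs(r["threshold"] - 10.0) < 1.0

    def test_single_label_training_rejected(self):
        with pytest.raises(ValueError):
            nonsocial_contact_threshold(np.arange(5.0), np.ones(5, bool))

    def test_head_inside_roi_counts_as_eating(self):
        roi = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])
        inside = food_interaction_mask(np.array([[5.0, 5.0]]), roi)
        outside = food_interaction_mask(np.array([[15.0, 5.0]]), roi)
        assert inside[0] and not outside[0]


def _gated_unit(rng, mask_fn, t_end, rate_on=6.0, rate_off=2.0):
    spikes = []
    t = 0.0
    while t < t_end:
        r = rate_on if mask_fn(t, t + 1.0) else rate_off
        spikes.extend(np.sort(t + rng.uniform(0, 1, rng.poisson(r))))
        t += 1.0
    return Unit("gated", np.array(sorted(set(spikes))), 0, 0.0)


class TestInteractionResponse:
    EV = EventBlock("male", 1, 0.0, 300.0, 310.0, 600.0, 900.0)

    def test_identical_firing_scores_none(self):
        rng = np.random.default_rng(0)
        unit = _gated_unit(rng, lambda a, b: False, 900.0)
        mask = lambda a, b: (int(a) % 2) == 0
        r = interaction_response_score(unit, [self.EV], mask)
        assert r["cls"] == "none"

    def test_mask_gated_unit_flagged_increase(self):
        rng = np.random.default_rng(1)
        mask = lambda a, b: (int(a) // 10) % 2 == 0
        unit = _gated_unit(rng, mask, 900.0)
        r = interaction_response_score(unit, [self.EV], mask)
        assert r["cls"] == "increase" and r["score"] > 0.2

    def test_antisymmetric_under_mask_inversion(self):
        rng = np.random.default_rng(2)
        mask = lambda a, b: (int(a) // 10) % 2 == 0
        unit = _gated_unit(rng, mask, 900.0)
        r_pos = interaction_response_score(unit, [self.EV], mask)
        r_neg = interaction_response_score(
            unit, [self.EV], lambda a, b: not mask(a, b)
        )
        assert r_pos["score"] == pytest.approx(-r_neg["score"], abs=1e-12)


class TestBehaviorPeth:
    def test_bout_locked_burst_flagged(self):
        rng = np.random.default_rng(3)
        starts = np.arange(20.0, 1020.0, 20.0)  # 50 bouts
        base = np.sort(rng.uniform(0, 1040, rng.poisson(2.0 * 1040)))
        burst = np.concatenate([s + rng.uniform(0, 1.0, rng.poisson(8))
                                for s in starts])
        unit = Unit("b", np.unique(np.concatenate([base, burst])), 0, 0.0)
        r = behavior_peth(unit, starts)
        assert r["responsive"]

    def test_constant_unit_rarely_flagged(self):
        rng = np.random.default_rng(4)
        starts = np.arange(20.0, 620.0, 20.0)
        base = np.sort(rng.uniform(0, 640, rng.poisson(3.0 * 640)))
        unit = Unit("c", base, 0, 0.0)
        r = behavior_peth(unit, starts)
        assert not r["responsive"]

    def test_flag_invariant_to_bout_order(self):
        rng = np.random.default_rng(5)
        starts = np.arange(20.0, 620.0, 20.0)
        base = np.sort(rng.uniform(0, 640, rng.poisson(3.0 * 640)))
        unit = Unit("c", base, 0, 0.0)
        a = behavior_peth(unit, starts)
        b = behavior_peth(unit, rng.permutation(starts))
        np.testing.assert_allclose(a["z"], b["z"])

    def test_too_few_bouts_skipped(self):
        unit = Unit("c", np.arange(10.0), 0, 0.0)
        r = behavior_peth(unit, np.array([20.0, 40.0]))
        assert r["skipped"]


class TestSpeedCorrelation:
    @staticmethod
    def _speed_trace(rng, t):
        # smooth, aperiodic locomotion trace (low-pass filtered noise)
        from scipy.ndimage import gaussian_filter1d

        raw = gaussian_filter1d(rng.standard_normal(t.size), 60.0)
        return np.clip(2.0 + raw / raw.std(), 0.05, None)

    def _session(self, sign, seed=0, dur=600.0):
        rng = np.random.default_rng(seed)
        t = np.arange(0, dur, 0.05)
        speed = self._speed_trace(rng, t)
        rate = 4.0 + sign * 1.5 * (speed - speed.mean())
        rate = np.clip(rate, 0.1, None)
        counts = rng.poisson(rate * 0.05)
        spikes = np.concatenate(
            [ti + rng.uniform(0, 0.05, c) for ti, c in zip(t, counts)]
        )
        unit = Unit("s", np.unique(spikes), 0, 0.0)
        return unit, t, speed

    def test_rate_tracking_speed_is_positive(self):
        unit, t, speed = self._session(+1)
        r = speed_correlation(unit, t, speed, [(0.0, 600.0)])
        assert r["cls"] == "positive"

    def test_rate_opposing_speed_is_negative(self):
        unit, t, speed = self._session(-1)
        r = speed_correlation(unit, t, speed, [(0.0, 600.0)])
        assert r["cls"] == "negative"

    def test_independent_rate_is_none(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 600, 0.05)
        speed = self._speed_trace(rng, t)
        spikes = np.sort(rng.uniform(0, 600, rng.poisson(4.0 * 600)))
        unit = Unit("i", spikes, 0, 0.0)
        r = speed_correlation(unit, t, speed, [(0.0, 600.0)])
        assert r["cls"] == "none"

    def test_constant_speed_undefined(self):
        unit = Unit("u", np.arange(100.0), 0, 0.0)
        r = speed_correlation(unit, np.arange(100.0), np.ones(100), [(0.0, 99.0)])
        assert r["cls"] == "undefined"
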
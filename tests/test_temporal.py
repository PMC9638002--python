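import numpy as np
import pytest

from ethospike.io_core import EventBlock, Unit
from ethospike.temporal import (
    ZPsth,
    detect_aftereffects,
    onset_synchrony,
    timewarp,
    zscore_psth,
)


def _unit_from_counts(baseline_counts, event_rates, bin_s=1.0):
    """Build a unit whose per-bin spike counts are exactly as given."""
    spikes = []
    for i, c in enumerate(baseline_counts):
        spikes.extend(i * bin_s + (np.arange(c) + 0.5) / (c + 1) * bin_s)
    t0 = len(baseline_counts) * bin_s
    for i, c in enumerate(event_rates):
        spikes.extend(t0 + i * bin_s + (np.arange(c) + 0.5) / (c + 1) * bin_s)
    return Unit("hand", np.array(sorted(spikes)), channel=0, depth_um=0)


class TestZscorePsth:
    def test_hand_computed_example(self):
        # baseline bins [1,1,3,3] -> mean 2, SD 1; event rates [4,2,6]
        unit = _unit_from_counts([1, 1, 3, 3], [4, 2, 6])
        ev = EventBlock("male", 1, 0.0, 4.0, 4.5, 7.0, 10.0)
        psth = zscore_psth(unit, ev, bin_s=1.0)
        np.testing.assert_allclose(psth.z, [2.0, 0.0, 4.0])

    def test_silent_baseline_uses_sd_floor(self):
        unit = _unit_from_counts([0, 0, 0, 0], [3, 3, 3])
        ev = EventBlock("male", 1, 0.0, 4.0, 4.5, 7.0, 10.0)
        psth = zscore_psth(unit, ev, bin_s=1.0, sd_floor_hz=0.1)
        assert np.all(np.isfinite(psth.z)) and np.all(psth.z > 0)

    def test_constant_rate_unit_centers_near_zero(self, small_session):
        session, gt = small_session
        nonresp = next(u for u in session.units
                       if gt.category[u.unit_id] == "nonresponsive")
        ev = session.events[0]
        psth = zscore_psth(nonresp, ev)
        se = 1.0 / np.sqrt(psth.z.size)
        assert abs(psth.z.mean()) < 4 * se

    def test_mean_shift_identity(self):
        # adding k spikes/s to every event bin moves z by exactly k/SD
        unit = _unit_from_counts([1, 1, 3, 3], [4, 2, 6])
        ev = EventBlock("male", 1, 0.0, 4.0, 4.5, 7.0, 10.0)
        psth = zscore_psth(unit, ev, bin_s=1.0)
        shifted = ZPsth(psth.unit_id, psth.event_label, psth.bin_centers,
                        (np.array([5.0, 3.0, 7.0]) - psth.baseline_mean_hz)
                        / psth.baseline_sd_hz,
                        psth.baseline_mean_hz, psth.baseline_sd_hz)
        np.testing.assert_allclose(shifted.z - psth.z, 1.0 / psth.baseline_sd_hz)


class TestTimewarp:
    def _trace(self, t, z):
        return ZPsth("u", "male1", np.asarray(t, float), np.asarray(z, float),
                     0.0, 1.0)

    def test_linear_segments_reproduced_exactly(self):
        t = np.arange(0.05, 20.0, 0.1)
        z = 0.5 * t  # globally linear; splines reproduce cubics exactly
        w = timewarp(self._trace(t, z), (5.0, 10.0))
        expect_pres = 0.5 * 5.0
        assert w.samples[w.anchor_presentation] == pytest.approx(expect_pres)
        seg = w.samples[: w.anchor_presentation]
        diffs = np.diff(seg)
        np.testing.assert_allclose(diffs, diffs[0], atol=1e-9)

    def test_anchor_values_preserved(self):
        rng = np.random.default_rng(4)
        t = np.arange(0.05, 30.0, 0.1)
        z = rng.normal(size=t.size)
        from scipy.interpolate import CubicSpline

        w = timewarp(self._trace(t, z), (8.0, 17.0))
        spline = CubicSpline(t, z)
        assert w.samples[w.anchor_presentation] == float(spline(8.0))
        assert w.samples[w.anchor_contact] == float(spline(17.0))

    def test_monotone_segment_stays_monotone(self):
        t = np.arange(0.05, 12.0, 0.1)
        z = np.tanh((t - 6.0))  # smooth monotone
        w = timewarp(self._trace(t, z), (4.0, 8.0))
        assert np.all(np.diff(w.samples) > -1e-9)

    def test_out_of_range_anchor_rejected(self):
        t = np.arange(0.05, 5.0, 0.1)
        with pytest.raises(ValueError):
            timewarp(self._trace(t, t), (4.0, 9.0))


class TestOnsetSynchrony:
    def test_within_event_distances_smaller_than_across(
        self, gain5_session, gain5_profiles
    ):
        session, _ = gain5_session
        res = onset_synchrony(session, gain5_profiles)
        assert res["within"].size >= 100
        assert res["within"].mean() < res["across"].mean()
        assert res["p_value"] < 0.05

    def test_peak_latency_of_scripted_bursts(self):
        from ethospike.temporal import peak_latency

        ev = EventBlock("male", 1, 0.0, 10.0, 20.0, 310.0, 610.0)
        lat = {}
        for name, burst_at in (("a", 1.0), ("b", 3.5)):
            spikes = np.sort(np.concatenate([
                np.arange(0.5, 9.5, 1.0),  # sparse baseline
                10.0 + burst_at - 0.05 + np.arange(8) * 0.01,  # sharp burst
            ]))
            lat[name] = peak_latency(Unit(name, spikes, 0, 0.0), ev)
        assert abs(lat["a"] - lat["b"]) == pytest.approx(2.5, abs=0.11)


class TestAftereffects:
    def test_injected_decays_flagged_and_clean_units_not(
        self, small_session, small_profiles
    ):
        session, gt = small_session
        res = detect_aftereffects(session, small_profiles)
        flags = res["unit_flags"]
        assert flags, "no responsive units analyzed"
        for uid, flag in flags.items():
            if gt.aftereffect[uid]:
                assert flag, f"{uid} has an injected decay but was not flagged"

    def test_false_flag_rate_bounded(self, gain5_session, gain5_profiles):
        session, gt = gain5_session
        res = detect_aftereffects(session, gain5_profiles)
        clean = [f for u, f in res["unit_flags"].items() if not gt.aftereffect[u]]
        assert np.mean(clean) <= 0.10


class TestDecodeTimecourse:
    def test_baseline_chance_and_event_above(self, gain5_session, gain5_profiles):
        from ethospike.temporal import event_period_decode_timecourse

        session, _ = gain5_session
        res = event_period_decode_timecourse(session, gain5_profiles)
        tags = np.array([t for t, _ in res["rel_times"]])
        offs = np.array([o for _, o in res["rel_times"]])
        acc = res["accuracy"]
        early_baseline = acc[(tags == "re_start") & (offs < -60)]
        during_event = acc[(tags == "re_start") & (offs >= 10)]
        assert during_event.mean() > early_baseline.mean() + 0.2
        assert abs(early_baseline.mean() - 0.25) < 0.2
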
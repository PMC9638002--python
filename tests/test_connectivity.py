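import numpy as np
import pytest

from ethospike.connectivity import (
    ConnectionRecord,
    connection_strength,
    connection_type_enrichment,
    cross_correlogram,
    detect_connection,
    paired_epoch_strength_change,
)
from ethospike.synthetic import _merge_trains, inject_connection


def _train(rng, rate, dur):
    return np.sort(rng.uniform(0, dur, rng.poisson(rate * dur)))


def _coupled_pair(rng, p=0.15, delay=1.5, dur=600.0, r_proj=8.0, r_targ=3.0):
    proj = _train(rng, r_proj, dur)
    targ = _merge_trains(
        _train(rng, r_targ, dur),
        inject_connection(proj, delay, p, jitter_ms=0.5, rng=rng),
    )
    return proj, targ


class TestCrossCorrelogram:
    def test_ccg_is_mirror_of_reversed_pair(self):
        rng = np.random.default_rng(0)
        a, b = _train(rng, 5, 60), _train(rng, 5, 60)
        ab = cross_correlogram(a, b)
        ba = cross_correlogram(b, a)
        np.testing.assert_array_equal(ab.counts, ba.counts[::-1])

    def test_single_lag_lands_in_correct_bin(self):
        ccg = cross_correlogram(np.array([0.1]), np.array([0.1015]))
        hit = ccg.counts.nonzero()[0]
        assert hit.size == 1
        assert ccg.lags_ms[hit[0]] == pytest.approx(1.5, abs=0.25)

    def test_independent_poisson_counts_match_closed_form(self):
        rng = np.random.default_rng(1)
        r1, r2, dur = 6.0, 4.0, 600.0
        ccg = cross_correlogram(_train(rng, r1, dur), _train(rng, r2, dur))
        expected = r1 * r2 * dur * 0.00025
        sd = np.sqrt(expected)
        noise = np.abs(ccg.lags_ms) > 5
        assert abs(ccg.counts[noise].mean() - expected) < 3 * sd / np.sqrt(
            noise.sum()
        )

    def test_empty_train_flagged(self):
        ccg = cross_correlogram(np.array([]), np.array([1.0]))
        assert ccg.empty and not detect_connection(ccg).significant


class TestDetectConnection:
    def test_flat_ccg_not_significant(self):
        rng = np.random.default_rng(2)
        ccg = cross_correlogram(_train(rng, 5, 300), _train(rng, 5, 300))
        assert not detect_connection(ccg).significant

    def test_injected_connection_found_at_its_delay(self):
        rng = np.random.default_rng(3)
        proj, targ = _coupled_pair(rng, p=0.15, delay=1.5)
        ccg = detect_connection(cross_correlogram(proj, targ))
        assert ccg.significant
        assert 1.0 <= ccg.peak_lag_ms <= 2.0
        assert ccg.peak_width_ms >= 0.75

    def test_reverse_direction_not_detected(self):
        rng = np.random.default_rng(3)
        proj, targ = _coupled_pair(rng, p=0.15, delay=1.5)
        assert not detect_connection(cross_correlogram(targ, proj)).significant

    def test_low_spike_count_excluded(self):
        rng = np.random.default_rng(4)
        proj, targ = _coupled_pair(rng, p=1.0, dur=10.0)  # < 100 spikes
        assert not detect_connection(cross_correlogram(proj, targ)).significant


class TestConnectionStrength:
    def test_pure_relay_has_strength_near_one(self):
        rng = np.random.default_rng(5)
        proj = _train(rng, 8.0, 600.0)
        targ = inject_connection(proj, 1.5, 1.0, jitter_ms=0.5, rng=rng)
        ccg = detect_connection(cross_correlogram(proj, targ))
        rec = connection_strength(proj, targ, ccg)
        assert rec.strength > 0.9

    def test_requires_significant_ccg(self):
        rng = np.random.default_rng(6)
        a, b = _train(rng, 5, 300), _train(rng, 5, 300)
        ccg = detect_connection(cross_correlogram(a, b))
        with pytest.raises(ValueError):
            connection_strength(a, b, ccg)

    def test_strength_tracks_transfer_probability(self):
        from ethospike.validation import strength_monotonicity

        res = strength_monotonicity(seed=0, n_replicates=5)
        assert res["mean_strength"][0] < res["mean_strength"][1] \
            < res["mean_strength"][2]


class TestEnrichment:
    def _records(self, pairs):
        return [ConnectionRecord(p, t, "whole", 1, 10, 0.1, 1.5) for p, t in pairs]

    def test_single_category_gives_unit_ratio(self):
        recs = self._records([("a", "b"), ("c", "d"), ("e", "f")])
        cats = {k: "panresponsive" for k in "abcdef"}
        r = connection_type_enrichment(recs, cats, n_resample=200, seed=0)
        assert r[("panresponsive", "panresponsive")] == pytest.approx(1.0)

    def test_exclusive_wiring_enriched_over_chance(self):
        pairs = [(f"s{i}", f"p{i}") for i in range(12)]
        recs = self._records(pairs)
        cats = {f"s{i}": "male_specific" for i in range(12)}
        cats.update({f"p{i}": "panresponsive" for i in range(12)})
        r = connection_type_enrichment(recs, cats, n_resample=500, seed=0)
        assert r[("male_specific", "panresponsive")] > 1.5

    def test_ratios_stable_across_seeds(self):
        # enough records that every expected cell count is well resolved
        pairs = [(f"s{i}", f"p{i % 8}t") for i in range(40)]
        recs = self._records(pairs)
        cats = {f"s{i}": ("male_specific" if i % 2 else "toy_specific")
                for i in range(40)}
        cats.update({f"p{i}t": ("panresponsive" if i % 2 else "decreased")
                     for i in range(8)})
        r1 = connection_type_enrichment(recs, cats, n_resample=4000, seed=1)
        r2 = connection_type_enrichment(recs, cats, n_resample=4000, seed=2)
        for k in r1:
            assert r1[k] == pytest.approx(r2[k], rel=0.05)


class TestEpochChange:
    def test_identical_epochs_give_zero_deltas(self):
        recs = [ConnectionRecord("a", "b", "event", 5, 50, 0.1, 1.5)]
        res = paired_epoch_strength_change(recs, recs)
        np.testing.assert_allclose(res["deltas"], 0.0)

    def test_sign_flip_flips_deltas(self):
        r1 = [ConnectionRecord("a", "b", "event", 5, 50, 0.10, 1.5),
              ConnectionRecord("c", "d", "event", 5, 50, 0.20, 1.5)]
        r2 = [ConnectionRecord("a", "b", "post", 5, 50, 0.15, 1.5),
              ConnectionRecord("c", "d", "post", 5, 50, 0.10, 1.5)]
        fwd = paired_epoch_strength_change(r1, r2)
        rev = paired_epoch_strength_change(r2, r1)
        np.testing.assert_allclose(fwd["deltas"], -rev["deltas"])

    def test_simulated_potentiation_detected(self):
        from ethospike.validation import epoch_plasticity

        res = epoch_plasticity(seed=0, n_pairs=25)
        assert res["mean_delta"] > 0
        assert res["p_value"] < 0.05
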
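import numpy as np
import pytest

from ethospike.decoding import (
    category_omission,
    interaction_decoder,
    loo_stimulus_decoder,
    neuron_dropping_curve,
    session_score_matrix,
    depth_restricted_decoder,
)


def _separable(rng, n_per_class=4, n_units=12, n_classes=4, noise=0.05):
    X, y = [], []
    for c in range(n_classes):
        mu = np.zeros(n_units)
        mu[c * 3 : c * 3 + 3] = 0.8
        for _ in range(n_per_class):
            X.append(mu + noise * rng.standard_normal(n_units))
            y.append(f"class{c}")
    return np.array(X), np.array(y)


class TestLooStimulusDecoder:
    def test_separable_scores_decode_perfectly(self):
        X, y = _separable(np.random.default_rng(0))
        rep = loo_stimulus_decoder(X, y, n_shuffles=20, seed=0)
        assert rep.accuracy == 1.0

    def test_shuffled_labels_sit_at_chance(self):
        # moderate noise and enough events: tightly clustered features or
        # tiny event counts bias leave-one-out under label permutation
        X, y = _separable(np.random.default_rng(1), n_per_class=10, noise=0.8)
        rep = loo_stimulus_decoder(X, y, n_shuffles=150, seed=1)
        assert abs(rep.shuffle_mean - 0.25) < 0.03

    def test_single_event_class_warns(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((5, 4))
        y = np.array(["a", "a", "b", "b", "c"])
        with pytest.warns(UserWarning, match="single event"):
            loo_stimulus_decoder(X, y, n_shuffles=1, seed=0)


class TestNeuronDropping:
    def test_full_set_matches_loo_decoder(self):
        X, y = _separable(np.random.default_rng(3))
        rep = loo_stimulus_decoder(X, y, n_shuffles=1, seed=0)
        curve = neuron_dropping_curve(X, y, n_grid=[X.shape[1]], seed=0)
        assert curve["mean_accuracy"][-1] == rep.accuracy

    def test_mean_accuracy_nondecreasing_on_separable_data(self):
        X, y = _separable(np.random.default_rng(4))
        curve = neuron_dropping_curve(X, y, n_grid=[2, 4, 8, 12], n_repeat=40,
                                      seed=0)
        acc = curve["mean_accuracy"]
        assert all(b >= a - 0.05 for a, b in zip(acc, acc[1:]))

    def test_omitting_informative_units_hurts_more(self):
        rng = np.random.default_rng(5)
        X, y = _separable(rng, n_units=12)
        # add 12 pure-noise units
        X = np.hstack([X, 0.05 * rng.standard_normal((X.shape[0], 12))])
        cats = ["event_specific"] * 12 + ["nonresponsive"] * 12
        omit_spec = category_omission(X, y, cats, "event_specific",
                                      n_repeat=30, seed=0)
        omit_non = category_omission(X, y, cats, "nonresponsive",
                                     n_repeat=30, seed=0)
        assert omit_spec["delta"] < omit_non["delta"]

    def test_absent_category_rejected(self):
        X, y = _separable(np.random.default_rng(6))
        with pytest.raises(ValueError):
            category_omission(X, y, ["a"] * X.shape[1], "missing")


class TestInteractionDecoder:
    def _population(self, rng, gated=True, n_bins=300, n_units=12):
        mask = rng.uniform(size=n_bins) < 0.5
        X = rng.standard_normal((n_bins, n_units))
        if gated:
            X[mask] += 1.5
        ev = np.repeat(np.arange(3), n_bins // 3)
        return X, mask, ev

    def test_gated_population_discriminates(self):
        rng = np.random.default_rng(7)
        X, mask, ev = self._population(rng, gated=True)
        res = interaction_decoder(X, mask, ev, n_shuffles=5, seed=0)
        assert all(a > 0.9 for a in res["per_event_auc"].values())

    def test_shuffle_control_near_half(self):
        rng = np.random.default_rng(8)
        X, mask, ev = self._population(rng, gated=True)
        res = interaction_decoder(X, mask, ev, n_shuffles=40, seed=0)
        for a in res["per_event_shuffle_auc"].values():
            assert abs(a - 0.5) < 0.1

    def test_ungated_population_near_chance(self):
        rng = np.random.default_rng(9)
        X, mask, ev = self._population(rng, gated=False)
        res = interaction_decoder(X, mask, ev, n_shuffles=5, seed=0)
        for a in res["per_event_auc"].values():
            assert abs(a - 0.5) < 0.2

    def test_single_label_event_skipped(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((60, 5))
        mask = np.zeros(60, bool)
        ev = np.repeat([0, 1], 30)
        res = interaction_decoder(X, mask, ev, n_shuffles=2, seed=0)
        assert list(res["skipped_events"]) == [0, 1]


class TestSessionDecoding:
    def test_gain5_session_decodes_above_09(self, gain5_session, gain5_profiles):
        session, _ = gain5_session
        X, y, _ids = session_score_matrix(session, gain5_profiles)
        assert X.shape[1] >= 10
        rep = loo_stimulus_decoder(X, y, n_shuffles=5, seed=0)
        assert rep.accuracy > 0.9

    def test_depth_filter_reduces_to_full_decoder_when_all_pass(
        self, gain5_session, gain5_profiles
    ):
        session, _ = gain5_session
        X, y, _ids = session_score_matrix(session, gain5_profiles)
        full = loo_stimulus_decoder(X, y, n_shuffles=1, seed=0)
        banded = depth_restricted_decoder(
            session, gain5_profiles, center_um=3840.0, half_window_um=1e7,
            min_units=2, n_shuffles=1,
        )
        assert banded.accuracy == full.accuracy


class TestWindowDecoder:
    def test_precontact_rise_and_early_chance(self, gain5_session, gain5_profiles):
        from ethospike.decoding import window_decoder

        session, _ = gain5_session
        res = window_decoder(session, gain5_profiles)
        starts = np.array(res["window_start_s"])
        acc = np.array(res["accuracy"])
        # windows ending well before presentation carry no stimulus signal
        early = acc[starts <= -30.0 + 1e-9][:1]
        late = acc[starts >= 0.0]
        assert late.mean() > 0.9
        assert late.mean() > early.mean()
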
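"""Seeded parameter-recovery benchmarks.

Every analysis stage in this package is validated against the synthetic
generator's ground truth: the generator injects a known effect (response
category, spike coupling, aftereffect decay, behavior bout, clock drift,
waveform identity) and the corresponding benchmark here measures how well
the analysis recovers it.  The functions are deterministic given their
seed and sized to run on one CPU in seconds to a couple of minutes; both
the test suite and the results-reproduction script call them.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import synthetic
from .io_core import align_sync
from .scoring import response_score, score_session
from .synthetic import SimConfig, inject_connection, simulate_session

__all__ = [
    "auroc_oracle_max_error",
    "category_recovery",
    "connectivity_recovery",
    "ccg_false_positive_rate",
    "strength_monotonicity",
    "epoch_plasticity",
    "decoding_benchmark",
    "aftereffect_recovery",
    "onset_synchrony_benchmark",
    "behavior_benchmark",
    "sync_benchmark",
    "matching_benchmark",
]


# ---------------------------------------------------------------------------
# response scoring


def mann_whitney_pair_count(baseline, event) -> float:
    """Brute-force auROC: fraction of (event, baseline) pairs won, with
    half credit for ties.  O(n*m) by construction - the oracle against
    which the rank-sum implementation is checked."""
    wins = ties = 0
    for e in event:
        for b in baseline:
            if e > b:
                wins += 1
            elif e == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(event) * len(baseline))


def auroc_oracle_max_error(seed: int = 0, n_instances: int = 1000) -> float:
    """Max |response_score - pair-count oracle| over random instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        nb = int(rng.integers(1, 31))
        ne = int(rng.integers(1, 31))
        b = rng.integers(0, 5, nb).astype(float)
        e = rng.integers(0, 5, ne).astype(float)
        got = response_score(b, e, min_spikes=0)
        expect = (mann_whitney_pair_count(b, e) - 0.5) * 2.0
        worst = max(worst, abs(got - expect))
    return worst


def category_recovery(
    seed: int = 0, n_units: int = 200, event_gain: float | None = None
) -> dict:
    """Fraction of units whose response category is recovered exactly."""
    cfg = SimConfig(
        n_units=n_units,
        events_per_class=2,
        event_gain=event_gain,
        seed=seed,
    )
    session, gt = simulate_session(cfg)
    profiles = score_session(session)
    hits = sum(p.category == gt.category[p.unit_id] for p in profiles)
    return dict(accuracy=hits / n_units, n=n_units)


# ---------------------------------------------------------------------------
# connectivity


def _poisson_train(rng, rate, duration):
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0, duration, n))


def connectivity_recovery(
    seed: int = 0,
    n_units: int = 50,
    n_connections: int = 20,
    duration_s: float = 600.0,
    proj_rate_range=(5.0, 8.0),
    background_rate_range=(1.0, 3.0),
    transfer_prob_range=(0.1, 0.2),
    delay_range_ms=(1.0, 3.0),
) -> dict:
    """Precision/recall of CCG connection detection on injected couplings.

    Projection units fire at interneuron-like rates (>=3,000 spikes over
    the session); the rest of the population fires at the low pyramidal
    rates typical of the recorded region.
    """
    from .connectivity import cross_correlogram, detect_connection

    rng = np.random.default_rng(seed)
    # node-disjoint wiring: chains and common input would themselves induce
    # real short-latency correlations and confound the precision estimate
    order = rng.permutation(n_units)
    pairs = {
        (int(order[2 * k]), int(order[2 * k + 1])) for k in range(n_connections)
    }
    proj_nodes = {i for i, _ in pairs}
    trains = [
        _poisson_train(
            rng,
            rng.uniform(*(proj_rate_range if i in proj_nodes
                          else background_rate_range)),
            duration_s,
        )
        for i in range(n_units)
    ]
    truth = {}
    for i, j in pairs:
        p = rng.uniform(*transfer_prob_range)
        d = rng.uniform(*delay_range_ms)
        induced = inject_connection(trains[i], d, p, jitter_ms=0.5, rng=rng)
        trains[j] = synthetic._merge_trains(trains[j], induced)
        truth[(i, j)] = (d, p)
    detected = set()
    reversed_hits = 0
    for a in range(n_units):
        for b in range(n_units):
            if a == b:
                continue
            ccg = cross_correlogram(trains[a], trains[b],
                                    projection_id=str(a), target_id=str(b))
            detect_connection(ccg)
            if ccg.significant:
                detected.add((a, b))
                if (b, a) in truth:
                    reversed_hits += 1
    tp = len(detected & set(truth))
    precision = tp / len(detected) if detected else float("nan")
    recall = tp / len(truth)
    return dict(
        precision=precision,
        recall=recall,
        n_detected=len(detected),
        n_true=len(truth),
        reversed=reversed_hits,
    )


def ccg_false_positive_rate(
    seed: int = 0,
    n_pairs: int = 1000,
    duration_s: float = 600.0,
    rate_range=(1.0, 10.0),
) -> dict:
    """Detection rate on independent Poisson pairs (3-SD rule calibration)."""
    from .connectivity import cross_correlogram, detect_connection

    rng = np.random.default_rng(seed)
    fp = 0
    for _ in range(n_pairs):
        a = _poisson_train(rng, rng.uniform(*rate_range), duration_s)
        b = _poisson_train(rng, rng.uniform(*rate_range), duration_s)
        ccg = detect_connection(cross_correlogram(a, b))
        fp += int(ccg.significant)
    return dict(rate=fp / n_pairs, n=n_pairs)


def strength_monotonicity(
    seed: int = 0,
    probs=(0.05, 0.1, 0.2),
    n_replicates: int = 20,
    duration_s: float = 600.0,
    rate_hz: float = 8.0,
) -> dict:
    """Mean connection strength per transfer probability (should increase)."""
    from .connectivity import connection_strength, cross_correlogram, detect_connection

    rng = np.random.default_rng(seed)
    means = []
    for p in probs:
        vals = []
        for _ in range(n_replicates):
            proj = _poisson_train(rng, rate_hz, duration_s)
            targ = _poisson_train(rng, rate_hz, duration_s)
            targ = synthetic._merge_trains(
                targ, inject_connection(proj, 1.5, p, jitter_ms=0.5, rng=rng)
            )
            ccg = detect_connection(cross_correlogram(proj, targ))
            if ccg.significant:
                vals.append(connection_strength(proj, targ, ccg).strength)
        means.append(float(np.mean(vals)))
    return dict(probs=list(probs), mean_strength=means)


def epoch_plasticity(
    seed: int = 0,
    n_pairs: int = 50,
    p_event: float = 0.1,
    p_post: float = 0.15,
    epoch_s: float = 300.0,
    rate_hz: float = 10.0,
) -> dict:
    """Paired event-to-post strength change when coupling strengthens."""
    from .connectivity import connection_strength, cross_correlogram, detect_connection

    rng = np.random.default_rng(seed)
    deltas = []
    for _ in range(n_pairs):
        strengths = {}
        for epoch, p in (("event", p_event), ("post", p_post)):
            proj = _poisson_train(rng, rate_hz, epoch_s)
            targ = _poisson_train(rng, rate_hz, epoch_s)
            targ = synthetic._merge_trains(
                targ, inject_connection(proj, 1.5, p, jitter_ms=0.5, rng=rng)
            )
            ccg = detect_connection(cross_correlogram(proj, targ))
            if ccg.significant:
                strengths[epoch] = connection_strength(proj, targ, ccg).strength
        if "event" in strengths and "post" in strengths:
            deltas.append(strengths["post"] - strengths["event"])
    deltas = np.asarray(deltas)
    t = stats.ttest_rel(deltas + 0.0, np.zeros_like(deltas)) if deltas.size >= 2 else None
    # paired t of post vs event == one-sample t of the deltas
    return dict(
        mean_delta=float(deltas.mean()),
        p_value=float(t.pvalue) if t else float("nan"),
        n_pairs=int(deltas.size),
    )


# ---------------------------------------------------------------------------
# decoding / temporal


def decoding_benchmark(
    seed: int = 0, n_units: int = 40, n_shuffles: int = 500
) -> dict:
    """Stimulus decoding on a gain-5 synthetic session.

    Returns leave-one-out accuracy, shuffle-control mean, the
    neuron-dropping curve, and category-omission deltas.
    """
    from .decoding import (
        category_omission,
        loo_stimulus_decoder,
        neuron_dropping_curve,
        session_score_matrix,
    )

    cfg = SimConfig(n_units=n_units, events_per_class=4, event_gain=5.0, seed=seed)
    session, gt = simulate_session(cfg)
    profiles = score_session(session)
    X, y, unit_ids = session_score_matrix(session, profiles)
    report = loo_stimulus_decoder(X, y, n_shuffles=n_shuffles, seed=seed)
    curve = neuron_dropping_curve(X, y, n_repeat=100, seed=seed)
    # the responsive matrix contains no nonresponsive units, so the
    # omission contrast uses the full unit set scored by true category
    all_vectors = np.array(
        [[p.event_scores[ev.label] for p in profiles] for ev in session.events]
    )
    cats_all = [
        "event_specific" if gt.category[p.unit_id].endswith("_specific")
        else gt.category[p.unit_id]
        for p in profiles
    ]
    n_spec = cats_all.count("event_specific")
    n_non = cats_all.count("nonresponsive")
    omit_spec = category_omission(all_vectors, y, cats_all, "event_specific",
                                  n_repeat=50, seed=seed)
    omit_non = category_omission(all_vectors, y, cats_all, "nonresponsive",
                                 n_repeat=50, seed=seed)
    return dict(
        accuracy=report.accuracy,
        shuffle_mean=report.shuffle_mean,
        n_responsive=X.shape[1],
        dropping_curve=curve,
        omission_specific=omit_spec,
        omission_nonresponsive=omit_non,
        n_specific=n_spec,
        n_nonresponsive=n_non,
    )


def aftereffect_recovery(seed: int = 0, n_units: int = 100) -> dict:
    """Recovered aftereffect proportion vs the injected 30%."""
    from .temporal import detect_aftereffects

    mix = {
        "male_specific": 0.175,
        "female_specific": 0.175,
        "toy_specific": 0.175,
        "food_specific": 0.175,
        "panresponsive": 0.3,
        "decreased": 0.0,
        "nonresponsive": 0.0,
    }
    cfg = SimConfig(n_units=n_units, class_mix=mix, events_per_class=2, seed=seed)
    session, gt = simulate_session(cfg)
    profiles = score_session(session)
    res = detect_aftereffects(session, profiles)
    flags = res["unit_flags"]
    detected = float(np.mean([flags[u] for u in flags]))
    injected = float(np.mean([gt.aftereffect[u] for u in flags]))
    false_flags = [flags[u] for u in flags if not gt.aftereffect[u]]
    return dict(
        detected_proportion=detected,
        injected_proportion=injected,
        false_flag_rate=float(np.mean(false_flags)) if false_flags else 0.0,
        n_units=len(flags),
    )


def onset_synchrony_benchmark(seed: int = 0, n_units: int = 40) -> dict:
    """Within- vs across-event onset-latency distances (KS test)."""
    from .temporal import onset_synchrony

    cfg = SimConfig(n_units=n_units, events_per_class=4, event_gain=5.0, seed=seed)
    session, _ = simulate_session(cfg)
    profiles = score_session(session)
    res = onset_synchrony(session, profiles)
    return dict(
        within_mean=float(res["within"].mean()),
        across_mean=float(res["across"].mean()),
        p_value=res["p_value"],
        n_within=int(res["within"].size),
        n_across=int(res["across"].size),
    )


# ---------------------------------------------------------------------------
# behavior / sync / waveform


def behavior_benchmark(seed: int = 0, duration_s: float = 240.0) -> dict:
    """Scripted-bout classifier accuracy plus permuted-label control.

    Frames are subsampled to balanced classes for the permutation control
    so chance is exactly 1/7.
    """
    from .behavior import clean_tracking, compute_features, crossval_behavior_classifier

    cfg = SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    track, labels = synthetic.simulate_tracking(
        cfg, duration_s=duration_s, rng=rng, balanced=True
    )
    feats = compute_features(clean_tracking(track))
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    nmin = counts.min()
    idx = np.concatenate(
        [rng.choice(np.flatnonzero(labels == c), nmin, replace=False) for c in classes]
    )
    idx = rng.permutation(idx)
    Xb, yb = feats.iloc[idx], labels[idx]
    acc = crossval_behavior_classifier(Xb, yb, seed=seed)
    perm = rng.permutation(yb)
    acc_perm = crossval_behavior_classifier(Xb, perm, seed=seed)
    return dict(
        accuracy=acc,
        permuted_accuracy=acc_perm,
        chance=1.0 / len(classes),
        n_frames=int(len(yb)),
    )


def sync_benchmark(seed: int = 0, duration_s: float = 120.0) -> dict:
    """Frame-time recovery error under 80% pulses, offset, and drift."""
    cfg = SimConfig(
        n_units=2, events_per_class=1, baseline_s=duration_s / 9,
        event_s=duration_s / 9, post_s=duration_s / 9, seed=seed,
        contact_delay_range=(2.0, 8.0), clock_offset_s=3.0, clock_drift=2e-4,
    )
    session, gt = simulate_session(cfg)
    recovered = align_sync(session.sync)
    err = np.abs(recovered - gt.frame_times)
    return dict(
        max_error_s=float(err.max()),
        frame_period_s=1.0 / cfg.frame_rate,
        n_frames=int(recovered.size),
    )


def matching_benchmark(seed: int = 0, n_units: int = 100) -> dict:
    """Cross-day matching accuracy and unrelated-pair false acceptance."""
    from .waveform import _pair_similarity, _prepared, match_units_across_days

    d1, d2, _, _ = synthetic.simulate_waveform_cohort(n_units=n_units, seed=seed)
    matches = match_units_across_days(d1, d2)
    correct = sum(m.day2_id == m.day1_id + "_d2" for m in matches)
    # null calibration: same-index units from two unrelated cohorts
    da, _, _, _ = synthetic.simulate_waveform_cohort(n_units, seed=seed + 1000)
    db, _, _, _ = synthetic.simulate_waveform_cohort(n_units, seed=seed + 2000)
    false_accepts = 0
    for ua, ub in zip(da, db):
        s, c = _pair_similarity(_prepared(ua.waveform), _prepared(ub.waveform))
        false_accepts += int(s >= 0.8 and c >= 0.9)
    return dict(
        correct_fraction=correct / n_units,
        n_matched=len(matches),
        false_acceptance_rate=false_accepts / n_units,
        n_units=n_units,
    )
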
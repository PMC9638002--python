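"""Event-start dynamics: z-scored PSTHs, time-warping, onset synchrony,
and post-event aftereffects.

Firing around each event is expressed as a z-score of 100-ms binned rates
relative to that event's own baseline. For display across events with
different presentation-to-contact delays, traces can be time-warped onto a
common frame by piecewise cubic splines; every quantification runs on the
raw, unwarped z traces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.interpolate import CubicSpline

from .io_core import EventBlock, Session, Unit
from .scoring import ResponseProfile, binned_rates

__all__ = [
    "ZPsth",
    "WarpedTrace",
    "zscore_psth",
    "timewarp",
    "onset_synchrony",
    "detect_aftereffects",
    "event_period_decode_timecourse",
]

log = logging.getLogger(__name__)


@dataclass
class ZPsth:
    unit_id: str
    event_label: str
    bin_centers: np.ndarray  # seconds, ephys clock
    z: np.ndarray
    baseline_mean_hz: float
    baseline_sd_hz: float


@dataclass
class WarpedTrace:
    samples: np.ndarray
    anchor_presentation: int  # index into samples
    anchor_contact: int


def zscore_psth(
    unit: Unit,
    event: EventBlock,
    bin_s: float = 0.1,
    span: tuple[float, float] | None = None,
    sd_floor_hz: float = 0.1,
) -> ZPsth:
    """Baseline-referenced z-scored PSTH for one unit and one event.

    z = (rate - baseline mean) / baseline SD per bin, with baseline
    statistics computed from the event's own baseline period binned at the
    same bin_s.  For units silent at baseline the SD is floored so z stays
    finite.
    """
    start, end = span if span is not None else (event.t_presentation, event.t_event_end)
    if end <= start:
        raise ValueError("degenerate event interval")
    base = binned_rates(unit.spike_times, event.baseline, bin_s)
    mu, sd = float(base.mean()), float(base.std())
    sd = max(sd, sd_floor_hz)  # keep z finite for baseline-silent units
    rates = binned_rates(unit.spike_times, (start, end), bin_s)
    centers = start + (np.arange(rates.size) + 0.5) * bin_s
    return ZPsth(
        unit_id=unit.unit_id,
        event_label=event.label,
        bin_centers=centers,
        z=(rates - mu) / sd,
        baseline_mean_hz=mu,
        baseline_sd_hz=sd,
    )


def timewarp(
    trace: ZPsth,
    anchors: tuple[float, float],
    segment_lengths: tuple[int, int, int] = (50, 100, 50),
) -> WarpedTrace:
    """Resample a z trace onto a common frame anchored at presentation and
    contact.

    The three segments [start, presentation], [presentation, contact], and
    [contact, end] are each cubic-spline resampled to fixed lengths;
    anchor samples are preserved exactly.
    """
    t_pres, t_contact = anchors
    t = trace.bin_centers
    if not (t[0] <= t_pres < t_contact <= t[-1]):
        raise ValueError("anchors must lie inside the trace span, presentation first")
    spline = CubicSpline(t, trace.z)
    n1, n2, n3 = segment_lengths
    seg1 = np.linspace(t[0], t_pres, n1, endpoint=False)
    seg2 = np.linspace(t_pres, t_contact, n2, endpoint=False)
    seg3 = np.linspace(t_contact, t[-1], n3)
    samples = spline(np.concatenate([seg1, seg2, seg3]))
    # anchors map to the segment boundaries exactly
    samples[n1] = float(spline(t_pres))
    samples[n1 + n2] = float(spline(t_contact))
    return WarpedTrace(samples=samples, anchor_presentation=n1, anchor_contact=n1 + n2)


# ---------------------------------------------------------------------------
# onset synchrony


def peak_latency(
    unit: Unit, event: EventBlock, bin_s: float = 0.1
) -> float | None:
    """Latency (s after presentation) of peak z between presentation and
    contact; None when the trace never leaves zero.  Ties break earliest.
    """
    psth = zscore_psth(unit, event, bin_s, span=(event.t_presentation, event.t_contact))
    if psth.z.size == 0 or np.all(psth.z == psth.z[0]) and psth.z[0] <= 0:
        return None
    idx = int(np.argmax(psth.z))
    return float((idx + 0.5) * bin_s)


def onset_synchrony(
    session: Session,
    profiles: list[ResponseProfile],
    bin_s: float = 0.1,
) -> dict:
    """Do responsive units switch on together within a trial?

    Within-event set: |latency_i - latency_j| for all responsive-unit
    pairs inside the same event.  Across-event set: the same unit pairs,
    latencies taken from different events.  A two-sample KS test compares
    the two distance distributions; synchronous onsets make the
    within-event distances stochastically smaller.
    """
    responsive = {p.unit_id for p in profiles if p.responsive}
    units = [u for u in session.units if u.unit_id in responsive]
    lat: dict[tuple[str, str], float] = {}
    for ev in session.events:
        for u in units:
            l = peak_latency(u, ev, bin_s)
            if l is None:
                log.info("unit %s has no peak in event %s; skipped", u.unit_id, ev.label)
                continue
            lat[(u.unit_id, ev.label)] = l
    within, across = [], []
    labels = [ev.label for ev in session.events]
    for ua, ub in combinations([u.unit_id for u in units], 2):
        for la in labels:
            if (ua, la) in lat and (ub, la) in lat:
                within.append(abs(lat[(ua, la)] - lat[(ub, la)]))
            for lb in labels:
                if lb != la and (ua, la) in lat and (ub, lb) in lat:
                    across.append(abs(lat[(ua, la)] - lat[(ub, lb)]))
    within = np.asarray(within)
    across = np.asarray(across)
    if within.size and across.size:
        ks = stats.ks_2samp(within, across)
        statistic, pvalue = float(ks.statistic), float(ks.pvalue)
    else:
        statistic = pvalue = float("nan")
    return dict(
        within=within,
        across=across,
        ks_statistic=statistic,
        p_value=pvalue,
    )


# ---------------------------------------------------------------------------
# aftereffects


def detect_aftereffects(
    session: Session,
    profiles: list[ResponseProfile],
    z_thresh: float = 1.0,
    bin_s: float = 10.0,
    horizon_s: float = 180.0,
) -> dict:
    """Persistent post-event activity.

    For each responsive unit and each of its responsive events, the rate
    over [event_end, event_end + 3 min) is binned at 10 s and z-scored to
    the event's baseline; the unit/event is flagged when the mean bin z
    exceeds z_thresh.  A unit's aftereffect flag is the majority vote over
    its analyzed events.  Returns per-unit flags, per-(unit, event) flags,
    and per-category proportions.
    """
    by_cat: dict[str, list[bool]] = {}
    unit_flags: dict[str, bool] = {}
    pair_flags: dict[tuple[str, str], bool] = {}
    mean_z: dict[tuple[str, str], float] = {}
    for p in profiles:
        if not p.responsive:
            continue
        unit = session.unit(p.unit_id)
        votes = []
        for ev in session.events:
            if p.event_scores.get(ev.label, 0.0) <= 0.2:
                continue  # only events the unit responded to
            end = min(ev.t_event_end + horizon_s, ev.t_post_end)
            if end < ev.t_event_end + horizon_s:
                log.warning(
                    "post period of %s truncated to %.0f s", ev.label,
                    end - ev.t_event_end,
                )
            if end - ev.t_event_end < bin_s:
                continue
            psth = zscore_psth(unit, ev, bin_s, span=(ev.t_event_end, end))
            flagged = bool(psth.z.mean() > z_thresh)
            pair_flags[(p.unit_id, ev.label)] = flagged
            mean_z[(p.unit_id, ev.label)] = float(psth.z.mean())
            votes.append(flagged)
        if votes:
            unit_flags[p.unit_id] = sum(votes) * 2 >= len(votes)
            by_cat.setdefault(p.category, []).append(unit_flags[p.unit_id])
    proportions = {c: float(np.mean(v)) for c, v in by_cat.items()}
    return dict(
        unit_flags=unit_flags,
        pair_flags=pair_flags,
        mean_z=mean_z,
        proportions=proportions,
    )


# ---------------------------------------------------------------------------
# peri-event decoding timecourse


def event_period_decode_timecourse(
    session: Session,
    profiles: list[ResponseProfile],
    bin_s: float = 10.0,
    margin_s: float = 120.0,
    seed: int = 0,
) -> dict:
    """Decoding accuracy per 10-s bin from 2 min before event start to
    2 min after event stop.

    A stimulus decoder is trained on whole-event response scores; each
    peri-event bin then contributes a per-unit response score (that bin's
    1-s rates vs the event baseline) which the trained decoder classifies.
    Bins are aligned to event start for the pre/during-start stretch and
    to event end for the post stretch.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    from .scoring import population_vectors, response_score

    resp = [p for p in profiles if p.responsive]
    if len(resp) < 2:
        raise ValueError("need at least 2 responsive units to decode")
    vectors = population_vectors(profiles, session.events)
    labels = np.array([ev.stimulus_class for ev in session.events])
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto",
                                     priors=np.full(len(set(labels)), 1.0 / len(set(labels))))
    lda.fit(vectors.to_numpy(), labels)

    units = {p.unit_id: session.unit(p.unit_id) for p in resp}
    # bins from 2 min before event start into the event, and from late
    # event through 2 min after event stop
    offsets_start = np.arange(-margin_s, margin_s, bin_s)  # re event start
    offsets_end = np.arange(-margin_s, margin_s, bin_s)  # re event end
    rel_times, accs = [], []

    def _decode_bins(anchor_of, offsets, tag):
        for off in offsets:
            feats, y = [], []
            for ev in session.events:
                t0 = anchor_of(ev) + off
                t1 = t0 + bin_s
                if t0 < ev.t_baseline_start or t1 > ev.t_post_end:
                    continue
                base = {
                    uid: binned_rates(u.spike_times, ev.baseline, 1.0)
                    for uid, u in units.items()
                }
                row = [
                    response_score(
                        base[uid],
                        binned_rates(u.spike_times, (t0, t1), 1.0),
                        min_spikes=0,
                    )
                    for uid, u in units.items()
                ]
                feats.append(row)
                y.append(ev.stimulus_class)
            if feats:
                pred = lda.predict(np.asarray(feats))
                accs.append(float(np.mean(pred == np.asarray(y))))
                rel_times.append((tag, float(off)))

    _decode_bins(lambda ev: ev.t_presentation, offsets_start, "re_start")
    _decode_bins(lambda ev: ev.t_event_end, offsets_end, "re_end")
    return dict(rel_times=rel_times, accuracy=np.asarray(accs))
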
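"""Synthetic session generator with ground truth.

Emulates the statistical structure of ethological-event recordings from the
basolateral amygdala: low baseline firing rates (log-normal, median about
0.5 spikes/s), event-specific units whose rate rises 3-6x during their
preferred stimulus class starting shortly before first contact,
panresponsive units with presentation/removal transients, units with
decreased firing during one class, minutes-long exponentially decaying
aftereffects after stimulus removal, millisecond-latency pairwise spike
coupling, and two-animal pose tracks with scripted behavior bouts.

Spike trains are inhomogeneous Poisson: lambda(t) = baseline * gain(t) with
gain piecewise constant except for the exponential aftereffect decay
(sampled by thinning).  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import STIMULUS_CLASSES, EventBlock, Session, SyncTrain, Unit

__all__ = [
    "SimConfig",
    "Connection",
    "GroundTruth",
    "simulate_session",
    "inject_connection",
    "simulate_tracking",
    "BEHAVIOR_LABELS",
]

BEHAVIOR_LABELS = (
    "non-social",
    "head-head",
    "head-tail",
    "approach",
    "following",
    "conspecific-contact",
    "other-social",
)

CATEGORIES = (
    "male_specific",
    "female_specific",
    "toy_specific",
    "food_specific",
    "panresponsive",
    "decreased",
    "nonresponsive",
)


@dataclass
class Connection:
    """A directed, fixed-delay spike coupling from one unit onto another."""

    projection: str
    target: str
    delay_ms: float
    transfer_prob: float
    jitter_ms: float = 0.5  # half-width of uniform lag jitter

    def __post_init__(self) -> None:
        if not 0.0 <= self.transfer_prob <= 1.0:
            raise ValueError("transfer_prob must be in [0, 1]")
        if not 0.0 < self.delay_ms <= 5.0:
            raise ValueError("delay_ms must be in (0, 5] ms")


@dataclass
class SimConfig:
    """Parameters of one simulated session.

    class_mix gives the proportion of units per response category; the
    four event-specific entries split "event_specific" across classes.
    baseline rates are log-normal with the given median (spikes/s) and
    log-SD sigma; panresponsive units draw from the higher median.
    """

    n_units: int = 50
    class_mix: dict = field(
        default_factory=lambda: {
            "male_specific": 0.0625,
            "female_specific": 0.0625,
            "toy_specific": 0.0625,
            "food_specific": 0.0625,
            "panresponsive": 0.12,
            "decreased": 0.08,
            "nonresponsive": 0.55,
        }
    )
    baseline_rate_median: float = 0.5  # spikes/s, event-specific & nonresponsive
    baseline_rate_sigma: float = 0.5  # log-SD
    panresponsive_rate_median: float = 2.0
    event_gain_range: tuple[float, float] = (3.0, 6.0)  # multiplicative
    event_gain: float | None = None  # fix the gain instead of sampling
    presentation_transient_gain: float = 3.0  # panresponsive on/off bursts
    presentation_transient_s: float = 2.0
    aftereffect_prob: float = 0.3  # fraction of responsive units, exact
    aftereffect_tau_s: float = 120.0
    onset_jitter_s: float = 0.5  # per-unit jitter around the trial onset
    events_per_class: int = 2
    baseline_s: float = 300.0
    event_s: float = 300.0
    post_s: float = 300.0
    contact_delay_range: tuple[float, float] = (2.0, 20.0)  # s after presentation
    connections: list[Connection] = field(default_factory=list)
    frame_rate: float = 30.0
    sync_send_prob: float = 0.8
    clock_offset_s: float = 3.0
    clock_drift: float = 1e-4  # fractional ephys-vs-camera rate mismatch
    with_tracking: bool = False
    tracking_duration_s: float | None = None
    bout_duration_s: tuple[float, float] = (1.0, 4.0)
    nonsocial_fraction: float = 0.5
    dropout_prob: float = 0.03  # low-likelihood tracking points
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class_mix proportions sum to {total}, expected 1")
        lo, hi = self.event_gain_range
        if lo <= 0 or (self.event_gain is not None and self.event_gain <= 0):
            raise ValueError("event gain must be positive")
        for c in self.connections:
            Connection(c.projection, c.target, c.delay_ms, c.transfer_prob)


@dataclass
class GroundTruth:
    category: dict  # unit_id -> category (event-specific carries its class)
    baseline_rate: dict  # unit_id -> spikes/s
    event_gain: dict  # unit_id -> gain used (1.0 for nonresponsive)
    aftereffect: dict  # unit_id -> bool
    aftereffect_tau_s: float
    connections: list[Connection]
    trial_onsets: dict  # event label -> common onset time (s, ephys clock)
    frame_times: np.ndarray | None = None  # true ephys time of each video frame
    behavior_labels: np.ndarray | None = None  # per-frame true label

    def responsive_units(self) -> list[str]:
        return [
            u
            for u, c in self.category.items()
            if c not in ("nonresponsive", "decreased")
        ]


# ---------------------------------------------------------------------------
# spike-train primitives


def _poisson_constant(rng, rate, t0, t1):
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def _poisson_decay(rng, baseline, gain, tau, t0, t1):
    """Thinning sampler for lambda(t) = baseline*(1+(gain-1)exp(-(t-t0)/tau))."""
    lam_max = baseline * gain
    cand = _poisson_constant(rng, lam_max, t0, t1)
    if cand.size == 0:
        return cand
    lam = baseline * (1.0 + (gain - 1.0) * np.exp(-(cand - t0) / tau))
    keep = rng.uniform(0, lam_max, cand.size) < lam
    return cand[keep]


def inject_connection(
    projection_spikes: np.ndarray,
    delay_ms: float,
    transfer_prob: float,
    jitter_ms: float = 0.25,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Spikes a target fires because of a projection unit.

    Each projection spike independently triggers a target spike at
    +delay_ms, jittered uniformly by +/- jitter_ms, with probability
    transfer_prob.
    """
    if not 0.0 <= transfer_prob <= 1.0:
        raise ValueError("transfer_prob must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    proj = np.asarray(projection_spikes, float)
    keep = rng.uniform(size=proj.size) < transfer_prob
    out = proj[keep] + delay_ms / 1000.0
    if jitter_ms > 0:
        out = out + rng.uniform(-jitter_ms, jitter_ms, out.size) / 1000.0
    return np.sort(out)


def _merge_trains(background: np.ndarray, induced: np.ndarray, min_gap_s=5e-5):
    merged = np.sort(np.concatenate([background, induced]))
    if merged.size < 2:
        return merged
    keep = np.concatenate([[True], np.diff(merged) >= min_gap_s])
    return merged[keep]


# ---------------------------------------------------------------------------
# session assembly


def _event_schedule(cfg: SimConfig, rng) -> tuple[list[EventBlock], dict]:
    order: list[str] = []
    for _ in range(cfg.events_per_class):
        battery = list(STIMULUS_CLASSES)
        rng.shuffle(battery)
        order.extend(battery)
    events, trial_onsets = [], {}
    counts = {c: 0 for c in STIMULUS_CLASSES}
    t = 0.0
    for cls in order:
        counts[cls] += 1
        t_pres = t + cfg.baseline_s
        t_contact = t_pres + rng.uniform(*cfg.contact_delay_range)
        t_end = t_pres + cfg.event_s
        t_post = t_end + cfg.post_s
        block = EventBlock(cls, counts[cls], t, t_pres, t_contact, t_end, t_post)
        events.append(block)
        # shared per-trial onset: the population switches on together,
        # somewhere between presentation and first contact
        trial_onsets[block.label] = rng.uniform(t_pres, t_contact)
        t = t_post
    return events, trial_onsets


def _assign_categories(cfg: SimConfig, rng) -> list[str]:
    cats = list(cfg.class_mix)
    counts = np.floor(np.array([cfg.class_mix[c] for c in cats]) * cfg.n_units)
    counts = counts.astype(int)
    # distribute the rounding remainder to the largest fractional parts
    frac = np.array([cfg.class_mix[c] for c in cats]) * cfg.n_units - counts
    for i in np.argsort(frac)[::-1][: cfg.n_units - counts.sum()]:
        counts[i] += 1
    labels = [c for c, n in zip(cats, counts) for _ in range(n)]
    rng.shuffle(labels)
    return labels


def _unit_segments(category, gain, cfg, events, trial_onsets, aftereffect, rng,
                   decreased_class="male"):
    """Piecewise gain profile for one unit: list of (t0, t1, kind, params)."""
    segs = []
    specific = category.endswith("_specific")
    preferred = category.replace("_specific", "") if specific else None
    for ev in events:
        responds = (
            category == "panresponsive"
            or (specific and ev.stimulus_class == preferred)
        )
        decreases = category == "decreased" and ev.stimulus_class == decreased_class
        if category == "panresponsive":
            a = cfg.presentation_transient_gain
            d = cfg.presentation_transient_s
            segs.append((ev.t_presentation, ev.t_presentation + d, "const", a))
            segs.append((ev.t_event_end, ev.t_event_end + d, "const", a))
        if responds:
            onset = trial_onsets[ev.label] + rng.uniform(
                -cfg.onset_jitter_s, cfg.onset_jitter_s
            )
            onset = min(max(onset, ev.t_presentation), ev.t_contact)
            start = onset
            if category == "panresponsive":
                start = max(onset, ev.t_presentation + cfg.presentation_transient_s)
            segs.append((start, ev.t_event_end, "const", gain))
            if aftereffect:
                t0 = ev.t_event_end
                if category == "panresponsive":
                    t0 = ev.t_event_end + cfg.presentation_transient_s
                segs.append((t0, ev.t_post_end, "decay", gain))
        elif decreases:
            segs.append((ev.t_presentation, ev.t_event_end, "const", 1.0 / gain))
    return segs


def _sample_unit_train(baseline, segs, duration, tau, rng):
    # sample the flat background first, then carve out / overlay segments
    segs = sorted(segs)
    spikes = []
    t = 0.0
    for t0, t1, kind, g in segs:
        t0, t1 = max(t0, t), min(t1, duration)
        if t1 <= t0:
            continue
        if t0 > t:
            spikes.append(_poisson_constant(rng, baseline, t, t0))
        if kind == "const":
            spikes.append(_poisson_constant(rng, baseline * g, t0, t1))
        else:  # exponential decay back to baseline
            spikes.append(_poisson_decay(rng, baseline, g, tau, t0, t1))
        t = t1
    if t < duration:
        spikes.append(_poisson_constant(rng, baseline, t, duration))
    out = np.concatenate(spikes) if spikes else np.array([])
    out = np.sort(out)
    if out.size > 1:  # enforce a 0.05-ms separation so trains stay strict
        out = out[np.concatenate([[True], np.diff(out) >= 5e-5])]
    return out


def simulate_session(config: SimConfig) -> tuple[Session, GroundTruth]:
    """Generate one session plus the ground truth that produced it."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    events, trial_onsets = _event_schedule(cfg, rng)
    duration = events[-1].t_post_end
    categories = _assign_categories(cfg, rng)

    lo, hi = cfg.event_gain_range
    # aftereffects hit an exact fraction of the responsive units: the
    # configured proportion is a population parameter, not a coin flip
    responsive_idx = [
        i for i, c in enumerate(categories)
        if c not in ("nonresponsive", "decreased")
    ]
    n_flag = int(round(cfg.aftereffect_prob * len(responsive_idx)))
    flagged_idx = set(
        rng.choice(responsive_idx, size=n_flag, replace=False).tolist()
    ) if n_flag else set()

    units: list[Unit] = []
    gt_cat, gt_rate, gt_gain, gt_after = {}, {}, {}, {}
    for i, cat in enumerate(categories):
        uid = f"u{i:03d}"
        median = (
            cfg.panresponsive_rate_median
            if cat == "panresponsive"
            else cfg.baseline_rate_median
        )
        baseline = float(
            np.exp(np.log(median) + cfg.baseline_rate_sigma * rng.standard_normal())
        )
        gain = float(cfg.event_gain if cfg.event_gain is not None else rng.uniform(lo, hi))
        aftereffect = i in flagged_idx
        dec_cls = str(rng.choice(STIMULUS_CLASSES))
        segs = _unit_segments(cat, gain, cfg, events, trial_onsets, aftereffect, rng,
                              decreased_class=dec_cls)
        train = _sample_unit_train(baseline, segs, duration, cfg.aftereffect_tau_s, rng)
        channel = int(rng.integers(0, 384))
        units.append(
            Unit(
                unit_id=uid,
                spike_times=train,
                channel=channel,
                depth_um=float(channel * 20.0),
                waveform=None,
            )
        )
        gt_cat[uid] = cat
        gt_rate[uid] = baseline
        gt_gain[uid] = gain if cat != "nonresponsive" else 1.0
        gt_after[uid] = aftereffect

    # pairwise spike coupling
    by_id = {u.unit_id: u for u in units}
    for con in cfg.connections:
        proj = by_id[con.projection]
        targ = by_id[con.target]
        induced = inject_connection(
            proj.spike_times, con.delay_ms, con.transfer_prob, con.jitter_ms, rng
        )
        targ.spike_times = _merge_trains(targ.spike_times, induced)

    # camera sync: ephys clock runs at (1+drift) x camera clock plus offset
    n_frames = int(round(duration * cfg.frame_rate))
    sent_times = np.arange(n_frames) / cfg.frame_rate
    true_frame_times = cfg.clock_offset_s + sent_times * (1.0 + cfg.clock_drift)
    sent_flags = rng.uniform(size=n_frames) < cfg.sync_send_prob
    sync = SyncTrain(
        sent_flags=sent_flags,
        sent_times=sent_times,
        received_times=true_frame_times[sent_flags],
        frame_rate=cfg.frame_rate,
    )

    tracking = labels = None
    if cfg.with_tracking:
        track_dur = cfg.tracking_duration_s or min(duration, 600.0)
        tracking, labels = simulate_tracking(cfg, duration_s=track_dur, rng=rng)

    session = Session(
        units=units,
        events=events,
        sync=sync,
        tracking=tracking,
        metadata={"duration_s": duration, "frame_rate": cfg.frame_rate,
                  "seed": cfg.seed},
    )
    gt = GroundTruth(
        category=gt_cat,
        baseline_rate=gt_rate,
        event_gain=gt_gain,
        aftereffect=gt_after,
        aftereffect_tau_s=cfg.aftereffect_tau_s,
        connections=list(cfg.connections),
        trial_onsets=trial_onsets,
        frame_times=true_frame_times,
        behavior_labels=labels,
    )
    return session, gt


# ---------------------------------------------------------------------------
# pose tracks

IMPLANTED_PARTS = (
    "headstage_l", "headstage_r", "head", "nape_l", "nape_c", "nape_r",
    "back_l", "back_c", "back_r", "tailbase",
)
CONSPECIFIC_PARTS = (
    "ear_l", "ear_r", "nose", "nape_l", "nape_c", "nape_r",
    "back_l", "back_c", "back_r", "tailbase",
)
# colored (experimenter-marked) parts track better; they get the stricter
# likelihood threshold downstream
COLORED_PARTS = {"tailbase", "ear_l", "ear_r"}

_ARENA = (100.0, 70.0)
_BODY_LEN = 18.0  # snout-to-tailbase, arena units
_HEAD_LEN = 5.0


def _skeleton(center, heading, parts, rng, noise=0.3):
    """Lay body parts along the heading axis with small lateral offsets."""
    ux, uy = np.cos(heading), np.sin(heading)
    px, py = -uy, ux  # lateral unit vector
    along = {
        "head": 0.5, "nose": 0.55, "headstage_l": 0.45, "headstage_r": 0.45,
        "ear_l": 0.45, "ear_r": 0.45,
        "nape_l": 0.25, "nape_c": 0.25, "nape_r": 0.25,
        "back_l": -0.1, "back_c": -0.1, "back_r": -0.1,
        "tailbase": -0.5,
    }
    lateral = {
        "headstage_l": -2.0, "headstage_r": 2.0, "ear_l": -2.0, "ear_r": 2.0,
        "nape_l": -2.5, "nape_r": 2.5, "back_l": -3.0, "back_r": 3.0,
    }
    rows = []
    for p in parts:
        a = along[p] * _BODY_LEN
        l = lateral.get(p, 0.0)
        x = center[0] + a * ux + l * px + rng.normal(0, noise)
        y = center[1] + a * uy + l * py + rng.normal(0, noise)
        rows.append((p, x, y))
    return rows


def _clip_arena(xy):
    return np.clip(xy, [5.0, 5.0], [_ARENA[0] - 5.0, _ARENA[1] - 5.0])


def _bout_kinematics(label, n, state, rng):
    """Advance (pos, heading) of both agents through one bout, per frame."""
    imp_pos, imp_hd, con_pos, con_hd = state
    imp, con = [], []
    for k in range(n):
        if label == "non-social":
            # independent random walks kept in opposite halves of the arena
            imp_pos = _clip_arena(imp_pos + rng.normal(0, 0.35, 2)
                                  + 0.05 * (np.array([25.0, 35.0]) - imp_pos))
            con_pos = _clip_arena(con_pos + rng.normal(0, 0.35, 2)
                                  + 0.05 * (np.array([80.0, 35.0]) - con_pos))
            imp_hd += rng.normal(0, 0.2)
            con_hd += rng.normal(0, 0.2)
        elif label == "approach":
            if k == 0 and np.linalg.norm(con_pos - imp_pos) < 35.0:
                # an approach starts from separation: back away first
                ang = rng.uniform(0, 2 * np.pi)
                imp_pos = _clip_arena(
                    con_pos + rng.uniform(40.0, 55.0)
                    * np.array([np.cos(ang), np.sin(ang)])
                )
            vec = con_pos - imp_pos
            d = np.linalg.norm(vec)
            imp_hd = np.arctan2(vec[1], vec[0])
            # close in but stop short of contact range
            step = min(1.2, max(d - 1.8 * _BODY_LEN, 0.0))
            imp_pos = _clip_arena(imp_pos + step * vec / max(d, 1e-9))
            # conspecific stationary
        elif label == "head-head":
            mid = (imp_pos + con_pos) / 2
            imp_hd = np.arctan2(*(mid - imp_pos)[::-1])
            con_hd = np.arctan2(*(mid - con_pos)[::-1])
            gap = _BODY_LEN + 1.0  # snouts ~1 unit apart
            imp_pos = mid - gap / 2 * np.array([np.cos(imp_hd), np.sin(imp_hd)])
            con_pos = mid - gap / 2 * np.array([np.cos(con_hd), np.sin(con_hd)])
            imp_pos = imp_pos + rng.normal(0, 0.1, 2)
            con_pos = con_pos + rng.normal(0, 0.1, 2)
        elif label == "head-tail":
            # implanted snout at conspecific tailbase
            tail = con_pos - _BODY_LEN / 2 * np.array(
                [np.cos(con_hd), np.sin(con_hd)]
            )
            vec = tail - imp_pos
            imp_hd = np.arctan2(vec[1], vec[0])
            imp_pos = tail - (_BODY_LEN / 2 + 2.0) * np.array(
                [np.cos(imp_hd), np.sin(imp_hd)]
            ) + rng.normal(0, 0.1, 2)
            con_pos = con_pos + rng.normal(0, 0.1, 2)
        elif label == "following":
            step = 1.0
            con_pos = _clip_arena(
                con_pos + step * np.array([np.cos(con_hd), np.sin(con_hd)])
            )
            imp_hd = con_hd
            imp_pos = con_pos - (_BODY_LEN + 8.0) * np.array(
                [np.cos(con_hd), np.sin(con_hd)]
            )
            con_hd += rng.normal(0, 0.05)
            if not (10 < con_pos[0] < 90 and 10 < con_pos[1] < 60):
                con_hd += np.pi / 2
        elif label == "conspecific-contact":
            # implanted faces away; conspecific head at implanted's flank
            back = imp_pos - _BODY_LEN * 0.2 * np.array(
                [np.cos(imp_hd), np.sin(imp_hd)]
            )
            vec = back - con_pos
            con_hd = np.arctan2(vec[1], vec[0])
            con_pos = back - (_BODY_LEN / 2 + 1.0) * np.array(
                [np.cos(con_hd), np.sin(con_hd)]
            ) + rng.normal(0, 0.1, 2)
            imp_pos = imp_pos + rng.normal(0, 0.05, 2)
        else:  # other-social: tight contact, tumbling orientations
            mid = (imp_pos + con_pos) / 2
            imp_hd += rng.normal(0, 0.7)
            con_hd += rng.normal(0, 0.7)
            imp_pos = mid + rng.normal(0, 1.5, 2)
            con_pos = mid + rng.normal(0, 1.5, 2)
        imp.append((imp_pos.copy(), imp_hd))
        con.append((con_pos.copy(), con_hd))
    return imp, con, (imp_pos, imp_hd, con_pos, con_hd)


def simulate_tracking(
    config: SimConfig,
    duration_s: float = 600.0,
    rng: np.random.Generator | None = None,
    balanced: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-agent pose tracks with scripted, labelled behavior bouts.

    Returns the tracking table (frame, agent, bodypart, x, y, likelihood)
    and the true per-frame behavior label.  ``balanced`` schedules equal
    frame counts per label instead of the configured non-social fraction.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 7) if rng is None else rng
    fps = cfg.frame_rate
    n_frames = int(round(duration_s * fps))
    social = [l for l in BEHAVIOR_LABELS if l != "non-social"]

    # bout schedule
    labels = np.empty(n_frames, dtype=object)
    frame = 0
    while frame < n_frames:
        if balanced:
            lab = BEHAVIOR_LABELS[
                int(rng.integers(0, len(BEHAVIOR_LABELS)))
            ]
        else:
            if rng.uniform() < cfg.nonsocial_fraction:
                lab = "non-social"
            else:
                lab = social[int(rng.integers(0, len(social)))]
        dur = rng.uniform(*cfg.bout_duration_s)
        n = max(int(round(dur * fps)), 5)
        labels[frame : frame + n] = lab
        frame += n
    labels = labels[:n_frames]

    state = (
        np.array([30.0, 35.0]), 0.0,
        np.array([70.0, 35.0]), np.pi,
    )
    rows = []
    # settling frames between bouts are labelled with the new bout's label
    # but realized by the kinematics below, which converge within a frame
    i = 0
    while i < n_frames:
        j = i
        while j < n_frames and labels[j] == labels[i]:
            j += 1
        imp, con, state = _bout_kinematics(labels[i], j - i, state, rng)
        for k in range(j - i):
            f = i + k
            for (pos, hd), agent, parts in (
                (imp[k], "implanted", IMPLANTED_PARTS),
                (con[k], "conspecific", CONSPECIFIC_PARTS),
            ):
                for p, x, y in _skeleton(pos, hd, parts, rng):
                    drop = rng.uniform() < cfg.dropout_prob
                    like = rng.uniform(0.2, 0.85) if drop else rng.uniform(0.9995, 1.0)
                    rows.append((f, agent, p, x, y, like))
        i = j
    table = pd.DataFrame(
        rows, columns=["frame", "agent", "bodypart", "x", "y", "likelihood"]
    )
    return table, labels


# ---------------------------------------------------------------------------
# waveform cohorts (cell typing + cross-day tracking)


def _spike_template(rng, n_samples=82, sample_rate=30000.0, t2p_ms=None):
    """Extracellular-like template: optional pre-trough bump, sharp negative
    trough, slower positive afterpeak at the given trough-to-peak delay."""
    t = np.arange(n_samples)
    trough_at = n_samples // 3
    trough_w = rng.uniform(1.5, 5.0)
    if t2p_ms is None:
        t2p_ms = rng.uniform(0.2, 1.0)
    peak_at = trough_at + t2p_ms / 1000.0 * sample_rate
    peak_w = rng.uniform(4.0, 14.0)
    peak_amp = rng.uniform(0.15, 0.6)
    bump_amp = rng.uniform(0.0, 0.3)
    bump_at = trough_at - rng.uniform(4.0, 10.0)
    bump_w = rng.uniform(2.0, 5.0)
    tail_amp = rng.uniform(-0.15, 0.1)  # slow after-hyperpolarization lobe
    tail_at = peak_at + rng.uniform(10.0, 25.0)
    w = -np.exp(-((t - trough_at) ** 2) / (2 * trough_w**2))
    w = w + peak_amp * np.exp(-((t - peak_at) ** 2) / (2 * peak_w**2))
    w = w + bump_amp * np.exp(-((t - bump_at) ** 2) / (2 * bump_w**2))
    w = w + tail_amp * np.exp(-((t - tail_at) ** 2) / (2 * 12.0**2))
    return w, t2p_ms


def simulate_waveform_cohort(
    n_units: int = 100,
    n_channels: int = 20,
    n_samples: int = 82,
    sample_rate: float = 30000.0,
    interneuron_fraction: float = 0.3,
    snr: float = 10.0,
    drift_max_channels: int = 2,
    seed: int = 0,
):
    """Waveform heatmaps for two recording days of the same population.

    Each unit gets an extracellular template (interneurons: short
    trough-to-peak, high baseline rate; pyramidal: long, low) spread over
    channels by a Gaussian spatial profile.  Day 2 repeats the template
    with additive noise at the given SNR and a uniform channel drift of at
    most drift_max_channels.  Returns (day1_units, day2_units,
    true_types, baseline_rates).
    """
    from .io_core import Unit as _Unit

    rng = np.random.default_rng(seed)
    day1, day2, types, rates = [], [], {}, {}
    for i in range(n_units):
        uid = f"w{i:03d}"
        is_in = rng.uniform() < interneuron_fraction
        t2p = rng.uniform(0.2, 0.4) if is_in else rng.uniform(0.6, 1.0)
        rate = rng.uniform(8.0, 16.0) if is_in else rng.uniform(0.2, 2.0)
        temp, _ = _spike_template(rng, n_samples, sample_rate, t2p)
        center = n_channels // 2 + rng.uniform(-0.8, 0.8)
        sig_up = rng.uniform(0.7, 3.0)  # asymmetric spatial decay
        sig_dn = rng.uniform(0.7, 3.0)
        ch = np.arange(n_channels)
        sigma_ch = np.where(ch < center, sig_dn, sig_up)
        profile = np.exp(-((ch - center) ** 2) / (2 * sigma_ch**2))
        # dipole far field: distant channels see a small inverted deflection
        inv = rng.uniform(0.0, 0.35)
        profile = profile - inv * np.exp(
            -((ch - center) ** 2) / (2 * (2.5 * sigma_ch) ** 2)
        )
        # spike propagation along the probe: per-channel temporal tilt
        slope = rng.uniform(-0.4, 0.4)  # samples per channel
        t_ax = np.arange(n_samples)
        heat = np.stack([
            p * np.interp(t_ax - slope * (c - center), t_ax, temp)
            for c, p in zip(ch, profile)
        ])
        channel = int(rng.integers(10, 374))
        # SNR defined the standard way: RMS(signal) / RMS(noise)
        noise_sd = float(np.sqrt(np.mean(heat**2))) / snr
        day1.append(
            _Unit(uid, np.array([float(i)]), channel, channel * 20.0,
                  waveform=heat + rng.normal(0, noise_sd, heat.shape))
        )
        drift = int(rng.integers(-drift_max_channels, drift_max_channels + 1))
        heat2 = np.roll(heat, drift, axis=0)
        day2.append(
            _Unit(uid + "_d2", np.array([float(i)]), channel + drift,
                  (channel + drift) * 20.0,
                  waveform=heat2 + rng.normal(0, noise_sd, heat2.shape))
        )
        types[uid] = "putative_interneuron" if is_in else "putative_pyramidal"
        rates[uid] = rate
    return day1, day2, types, rates
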
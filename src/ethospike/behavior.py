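"""Pose-track features, social-behavior classification, and behavior-locked
unit responses.

Pose tables arrive in the pose-estimation export dialect (one row per
frame/agent/bodypart with a likelihood).  Cleaning thresholds the
experimenter-colored parts at 0.999 and the rest at 0.9, drops anatomically
impossible points, and fills gaps by linear interpolation.  Thirty
kinematic and inter-individual features feed an RBF support-vector
classifier over 7 behavior labels; predicted label runs are post-processed
into bouts by merging same-label gaps shorter than 0.25 s and deleting
bouts shorter than 5 frames.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io_core import EventBlock, Unit
from .scoring import binned_rates, response_score

__all__ = [
    "BehaviorBout",
    "clean_tracking",
    "compute_features",
    "train_behavior_classifier",
    "classify_behavior",
    "crossval_behavior_classifier",
    "postprocess_bouts",
    "nonsocial_contact_threshold",
    "toy_interaction_mask",
    "food_interaction_mask",
    "interaction_response_score",
    "behavior_peth",
    "speed_correlation",
]

log = logging.getLogger(__name__)

COLORED_PARTS = {"tailbase", "ear_l", "ear_r"}


@dataclass
class BehaviorBout:
    label: str
    start_frame: int
    end_frame: int  # exclusive

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


# ---------------------------------------------------------------------------
# cleaning


def clean_tracking(
    raw: pd.DataFrame,
    colored_thresh: float = 0.999,
    other_thresh: float = 0.9,
    max_part_jump: float = 30.0,
) -> pd.DataFrame:
    """Likelihood-threshold, outlier-remove, and interpolate a pose table.

    Points below the likelihood threshold for their part class, or that
    jump implausibly far between consecutive frames, are removed and
    refilled by per-part linear interpolation over frames.  Adds an
    ``interpolated`` flag column.
    """
    out = []
    for (agent, part), g in raw.groupby(["agent", "bodypart"], sort=False):
        g = g.sort_values("frame").copy()
        thresh = colored_thresh if part in COLORED_PARTS else other_thresh
        g.loc[g["likelihood"] < thresh, ["x", "y"]] = np.nan
        # anatomically impossible jumps between consecutive frames
        jump = np.sqrt(g["x"].diff() ** 2 + g["y"].diff() ** 2)
        g.loc[jump > max_part_jump, ["x", "y"]] = np.nan
        missing = g["x"].isna()
        if missing.mean() > 0.5:
            warnings.warn(
                f"{agent}/{part}: {missing.mean():.0%} of frames dropped; "
                "part flagged low-quality"
            )
        g[["x", "y"]] = g[["x", "y"]].interpolate(
            method="linear", limit_direction="both"
        )
        g["interpolated"] = missing.to_numpy()
        out.append(g)
    res = pd.concat(out, ignore_index=True)
    return res[["frame", "agent", "bodypart", "x", "y", "likelihood", "interpolated"]]


# ---------------------------------------------------------------------------
# features


def _pivot(track: pd.DataFrame, agent: str) -> pd.DataFrame:
    g = track[track["agent"] == agent]
    return g.pivot_table(index="frame", columns="bodypart", values=["x", "y"])


def _xy(piv: pd.DataFrame, part: str) -> np.ndarray:
    return np.column_stack([piv[("x", part)].to_numpy(), piv[("y", part)].to_numpy()])


def _head_xy(piv, agent):
    part = "head" if ("x", "head") in piv.columns else "nose"
    return _xy(piv, part)


def _speed(xy: np.ndarray, fps: float) -> np.ndarray:
    v = np.linalg.norm(np.diff(xy, axis=0, prepend=xy[:1]), axis=1) * fps
    v[0] = v[1] if v.size > 1 else 0.0
    return v


def _heading(piv) -> np.ndarray:
    """Head direction: nape-center (or back) to head/nose axis, radians."""
    head = _head_xy(piv, None)
    base = _xy(piv, "nape_c") if ("x", "nape_c") in piv.columns else _xy(piv, "back_c")
    d = head - base
    return np.arctan2(d[:, 1], d[:, 0])


def _wrap(a: np.ndarray) -> np.ndarray:
    return np.mod(a + np.pi, 2 * np.pi) - np.pi


def _angvel(heading: np.ndarray, fps: float) -> np.ndarray:
    w = _wrap(np.diff(heading, prepend=heading[:1])) * fps
    w[0] = w[1] if w.size > 1 else 0.0
    return w


def _rolling_corr(a: np.ndarray, b: np.ndarray, win: int) -> np.ndarray:
    sa = pd.Series(a)
    sb = pd.Series(b)
    c = sa.rolling(win, center=True, min_periods=2).corr(sb)
    return c.fillna(0.0).to_numpy()


def compute_features(tracking: pd.DataFrame, frame_rate: float = 30.0) -> pd.DataFrame:
    """The 30 per-frame features used for behavior classification.

    Per agent (implanted, conspecific): head velocity, tailbase velocity,
    spine length, head angular velocity, tailbase velocity offset by 1 s.
    Between agents: same-part distances (head, tailbase, nape, back),
    head-direction angles from each rat's head to the other's head and
    tailbase, head-angle difference, head-head minus head-tail distance,
    head-direction difference, cross head-tailbase distances, and 1-s
    position correlations of heads and tailbases.  Velocities are
    displacement x frame rate; angles are radians wrapped to (-pi, pi].
    """
    agents = sorted(tracking["agent"].unique())
    if len(agents) < 2:
        log.warning("single-agent session: inter-individual features absent")
    imp = _pivot(tracking, "implanted")
    other_agent = "conspecific" if "conspecific" in agents else (
        [a for a in agents if a != "implanted"][0]
    )
    con = _pivot(tracking, other_agent).reindex(imp.index)
    fps = frame_rate
    win = max(int(round(fps)), 2)

    feats = {}
    for name, piv in (("imp", imp), ("con", con)):
        head = _head_xy(piv, name)
        tail = _xy(piv, "tailbase")
        feats[f"{name}_head_vel"] = _speed(head, fps)
        feats[f"{name}_tail_vel"] = _speed(tail, fps)
        feats[f"{name}_spine_len"] = np.linalg.norm(head - tail, axis=1)
        feats[f"{name}_head_angvel"] = _angvel(_heading(piv), fps)
        feats[f"{name}_tail_vel_lag1s"] = np.roll(feats[f"{name}_tail_vel"], win)

    ih, it = _head_xy(imp, "imp"), _xy(imp, "tailbase")
    ch, ct = _head_xy(con, "con"), _xy(con, "tailbase")
    inape = _xy(imp, "nape_c")
    cnape = _xy(con, "nape_c")
    iback = _xy(imp, "back_c")
    cback = _xy(con, "back_c")
    hh = np.linalg.norm(ih - ch, axis=1)
    ht = np.linalg.norm(ih - ct, axis=1)
    th = np.linalg.norm(it - ch, axis=1)
    feats["dist_head_head"] = hh
    feats["dist_tail_tail"] = np.linalg.norm(it - ct, axis=1)
    feats["dist_nape_nape"] = np.linalg.norm(inape - cnape, axis=1)
    feats["dist_back_back"] = np.linalg.norm(iback - cback, axis=1)
    feats["dist_imphead_contail"] = ht
    feats["dist_conhead_imptail"] = th

    ihd, chd = _heading(imp), _heading(con)

    def _angle_to(origin, heading, target):
        v = target - origin
        return _wrap(np.arctan2(v[:, 1], v[:, 0]) - heading)

    feats["imp_headdir_to_con_head"] = _angle_to(ih, ihd, ch)
    feats["imp_headdir_to_con_tail"] = _angle_to(ih, ihd, ct)
    feats["imp_headdir_to_con_nape"] = _angle_to(ih, ihd, cnape)
    feats["imp_headdir_to_con_back"] = _angle_to(ih, ihd, cback)
    feats["con_headdir_to_imp_head"] = _angle_to(ch, chd, ih)
    feats["con_headdir_to_imp_tail"] = _angle_to(ch, chd, it)
    feats["con_headdir_to_imp_nape"] = _angle_to(ch, chd, inape)
    feats["con_headdir_to_imp_back"] = _angle_to(ch, chd, iback)
    feats["head_angle_diff"] = _wrap(ihd - chd)
    feats["dist_hh_minus_ht"] = hh - ht
    feats["headdir_diff_hh_minus_ht"] = _wrap(
        feats["imp_headdir_to_con_head"] - feats["imp_headdir_to_con_tail"]
    )
    feats["corr_head_x"] = _rolling_corr(ih[:, 0], ch[:, 0], win)
    feats["corr_head_y"] = _rolling_corr(ih[:, 1], ch[:, 1], win)
    feats["corr_tail_x"] = _rolling_corr(it[:, 0], ct[:, 0], win)
    feats["corr_tail_y"] = _rolling_corr(it[:, 1], ct[:, 1], win)

    df = pd.DataFrame(feats, index=imp.index)
    # outlier removal + interpolation: clip beyond 8 robust SDs, refill
    for c in df.columns:
        x = df[c]
        med = x.median()
        mad = (x - med).abs().median() * 1.4826 or 1.0
        out = (x - med).abs() > 8 * mad
        if out.any():
            df[c] = x.mask(out).interpolate(limit_direction="both")
    if df.isna().any().any():
        df = df.fillna(0.0)
    return df


# ---------------------------------------------------------------------------
# classification


def train_behavior_classifier(features: pd.DataFrame, labels: np.ndarray):
    """RBF-kernel support-vector classifier on standardized features."""
    present = set(np.unique(labels))
    from .synthetic import BEHAVIOR_LABELS

    missing = [l for l in BEHAVIOR_LABELS if l not in present]
    if missing:
        raise ValueError(f"training labels missing classes: {missing}")
    model = make_pipeline(StandardScaler(), SVC(kernel="rbf"))
    model.fit(features.to_numpy(), labels)
    return model


def classify_behavior(features: pd.DataFrame, model) -> np.ndarray:
    return model.predict(features.to_numpy())


def crossval_behavior_classifier(
    features: pd.DataFrame,
    labels: np.ndarray,
    protocol: str = "5fold",
    groups: np.ndarray | None = None,
    seed: int = 0,
) -> float:
    """Frame-level accuracy under 5-fold or leave-one-recording-out CV."""
    X = features.to_numpy()
    y = np.asarray(labels)
    model = make_pipeline(StandardScaler(), SVC(kernel="rbf"))
    correct = 0
    if protocol == "5fold":
        splitter = StratifiedKFold(5, shuffle=True, random_state=seed).split(X, y)
    elif protocol == "leave-one-recording-out":
        if groups is None:
            raise ValueError("leave-one-recording-out needs group ids")
        splitter = GroupKFold(len(np.unique(groups))).split(X, y, groups)
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    for tr, te in splitter:
        model.fit(X[tr], y[tr])
        correct += int(np.sum(model.predict(X[te]) == y[te]))
    return correct / len(y)


def postprocess_bouts(
    labels: np.ndarray,
    frame_rate: float = 30.0,
    min_gap_s: float = 0.25,
    min_frames: int = 5,
) -> list[BehaviorBout]:
    """Label runs -> bouts: merge same-label gaps < 0.25 s, then delete
    bouts shorter than 5 frames."""
    y = np.asarray(labels, dtype=object)
    runs: list[BehaviorBout] = []
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and y[j] == y[i]:
            j += 1
        runs.append(BehaviorBout(str(y[i]), i, j))
        i = j
    max_gap = min_gap_s * frame_rate
    # merge pass: a run re-joins the most recent same-label run when the
    # stretch between them (whatever its labels) is shorter than the gap
    # limit; the stretch is absorbed into the merged bout
    merged: list[BehaviorBout] = []
    for b in runs:
        k = len(merged) - 1
        while k >= 0 and b.start_frame - merged[k].end_frame < max_gap:
            if merged[k].label == b.label:
                b = BehaviorBout(b.label, merged[k].start_frame, b.end_frame)
                del merged[k:]
                break
            k -= 1
        merged.append(b)
    # then delete bouts that are still too short
    return [b for b in merged if b.n_frames >= min_frames]


# ---------------------------------------------------------------------------
# non-social interaction masks


def nonsocial_contact_threshold(
    distances: np.ndarray, contact_labels: np.ndarray, n_grid: int = 512
) -> dict:
    """Inter-individual distance threshold separating contact from
    non-contact, fit on social frames by maximizing balanced accuracy."""
    d = np.asarray(distances, float)
    y = np.asarray(contact_labels, bool)
    if y.all() or not y.any():
        raise ValueError("need both contact and non-contact frames to fit")
    grid = np.linspace(d.min(), d.max(), n_grid)
    best_t, best_ba = grid[0], -1.0
    for t in grid:
        pred = d < t
        sens = np.mean(pred[y])
        spec = np.mean(~pred[~y])
        ba = (sens + spec) / 2
        if ba > best_ba:
            best_ba, best_t = ba, t
    return dict(threshold=float(best_t), balanced_accuracy=float(best_ba))


def toy_interaction_mask(head_to_toy_distance: np.ndarray, threshold: float):
    return np.asarray(head_to_toy_distance, float) < threshold


def food_interaction_mask(head_xy: np.ndarray, roi_polygon: np.ndarray):
    """True where the head lies inside the eating region of interest."""
    return MplPath(np.asarray(roi_polygon, float)).contains_points(
        np.asarray(head_xy, float)
    )


# ---------------------------------------------------------------------------
# unit responses to behavior


def interaction_response_score(
    unit: Unit,
    events: list[EventBlock],
    interaction_mask,
    theta: float = 0.2,
    bin_s: float = 1.0,
    min_spikes: int = 0,
) -> dict:
    """auROC score comparing firing during interaction vs non-interaction
    after first contact, averaged over the given (responded-to) events.

    interaction_mask(t0, t1) -> bool must report whether the 1-s bin
    [t0, t1) is an interaction bin; alternatively pass a callable over bin
    start times.
    """
    scores = []
    for ev in events:
        t0, t1 = ev.t_contact, ev.t_event_end
        n_bins = int(np.floor((t1 - t0) / bin_s))
        if n_bins < 2:
            continue
        starts = t0 + np.arange(n_bins) * bin_s
        inter = np.array([bool(interaction_mask(s, s + bin_s)) for s in starts])
        if inter.all() or not inter.any():
            log.warning("event %s has single-label interaction mask; skipped",
                        ev.label)
            continue
        rates = binned_rates(unit.spike_times, (t0, t0 + n_bins * bin_s), bin_s)
        scores.append(
            response_score(rates[~inter], rates[inter], min_spikes=min_spikes,
                           bin_s=bin_s)
        )
    if not scores:
        return dict(score=float("nan"), cls="undefined")
    s = float(np.mean(scores))
    cls = "increase" if s > theta else "decrease" if s < -theta else "none"
    return dict(score=s, cls=cls, n_events=len(scores))


def behavior_peth(
    unit: Unit,
    bout_starts: np.ndarray,
    window_s: float = 5.0,
    bin_s: float = 0.1,
    z_window: tuple[float, float] = (-5.0, -2.0),
    z_thresh: float = 5.0,
    min_bouts: int = 5,
) -> dict:
    """Average peri-bout histogram, z-scored to the pre-onset window.

    The unit is responsive to the behavior when any post-onset bin's |z|
    exceeds 5.
    """
    starts = np.asarray(bout_starts, float)
    if starts.size < min_bouts:
        log.info("only %d bouts (<%d); peth skipped", starts.size, min_bouts)
        return dict(z=None, responsive=None, skipped=True)
    edges = np.arange(-window_s, window_s + bin_s / 2, bin_s)
    centers = (edges[:-1] + edges[1:]) / 2
    counts = np.zeros(centers.size)
    for s in starts:
        c, _ = np.histogram(unit.spike_times - s, bins=edges)
        counts += c
    mean_rate = counts / starts.size / bin_s
    base = mean_rate[(centers >= z_window[0]) & (centers < z_window[1])]
    mu, sd = base.mean(), base.std()
    sd = max(sd, 1e-9)
    z = (mean_rate - mu) / sd
    post = centers >= 0
    return dict(
        bin_centers=centers,
        z=z,
        responsive=bool(np.any(np.abs(z[post]) > z_thresh)),
        skipped=False,
    )


# ---------------------------------------------------------------------------
# speed correlation


def speed_correlation(
    unit: Unit,
    speed_t: np.ndarray,
    speed_v: np.ndarray,
    epochs: list[tuple[float, float]],
    bin_s: float = 0.05,
    zero_band_sd: float = 2.0,
    far_lag_s: tuple[float, float] = (-20.0, -10.0),
) -> dict:
    """Classify a unit's firing as positively/negatively speed-correlated.

    Firing is binned at 50 ms and cross-correlated with the speed trace
    within each epoch (baseline/event/post); profiles are averaged, then
    CC at lag 0 is compared with the mean CC over lags -20..-10 s.  The
    class is "none" when the difference sits within ``zero_band_sd`` SDs
    of the far-lag CC values.
    """
    if np.std(speed_v) == 0:
        return dict(cls="undefined", flagged="constant speed")
    max_lag_s = -far_lag_s[0]
    n_lag = int(round(max_lag_s / bin_s))
    lags = np.arange(-n_lag, n_lag + 1)
    lags_s = lags * bin_s
    far = (lags_s >= far_lag_s[0]) & (lags_s <= far_lag_s[1])

    def _profile(r, s):
        return np.array([
            np.mean(r[max(0, -l): len(r) - max(0, l)]
                    * s[max(0, l): len(s) - max(0, -l)])
            for l in lags
        ])

    pairs = []
    for (a, b) in epochs:
        rates = binned_rates(unit.spike_times, (a, b), bin_s)
        t_bins = a + (np.arange(rates.size) + 0.5) * bin_s
        sp = np.interp(t_bins, speed_t, speed_v)
        if np.std(sp) == 0 or np.std(rates) == 0:
            continue
        pairs.append((
            (rates - rates.mean()) / rates.std(),
            (sp - sp.mean()) / sp.std(),
        ))
    if not pairs:
        return dict(cls="undefined", flagged="no usable epoch")

    def _diff(shift_bins: int) -> tuple[float, float, float]:
        cc = np.mean(
            [_profile(np.roll(r, shift_bins), s) for r, s in pairs], axis=0
        )
        cc0 = float(cc[lags_s == 0][0])
        far_mean = float(cc[far].mean())
        return cc0 - far_mean, cc0, far_mean

    diff, cc0, far_mean = _diff(0)
    # null band from circular shifts of the rate vector: alignment is
    # destroyed while both autocorrelation structures are preserved
    n_bins = min(len(r) for r, _ in pairs)
    shifts = np.linspace(0.2, 0.8, 24) * n_bins
    null_diffs = np.array([_diff(int(m))[0] for m in shifts])
    band = zero_band_sd * float(null_diffs.std())
    cls = "positive" if diff > band else "negative" if diff < -band else "none"
    return dict(cls=cls, cc0=cc0, far_mean=far_mean, band=band, diff=diff,
                lags_s=lags_s)
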
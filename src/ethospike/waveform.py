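"""Waveform-based cell typing and cross-day unit matching.

Putative interneurons have narrow spikes (short trough-to-peak delay) and
high baseline rates; putative pyramidal cells the opposite.  The two
groups are separated by 2-means clustering on those two axes.  Units are
tracked across recording days by comparing peak-centered multi-channel
waveform heatmaps with the structural similarity index (SSIM) plus the
mean per-channel Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .io_core import Unit

__all__ = [
    "WaveformMetrics",
    "UnitMatch",
    "waveform_metrics",
    "cell_type_clusters",
    "match_units_across_days",
]


@dataclass
class WaveformMetrics:
    unit_id: str
    trough_to_peak_ms: float
    inverted: bool
    baseline_rate_hz: float
    cell_type: str = "unclassified"


@dataclass
class UnitMatch:
    day1_id: str
    day2_id: str
    ssim: float
    channel_correlation: float
    accepted: bool


def waveform_metrics(
    unit: Unit, sample_rate: float = 30000.0, baseline_rate_hz: float = np.nan
) -> WaveformMetrics:
    """Trough-to-peak delay on the peak-amplitude channel.

    Trough = global minimum of the mean waveform; peak = the maximum that
    follows it.  A waveform whose dominant deflection is positive and
    precedes the trough is *inverted* and excluded from cell typing.
    """
    if unit.waveform is None:
        raise ValueError(f"unit {unit.unit_id} has no waveform")
    wf = np.atleast_2d(unit.waveform)
    if np.ptp(wf) == 0:
        raise ValueError(f"unit {unit.unit_id}: flat waveform")
    best = int(np.argmax(np.ptp(wf, axis=1)))
    w = wf[best]
    i_trough = int(np.argmin(w))
    i_extreme = int(np.argmax(np.abs(w)))
    inverted = w[i_extreme] > 0 and i_extreme < i_trough
    if inverted or i_trough == w.size - 1:
        return WaveformMetrics(unit.unit_id, np.nan, True, baseline_rate_hz,
                               "irregular")
    i_peak = i_trough + int(np.argmax(w[i_trough:]))
    t2p = (i_peak - i_trough) / sample_rate * 1000.0
    return WaveformMetrics(unit.unit_id, float(t2p), False, baseline_rate_hz)


def cell_type_clusters(
    metrics: list[WaveformMetrics], seed: int = 0
) -> list[WaveformMetrics]:
    """2-means on (trough-to-peak, baseline rate), standardized.

    The cluster with the larger mean trough-to-peak delay is labeled
    putative_pyramidal, the other putative_interneuron; inverted units
    stay irregular.  Labels are written into the metrics in place.
    """
    usable = [m for m in metrics if not m.inverted]
    if len(usable) < 2:
        raise ValueError("need at least 2 non-irregular units to cluster")
    X = np.array([[m.trough_to_peak_ms, m.baseline_rate_hz] for m in usable])
    if np.allclose(X, X[0]):
        raise ValueError("degenerate waveform metrics: all points identical")
    Xs = StandardScaler().fit_transform(X)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(Xs)
    mean_t2p = [X[km.labels_ == k, 0].mean() for k in (0, 1)]
    pyramidal_cluster = int(np.argmax(mean_t2p))
    for m, lab in zip(usable, km.labels_):
        m.cell_type = (
            "putative_pyramidal" if lab == pyramidal_cluster else "putative_interneuron"
        )
    return metrics


# ---------------------------------------------------------------------------
# cross-day matching


def _prepared(wf: np.ndarray) -> np.ndarray:
    """Peak-normalize and center the peak-amplitude channel row."""
    wf = np.atleast_2d(wf)
    peak = np.max(np.abs(wf))
    wf = wf / peak if peak > 0 else wf
    best = int(np.argmax(np.ptp(wf, axis=1)))
    return np.roll(wf, wf.shape[0] // 2 - best, axis=0)


def _pair_similarity(
    w1: np.ndarray, w2: np.ndarray, max_shift: int = 1
) -> tuple[float, float]:
    """Best (SSIM, signal-channel correlation) over small channel shifts.

    Peak-channel centering can be off by one channel under noise, so the
    comparison allows +/- max_shift row shifts and keeps the best SSIM.
    """
    best = (-1.0, 0.0)
    amp = np.ptp(w1, axis=1)
    sel = amp >= 0.2 * amp.max()  # signal-bearing channels only
    for shift in range(-max_shift, max_shift + 1):
        w2s = np.roll(w2, shift, axis=0)
        s = structural_similarity(w1, w2s, data_range=2.0)
        if s > best[0]:
            corrs = [
                np.corrcoef(a, b)[0, 1]
                for a, b in zip(w1[sel], w2s[sel])
                if np.std(a) > 0 and np.std(b) > 0
            ]
            best = (float(s), float(np.mean(corrs)) if corrs else 0.0)
    return best


def match_units_across_days(
    day1_units: list[Unit],
    day2_units: list[Unit],
    channel_window: int = 5,
    ssim_thresh: float = 0.8,
    corr_thresh: float = 0.9,
) -> list[UnitMatch]:
    """Greedy one-to-one matching of day-1 units onto day-2 units.

    Candidates are restricted to day-2 units within +/- channel_window
    probe channels.  Waveform heatmaps (channels x samples) are
    peak-normalized, centered on their peak channel, and compared by SSIM
    with ties broken by the mean Pearson correlation over signal-bearing
    channels; pairs are accepted when both exceed their thresholds.
    Matching is greedy by descending SSIM, each unit used at most once.
    """
    prepped2 = {u.unit_id: _prepared(u.waveform) for u in day2_units}
    cand: list[tuple[float, float, str, str]] = []
    for u1 in day1_units:
        w1 = _prepared(u1.waveform)
        for u2 in day2_units:
            if abs(u2.channel - u1.channel) > channel_window:
                continue
            w2 = prepped2[u2.unit_id]
            if w1.shape != w2.shape:
                raise ValueError("waveform heatmaps must share a common shape")
            s, c = _pair_similarity(w1, w2)
            cand.append((s, c, u1.unit_id, u2.unit_id))
    cand.sort(key=lambda t: (-t[0], -t[1]))
    used1, used2, matches = set(), set(), []
    for s, c, id1, id2 in cand:
        if id1 in used1 or id2 in used2:
            continue
        accepted = s >= ssim_thresh and c >= corr_thresh
        if not accepted:
            continue
        used1.add(id1)
        used2.add(id2)
        matches.append(UnitMatch(id1, id2, s, c, True))
    return matches
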
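"""auROC response scores, unit categorization, and population structure.

Each unit's response to each stimulus presentation is scored by comparing
its 1-s binned firing-rate distribution during the 5-min event period
against the immediately preceding 5-min baseline via the area under the
ROC curve, rescaled to a *response score* = (auROC - 0.5) * 2 in [-1, 1].
Units are then categorized from their per-class average scores with a
responsiveness threshold of +0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import STIMULUS_CLASSES, EventBlock, Session, Unit

__all__ = [
    "binned_rates",
    "response_score",
    "classify_unit",
    "score_session",
    "ResponseProfile",
    "population_vectors",
    "population_correlation",
    "pairwise_depth_stat",
    "SOCIAL_CLASSES",
    "NONSOCIAL_CLASSES",
]

SOCIAL_CLASSES = ("male", "female")
NONSOCIAL_CLASSES = ("toy", "food")

RESPONSIVE_CATEGORIES = (
    "male_specific",
    "female_specific",
    "toy_specific",
    "food_specific",
    "panresponsive",
    "multimodal_social",
    "multimodal_nonsocial",
)


def binned_rates(
    spike_times: np.ndarray,
    interval: tuple[float, float],
    bin_s: float = 1.0,
) -> np.ndarray:
    """Firing rate (spikes/s) in consecutive bins over [start, end).

    Only full bins are returned; a trailing partial bin is dropped.
    """
    start, end = interval
    if end - start < bin_s:
        raise ValueError(f"interval [{start}, {end}) shorter than one {bin_s}-s bin")
    n_bins = int(np.floor((end - start) / bin_s))
    edges = start + np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(spike_times, bins=edges)
    return counts / bin_s


def response_score(
    baseline_rates: np.ndarray,
    event_rates: np.ndarray,
    min_spikes: int = 50,
    bin_s: float = 1.0,
) -> float:
    """(auROC - 0.5) * 2 for event vs baseline rate distributions.

    auROC is computed by the rank-sum identity with midrank tie handling:
    auROC = (R_event - n_e(n_e+1)/2) / (n_e * n_b), equivalently the
    probability that a random event bin exceeds a random baseline bin with
    half credit for ties.  Units too quiet to score - fewer than
    ``min_spikes`` spikes pooled over both periods - get a score of 0.
    """
    b = np.asarray(baseline_rates, float)
    e = np.asarray(event_rates, float)
    if b.size == 0 or e.size == 0:
        raise ValueError("baseline and event rate sequences must be non-empty")
    total_spikes = (b.sum() + e.sum()) * bin_s
    if total_spikes < min_spikes:
        return 0.0
    ranks = stats.rankdata(np.concatenate([e, b]))
    r_event = ranks[: e.size].sum()
    u = r_event - e.size * (e.size + 1) / 2.0
    auroc = u / (e.size * b.size)
    return float((auroc - 0.5) * 2.0)


def classify_unit(class_scores: dict, theta: float = 0.2) -> str:
    """Category label from the four per-class average response scores.

    Exactly one class above +theta -> that event-specific category; classes
    above theta on both the social (male/female) and non-social (toy/food)
    side -> panresponsive; two or more on one side only -> multimodal_social
    or multimodal_nonsocial; none above +theta but at least one below
    -theta -> decreased; otherwise nonresponsive.
    """
    for c in STIMULUS_CLASSES:
        if not np.isfinite(class_scores[c]):
            raise ValueError(f"non-finite score for class {c}")
    up = [c for c in STIMULUS_CLASSES if class_scores[c] > theta]
    if len(up) == 1:
        return f"{up[0]}_specific"
    if len(up) >= 2:
        social = any(c in SOCIAL_CLASSES for c in up)
        nonsocial = any(c in NONSOCIAL_CLASSES for c in up)
        if social and nonsocial:
            return "panresponsive"
        return "multimodal_social" if social else "multimodal_nonsocial"
    if any(class_scores[c] < -theta for c in STIMULUS_CLASSES):
        return "decreased"
    return "nonresponsive"


@dataclass
class ResponseProfile:
    unit_id: str
    event_scores: dict  # event label -> score
    class_scores: dict  # stimulus class -> average score
    category: str

    @property
    def responsive(self) -> bool:
        return self.category in RESPONSIVE_CATEGORIES


def score_session(
    session: Session,
    theta: float = 0.2,
    min_spikes: int = 50,
    bin_s: float = 1.0,
) -> list[ResponseProfile]:
    """Score and categorize every unit in a session."""
    profiles = []
    for unit in session.units:
        event_scores = {}
        for ev in session.events:
            b = binned_rates(unit.spike_times, ev.baseline, bin_s)
            e = binned_rates(unit.spike_times, ev.event, bin_s)
            event_scores[ev.label] = response_score(b, e, min_spikes, bin_s)
        class_scores = {}
        for cls in STIMULUS_CLASSES:
            labels = [ev.label for ev in session.events_of(cls)]
            class_scores[cls] = float(
                np.mean([event_scores[l] for l in labels])
            ) if labels else 0.0
        profiles.append(
            ResponseProfile(
                unit_id=unit.unit_id,
                event_scores=event_scores,
                class_scores=class_scores,
                category=classify_unit(class_scores, theta),
            )
        )
    return profiles


def profiles_frame(profiles: list[ResponseProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = dict(unit_id=p.unit_id, category=p.category)
        row.update({f"score_{c}": p.class_scores[c] for c in STIMULUS_CLASSES})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population structure


def population_vectors(
    profiles: list[ResponseProfile], events: list[EventBlock]
) -> pd.DataFrame:
    """Per-event response-score vectors over all responsive units.

    Rows = events (label-indexed), columns = responsive unit ids, in a
    fixed unit order shared by every event.
    """
    resp = [p for p in profiles if p.responsive]
    if not resp:
        raise ValueError("no responsive units: population vectors undefined")
    data = {
        ev.label: [p.event_scores[ev.label] for p in resp] for ev in events
    }
    return pd.DataFrame(data, index=[p.unit_id for p in resp]).T


def population_correlation(vectors: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between per-event population vectors.

    Zero-variance vectors yield NaN entries (flagged, not silently 0).
    """
    if vectors.shape[0] < 2:
        raise ValueError("need at least 2 population vectors")
    arr = vectors.to_numpy(float)
    sd = arr.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=vectors.index, columns=vectors.index)


def pairwise_depth_stat(
    category_depths_um: np.ndarray, all_depths_um: np.ndarray
) -> dict:
    """Anatomical clustering of a response category along the probe.

    Mean absolute pairwise depth distance within the category, compared
    against the pairwise distances of the full population by a rank-based
    (Mann-Whitney) test.  A category clustered along the dorsoventral axis
    has a smaller mean pairwise distance than the average neuron.
    """
    cat = np.asarray(category_depths_um, float)
    alld = np.asarray(all_depths_um, float)
    if cat.size < 2:
        return dict(mean_pairwise_um=np.nan, null_mean_um=np.nan, p_value=np.nan,
                    n_pairs=0, flagged="singleton category")
    def _pd(d):
        i, j = np.triu_indices(d.size, k=1)
        return np.abs(d[i] - d[j])
    cat_pairs = _pd(cat)
    null_pairs = _pd(alld)
    res = stats.mannwhitneyu(cat_pairs, null_pairs, alternative="two-sided")
    return dict(
        mean_pairwise_um=float(cat_pairs.mean()),
        null_mean_um=float(null_pairs.mean()),
        p_value=float(res.pvalue),
        n_pairs=int(cat_pairs.size),
    )
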
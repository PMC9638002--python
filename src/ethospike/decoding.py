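"""Population decoding with linear discriminant analysis.

Stimulus identity is decoded from per-event population response-score
vectors by leave-one-out LDA, with a label-shuffle control (500 shuffles).
Additional protocols: neuron-dropping curves, category omission,
peri-contact sliding windows over raw rate features, and within-event
interaction / movement decoding scored by ROC area.

LDA uses least-squares solving with automatic (Ledoit-Wolf) covariance
shrinkage - unavoidable when units outnumber events - and features are
standardized before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .io_core import Session
from .scoring import ResponseProfile, binned_rates, population_vectors

__all__ = [
    "DecodeReport",
    "loo_stimulus_decoder",
    "neuron_dropping_curve",
    "category_omission",
    "window_decoder",
    "interaction_decoder",
    "movement_decoder",
    "depth_restricted_decoder",
]


@dataclass
class DecodeReport:
    protocol: str
    predicted: np.ndarray
    true: np.ndarray
    accuracy: float
    shuffle_accuracies: np.ndarray = field(default_factory=lambda: np.array([]))
    metadata: dict = field(default_factory=dict)

    @property
    def shuffle_mean(self) -> float:
        return float(self.shuffle_accuracies.mean()) if self.shuffle_accuracies.size else float("nan")


def _lda(y=None):
    # uniform priors: the event design is balanced, and leave-one-out
    # otherwise biases predictions away from the held-out class
    priors = None
    if y is not None:
        k = len(np.unique(y))
        priors = np.full(k, 1.0 / k)
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto",
                                      priors=priors)


def _loo_accuracy(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    n = len(y)
    preds = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        if len(set(y[mask])) < 2:
            preds[i] = "__undecodable__"
            continue
        scaler = StandardScaler().fit(X[mask])
        clf = _lda(y[mask]).fit(scaler.transform(X[mask]), y[mask])
        preds[i] = clf.predict(scaler.transform(X[i : i + 1]))[0]
    return float(np.mean(preds == y)), preds


def loo_stimulus_decoder(
    scores: np.ndarray,
    labels: np.ndarray,
    n_shuffles: int = 500,
    seed: int = 0,
) -> DecodeReport:
    """Leave-one-event-out LDA on population response scores.

    scores: events x units response-score matrix.  Every event is held out
    once; accuracy is compared against n_shuffles label permutations run
    through the same protocol.
    """
    X = np.asarray(scores, float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        import warnings

        warnings.warn(
            f"classes with a single event: {classes[counts < 2].tolist()}; "
            "their fold trains without that class"
        )
    acc, preds = _loo_accuracy(X, y)
    rng = np.random.default_rng(seed)
    shuffles = np.array(
        [_loo_accuracy(X, rng.permutation(y))[0] for _ in range(n_shuffles)]
    )
    return DecodeReport(
        protocol="loo_stimulus",
        predicted=preds,
        true=y,
        accuracy=acc,
        shuffle_accuracies=shuffles,
        metadata=dict(n_units=X.shape[1], n_events=X.shape[0]),
    )


def session_score_matrix(
    session: Session, profiles: list[ResponseProfile]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(events x responsive-units score matrix, class labels, unit ids)."""
    vectors = population_vectors(profiles, session.events)
    labels = np.array([ev.stimulus_class for ev in session.events])
    return vectors.to_numpy(float), labels, list(vectors.columns)


def neuron_dropping_curve(
    scores: np.ndarray,
    labels: np.ndarray,
    n_grid: list[int] | None = None,
    n_repeat: int = 500,
    seed: int = 0,
) -> dict:
    """Mean leave-one-out accuracy vs number of randomly selected units."""
    X = np.asarray(scores, float)
    y = np.asarray(labels)
    n_units = X.shape[1]
    if n_grid is None:
        n_grid = sorted({2, 4, 6, 10, min(15, n_units), n_units})
        n_grid = [n for n in n_grid if 2 <= n <= n_units]
    rng = np.random.default_rng(seed)
    mean_acc, sd_acc = [], []
    for n in n_grid:
        accs = []
        reps = 1 if n == n_units else n_repeat
        for _ in range(reps):
            cols = rng.choice(n_units, size=n, replace=False)
            accs.append(_loo_accuracy(X[:, cols], y)[0])
        mean_acc.append(float(np.mean(accs)))
        sd_acc.append(float(np.std(accs)))
    return dict(n_units=list(n_grid), mean_accuracy=mean_acc, sd_accuracy=sd_acc)


def category_omission(
    scores: np.ndarray,
    labels: np.ndarray,
    unit_categories: list[str],
    omit: str,
    n_repeat: int = 100,
    seed: int = 0,
) -> dict:
    """Accuracy change from omitting one unit category, neuron-count matched.

    The omitted-category decoder uses all remaining units; the control
    decoder uses equally many units drawn at random from the full set
    (n_repeat draws).  Returns delta = omitted - matched-control accuracy.
    """
    cats = np.asarray(unit_categories)
    if omit not in cats:
        raise ValueError(f"no units of category {omit!r} to omit")
    keep = cats != omit
    X = np.asarray(scores, float)
    y = np.asarray(labels)
    n_kept = int(keep.sum())
    acc_omit = _loo_accuracy(X[:, keep], y)[0]
    rng = np.random.default_rng(seed)
    controls = []
    for _ in range(n_repeat):
        cols = rng.choice(X.shape[1], size=n_kept, replace=False)
        controls.append(_loo_accuracy(X[:, cols], y)[0])
    return dict(
        omitted=omit,
        accuracy_omitted=acc_omit,
        accuracy_matched_control=float(np.mean(controls)),
        delta=float(acc_omit - np.mean(controls)),
        n_units_used=n_kept,
    )


def window_decoder(
    session: Session,
    profiles: list[ResponseProfile],
    window_s: float = 10.0,
    range_s: tuple[float, float] = (-30.0, 30.0),
    step_s: float = 5.0,
) -> dict:
    """Leave-one-out decoding from a 10-s rate window slid around contact.

    Features are per-unit spike counts in [t_contact + offset,
    t_contact + offset + window); offsets run from 30 s before to 30 s
    after contact.
    """
    resp = [p for p in profiles if p.responsive]
    units = [session.unit(p.unit_id) for p in resp]
    y = np.array([ev.stimulus_class for ev in session.events])
    offsets = np.arange(range_s[0], range_s[1] - window_s + 1e-9, step_s)
    accs = []
    for off in offsets:
        X = np.array(
            [
                [
                    np.count_nonzero(
                        (u.spike_times >= ev.t_contact + off)
                        & (u.spike_times < ev.t_contact + off + window_s)
                    )
                    for u in units
                ]
                for ev in session.events
            ],
            dtype=float,
        )
        accs.append(_loo_accuracy(X, y)[0])
    return dict(window_start_s=offsets.tolist(), accuracy=accs)


def _masked_fold_auc(X, y, k_folds, seed):
    if len(set(y)) < 2:
        return None
    k = min(k_folds, int(np.bincount(y).min()))
    if k < 2:
        return None
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    decision = np.zeros(len(y))
    for tr, te in skf.split(X, y):
        scaler = StandardScaler().fit(X[tr])
        clf = _lda(y[tr]).fit(scaler.transform(X[tr]), y[tr])
        decision[te] = clf.decision_function(scaler.transform(X[te]))
    return float(roc_auc_score(y, decision))


def interaction_decoder(
    z_population: np.ndarray,
    interaction_mask: np.ndarray,
    event_index: np.ndarray,
    k_folds: int = 5,
    n_shuffles: int = 100,
    seed: int = 0,
) -> dict:
    """Per-event ROC area for decoding interaction vs non-interaction.

    z_population: time-bins x units z-scored rates; interaction_mask:
    boolean per bin; event_index: which event each bin belongs to.  A
    5-fold cross-validated LDA is fit within each event; events with a
    single label are skipped.  A label-shuffle control is run per event.
    """
    X = np.asarray(z_population, float)
    mask = np.asarray(interaction_mask, bool).astype(int)
    ev = np.asarray(event_index)
    rng = np.random.default_rng(seed)
    aucs, shuffle_aucs, skipped = {}, {}, []
    for e in np.unique(ev):
        sel = ev == e
        auc = _masked_fold_auc(X[sel], mask[sel], k_folds, seed)
        if auc is None:
            skipped.append(e)
            continue
        aucs[e] = auc
        sh = []
        for _ in range(n_shuffles):
            a = _masked_fold_auc(X[sel], rng.permutation(mask[sel]), k_folds, seed)
            if a is not None:
                sh.append(a)
        shuffle_aucs[e] = float(np.mean(sh)) if sh else float("nan")
    return dict(per_event_auc=aucs, per_event_shuffle_auc=shuffle_aucs,
                skipped_events=skipped)


def movement_decoder(
    z_population: np.ndarray,
    moving_mask: np.ndarray,
    event_index: np.ndarray,
    k_folds: int = 5,
    n_shuffles: int = 100,
    seed: int = 0,
) -> dict:
    """Rest-vs-movement analog of :func:`interaction_decoder`."""
    return interaction_decoder(
        z_population, moving_mask, event_index, k_folds, n_shuffles, seed
    )


def depth_restricted_decoder(
    session: Session,
    profiles: list[ResponseProfile],
    center_um: float,
    half_window_um: float = 250.0,
    min_units: int = 10,
    n_shuffles: int = 0,
    seed: int = 0,
) -> DecodeReport | None:
    """Stimulus decoding restricted to units within a 500-um depth band.

    Returns None when fewer than min_units responsive units fall inside
    the band.  With every unit inside the band this reduces exactly to
    loo_stimulus_decoder.
    """
    depths = {u.unit_id: u.depth_um for u in session.units}
    kept = [
        p
        for p in profiles
        if p.responsive and abs(depths[p.unit_id] - center_um) <= half_window_um
    ]
    if len(kept) < min_units:
        return None
    vectors = population_vectors(kept, session.events)
    labels = np.array([ev.stimulus_class for ev in session.events])
    return loo_stimulus_decoder(
        vectors.to_numpy(float), labels, n_shuffles=n_shuffles, seed=seed
    )
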
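"""Session data model, disk layout, video-ephys synchronization, and unit QC.

A *session* is one continuous recording day: sorted single units (spike
times on the ephys clock, in seconds), a schedule of stimulus-presentation
event blocks, the camera sync-pulse record, and optionally a pose-tracking
table.  All analysis downstream runs on the ephys clock; video frames are
mapped onto it once, by :func:`align_sync`.  All time windows are half-open
``[start, end)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

STIMULUS_CLASSES = ("male", "female", "toy", "food")

__all__ = [
    "STIMULUS_CLASSES",
    "Unit",
    "EventBlock",
    "SyncTrain",
    "Session",
    "SessionValidationError",
    "SyncError",
    "read_session",
    "write_session",
    "align_sync",
    "refractory_violation_fraction",
    "passes_refractory_qc",
]


class SessionValidationError(ValueError):
    """A session invariant does not hold; the message names the offender."""


class SyncError(ValueError):
    """Sent and received sync-pulse records disagree."""


@dataclass
class Unit:
    """One isolated neuron: spike train, mean waveform, probe coordinates."""

    unit_id: str
    spike_times: np.ndarray  # seconds, ephys clock, strictly increasing
    channel: int
    depth_um: float
    waveform: np.ndarray | None = None  # channels x samples, mean voltage
    region: str = "unknown"

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        if self.spike_times.ndim != 1:
            raise SessionValidationError(f"unit {self.unit_id}: spike_times must be 1-D")
        if np.any(np.diff(self.spike_times) <= 0):
            raise SessionValidationError(
                f"unit {self.unit_id}: spike_times not strictly increasing"
            )
        if self.depth_um < 0:
            raise SessionValidationError(f"unit {self.unit_id}: depth_um < 0")
        if self.waveform is not None:
            self.waveform = np.atleast_2d(np.asarray(self.waveform, dtype=np.float64))

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass
class EventBlock:
    """One stimulus presentation with its five time anchors (seconds).

    baseline runs [t_baseline_start, t_presentation); the event period is
    [t_presentation, t_event_end) with first physical contact at t_contact;
    the post period is [t_event_end, t_post_end).
    """

    stimulus_class: str
    presentation_index: int
    t_baseline_start: float
    t_presentation: float
    t_contact: float
    t_event_end: float
    t_post_end: float

    def __post_init__(self) -> None:
        if self.stimulus_class not in STIMULUS_CLASSES:
            raise SessionValidationError(
                f"unknown stimulus_class {self.stimulus_class!r}"
            )
        if self.presentation_index < 1:
            raise SessionValidationError("presentation_index must be >= 1")
        ok = (
            self.t_baseline_start < self.t_presentation <= self.t_contact
            < self.t_event_end < self.t_post_end
        )
        if not ok:
            raise SessionValidationError(
                f"event {self.stimulus_class}#{self.presentation_index}: "
                "anchors must satisfy baseline_start < presentation <= contact "
                "< event_end < post_end"
            )

    @property
    def label(self) -> str:
        return f"{self.stimulus_class}{self.presentation_index}"

    @property
    def baseline(self) -> tuple[float, float]:
        return (self.t_baseline_start, self.t_presentation)

    @property
    def event(self) -> tuple[float, float]:
        return (self.t_presentation, self.t_event_end)

    @property
    def post(self) -> tuple[float, float]:
        return (self.t_event_end, self.t_post_end)


@dataclass
class SyncTrain:
    """Per-frame pulse bookkeeping linking the camera and ephys clocks.

    Each video frame either emitted a 5-V pulse (sent_flags True) or not;
    received_times are the ephys-clock arrival times of the emitted pulses,
    in order.
    """

    sent_flags: np.ndarray  # bool per frame
    sent_times: np.ndarray  # seconds, camera clock, per frame
    received_times: np.ndarray  # seconds, ephys clock, one per sent pulse
    frame_rate: float

    def __post_init__(self) -> None:
        self.sent_flags = np.asarray(self.sent_flags, dtype=bool)
        self.sent_times = np.asarray(self.sent_times, dtype=np.float64)
        self.received_times = np.asarray(self.received_times, dtype=np.float64)


@dataclass
class Session:
    units: list[Unit]
    events: list[EventBlock]
    sync: SyncTrain | None = None
    tracking: pd.DataFrame | None = None  # frame, agent, bodypart, x, y, likelihood
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Raise SessionValidationError on the first violated invariant."""
        blocks = sorted(self.events, key=lambda e: e.t_baseline_start)
        for a, b in zip(blocks, blocks[1:]):
            if b.t_baseline_start < a.t_post_end:
                raise SessionValidationError(
                    f"events {a.label} and {b.label} overlap"
                )
        span_end = self.duration
        for e in self.events:
            if e.t_post_end > span_end + 1e-9:
                raise SessionValidationError(
                    f"event {e.label} extends past the recording span"
                )

    @property
    def duration(self) -> float:
        ends = [e.t_post_end for e in self.events]
        spikes = [u.spike_times[-1] for u in self.units if u.n_spikes]
        if "duration_s" in self.metadata:
            return float(self.metadata["duration_s"])
        return max(ends + spikes) if (ends or spikes) else 0.0

    def unit(self, unit_id: str) -> Unit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def events_of(self, stimulus_class: str) -> list[EventBlock]:
        return [e for e in self.events if e.stimulus_class == stimulus_class]


# ---------------------------------------------------------------------------
# disk layout


def write_session(session: Session, path: str | Path) -> None:
    """Write a session as a plain directory of tabular/array text files."""
    root = Path(path)
    (root / "spikes").mkdir(parents=True, exist_ok=True)
    rows = [
        dict(unit_id=u.unit_id, channel=u.channel, depth_um=u.depth_um, region=u.region)
        for u in session.units
    ]
    pd.DataFrame(rows, columns=["unit_id", "channel", "depth_um", "region"]).to_csv(
        root / "units.tsv", sep="\t", index=False
    )
    for u in session.units:
        np.save(root / "spikes" / f"{u.unit_id}.npy", u.spike_times)
        if u.waveform is not None:
            (root / "waveforms").mkdir(exist_ok=True)
            np.save(root / "waveforms" / f"{u.unit_id}.npy", u.waveform)
    ev = pd.DataFrame(
        [
            dict(
                stimulus_class=e.stimulus_class,
                presentation_index=e.presentation_index,
                t_baseline_start=e.t_baseline_start,
                t_presentation=e.t_presentation,
                t_contact=e.t_contact,
                t_event_end=e.t_event_end,
                t_post_end=e.t_post_end,
            )
            for e in session.events
        ]
    )
    ev.to_csv(root / "events.tsv", sep="\t", index=False, float_format="%.17g")
    if session.sync is not None:
        s = session.sync
        pd.DataFrame(
            dict(
                frame=np.arange(s.sent_flags.size),
                sent_flag=s.sent_flags.astype(int),
                sent_time=s.sent_times,
            )
        ).to_csv(root / "sync.tsv", sep="\t", index=False, float_format="%.17g")
        np.savetxt(root / "sync_received.txt", s.received_times, fmt="%.17g")
        meta = dict(session.metadata)
        meta["frame_rate"] = s.frame_rate
    else:
        meta = dict(session.metadata)
    if session.tracking is not None:
        session.tracking.to_csv(root / "tracking.tsv", sep="\t", index=False,
                                float_format="%.17g")
    with open(root / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=float)


def _load_spikes(root: Path, unit_id: str) -> np.ndarray:
    npy = root / "spikes" / f"{unit_id}.npy"
    txt = root / "spikes" / f"{unit_id}.txt"
    if npy.exists():
        return np.load(npy)
    if txt.exists():  # one float64 second per line
        return np.loadtxt(txt, ndmin=1)
    raise FileNotFoundError(f"no spike file for unit {unit_id} under {root/'spikes'}")


def read_session(path: str | Path, validate: bool = True) -> Session:
    """Load a session directory written by :func:`write_session`."""
    root = Path(path)
    units_file = root / "units.tsv"
    if not units_file.exists():
        raise FileNotFoundError(f"missing required table {units_file}")
    units_df = pd.read_csv(units_file, sep="\t")
    units = []
    for row in units_df.itertuples():
        wf_file = root / "waveforms" / f"{row.unit_id}.npy"
        units.append(
            Unit(
                unit_id=str(row.unit_id),
                spike_times=_load_spikes(root, str(row.unit_id)),
                channel=int(row.channel),
                depth_um=float(row.depth_um),
                waveform=np.load(wf_file) if wf_file.exists() else None,
                region=str(row.region),
            )
        )
    events_file = root / "events.tsv"
    if not events_file.exists():
        raise FileNotFoundError(f"missing required table {events_file}")
    events = [
        EventBlock(
            stimulus_class=row.stimulus_class,
            presentation_index=int(row.presentation_index),
            t_baseline_start=float(row.t_baseline_start),
            t_presentation=float(row.t_presentation),
            t_contact=float(row.t_contact),
            t_event_end=float(row.t_event_end),
            t_post_end=float(row.t_post_end),
        )
        for row in pd.read_csv(events_file, sep="\t", float_precision="round_trip").itertuples()
    ]
    meta_file = root / "metadata.json"
    metadata = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    sync = None
    if (root / "sync.tsv").exists():
        sy = pd.read_csv(root / "sync.tsv", sep="\t", float_precision="round_trip")
        received = np.loadtxt(root / "sync_received.txt", ndmin=1)
        sync = SyncTrain(
            sent_flags=sy["sent_flag"].to_numpy(bool),
            sent_times=sy["sent_time"].to_numpy(float),
            received_times=received,
            frame_rate=float(metadata.get("frame_rate", 30.0)),
        )
    tracking = None
    if (root / "tracking.tsv").exists():
        tracking = pd.read_csv(root / "tracking.tsv", sep="\t",
                               float_precision="round_trip")
    session = Session(units=units, events=events, sync=sync, tracking=tracking,
                      metadata=metadata)
    if validate:
        session.validate()
    return session


# ---------------------------------------------------------------------------
# synchronization


def align_sync(sync: SyncTrain) -> np.ndarray:
    """Map every video frame onto the ephys clock.

    Frames that emitted a pulse take their received (ephys) pulse time
    directly; the ~20% of frames that did not are filled in by linear
    interpolation between neighbouring pulse times, extrapolating at the
    ends at the nominal frame period.

    Returns frame_times (seconds, ephys clock), strictly increasing.
    """
    flags = sync.sent_flags
    received = sync.received_times
    n_sent = int(flags.sum())
    if received.size != n_sent:
        raise SyncError(
            f"{n_sent} pulses sent but {received.size} received; "
            "sent and received trains must match in exact number and sequence"
        )
    if np.any(np.diff(received) <= 0):
        raise SyncError("received pulse times are not strictly increasing")
    frames = np.arange(flags.size, dtype=np.float64)
    sent_idx = np.flatnonzero(flags)
    if sent_idx.size == 0:
        raise SyncError("no sent pulses: cannot align")
    # linear interpolation in frame index; ends extrapolated at the local
    # frame period implied by the pulse train itself
    frame_times = np.interp(frames, sent_idx, received)
    if sent_idx.size >= 2:
        period0 = (received[1] - received[0]) / (sent_idx[1] - sent_idx[0])
        period1 = (received[-1] - received[-2]) / (sent_idx[-1] - sent_idx[-2])
    else:
        period0 = period1 = 1.0 / sync.frame_rate
    before = frames < sent_idx[0]
    after = frames > sent_idx[-1]
    frame_times[before] = received[0] - (sent_idx[0] - frames[before]) * period0
    frame_times[after] = received[-1] + (frames[after] - sent_idx[-1]) * period1
    if np.any(np.diff(frame_times) <= 0):
        raise SyncError("aligned frame times are not strictly increasing")
    return frame_times


# ---------------------------------------------------------------------------
# unit QC


def refractory_violation_fraction(
    spike_times: np.ndarray, refractory_ms: float = 2.0
) -> float:
    """Fraction of inter-spike intervals shorter than the refractory period.

    A well-isolated single unit should essentially never fire twice within
    2 ms; sorted clusters violating this in more than 0.1% of spikes are
    flagged by :func:`passes_refractory_qc`.
    """
    spikes = np.asarray(spike_times, dtype=float)
    if spikes.size < 2:
        warnings.warn("fewer than 2 spikes: refractory fraction undefined, using 0")
        return 0.0
    isi = np.diff(spikes)
    return float(np.count_nonzero(isi < refractory_ms / 1000.0) / spikes.size)


def passes_refractory_qc(
    spike_times: np.ndarray, refractory_ms: float = 2.0, max_fraction: float = 0.001
) -> bool:
    return refractory_violation_fraction(spike_times, refractory_ms) < max_fraction
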
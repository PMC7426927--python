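"""Shared data containers and interchange-format IO.

The universal input to every analysis stage is a :class:`SessionRecording`:
a channels x samples voltage matrix (microvolts) with a sampling rate,
channel labels and 3-D positions, and a :class:`LevelSchedule` describing
the stepped anesthetic protocol (constant-dose "levels", loss/return of
consciousness markers, burst-suppression flags) plus an optional per-sample
artifact mask.

Recordings round-trip losslessly through a plain HDF5 container
(:func:`save_session` / :func:`load_session`); level annotations can also be
exchanged as a CSV table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Level",
    "LevelSchedule",
    "SessionRecording",
    "save_session",
    "load_session",
    "write_annotations_csv",
    "read_annotations_csv",
]


@dataclass(frozen=True)
class Level:
    """One constant-target-dose period of the stepped protocol."""

    label: str
    start_s: float
    end_s: float
    dose: float
    burst_suppression: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"level {self.label!r}: end ({self.end_s}) must exceed start ({self.start_s})"
            )


@dataclass
class LevelSchedule:
    """Ordered, contiguous, non-overlapping levels with LOC/ROC markers."""

    levels: list[Level]
    loc_time_s: float | None = None
    roc_time_s: float | None = None

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("schedule must contain at least one level")
        labels = [lv.label for lv in self.levels]
        if len(set(labels)) != len(labels):
            raise ValueError("level labels must be unique")
        for prev, cur in zip(self.levels, self.levels[1:]):
            if cur.start_s < prev.end_s - 1e-9:
                raise ValueError(
                    f"levels {prev.label!r} and {cur.label!r} overlap"
                )
        if (
            self.loc_time_s is not None
            and self.roc_time_s is not None
            and not self.loc_time_s < self.roc_time_s
        ):
            raise ValueError("LOC must precede ROC")

    def level(self, label: str) -> Level:
        for lv in self.levels:
            if lv.label == label:
                return lv
        raise KeyError(f"unknown level label: {label!r}")

    def level_containing(self, time_s: float) -> Level | None:
        for lv in self.levels:
            if lv.start_s <= time_s < lv.end_s:
                return lv
        return None

    @property
    def labels(self) -> list[str]:
        return [lv.label for lv in self.levels]

    @property
    def end_s(self) -> float:
        return self.levels[-1].end_s


@dataclass
class SessionRecording:
    """Multichannel EEG-like recording with protocol annotations.

    ``data`` is (n_channels, n_samples) in microvolts. ``artifact_mask``
    is boolean with the same shape; True marks corrupted samples.
    """

    data: np.ndarray
    sample_rate_hz: float
    channel_labels: list[str]
    channel_positions: np.ndarray
    schedule: LevelSchedule
    artifact_mask: np.ndarray | None = None
    subject_id: str = "s0"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        self.channel_positions = np.asarray(self.channel_positions, dtype=float)
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data rows must match channel_labels")
        if self.channel_positions.shape != (self.data.shape[0], 3):
            raise ValueError("channel_positions must be (n_channels, 3)")
        if not np.all(np.isfinite(self.channel_positions)):
            raise ValueError("channel positions must be finite")
        if self.schedule.end_s > self.duration_s + 1e-6:
            raise ValueError("schedule extends beyond the recording")
        if self.artifact_mask is not None:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != self.data.shape:
                raise ValueError("artifact_mask shape must match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    def sample_slice(self, start_s: float, end_s: float) -> slice:
        """Sample index slice covering [start_s, end_s)."""
        i0 = int(round(start_s * self.sample_rate_hz))
        i1 = int(round(end_s * self.sample_rate_hz))
        return slice(max(i0, 0), min(i1, self.n_samples))

    def copy_with(self, **kwargs) -> "SessionRecording":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# HDF5 interchange container
# ---------------------------------------------------------------------------

def save_session(recording: SessionRecording, path) -> None:
    """Write a recording to the plain HDF5 interchange container."""
    sched = recording.schedule
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.attrs["sample_rate_hz"] = recording.sample_rate_hz
        f.attrs["subject_id"] = recording.subject_id
        f.create_dataset(
            "channel_labels",
            data=np.array(recording.channel_labels, dtype=h5py.string_dtype()),
        )
        f.create_dataset("channel_positions", data=recording.channel_positions)
        g = f.create_group("levels")
        g.create_dataset(
            "label",
            data=np.array([lv.label for lv in sched.levels], dtype=h5py.string_dtype()),
        )
        g.create_dataset("start_s", data=[lv.start_s for lv in sched.levels])
        g.create_dataset("end_s", data=[lv.end_s for lv in sched.levels])
        g.create_dataset("dose", data=[lv.dose for lv in sched.levels])
        g.create_dataset(
            "burst_suppression",
            data=np.array([lv.burst_suppression for lv in sched.levels], dtype=bool),
        )
        f.attrs["loc_time_s"] = np.nan if sched.loc_time_s is None else sched.loc_time_s
        f.attrs["roc_time_s"] = np.nan if sched.roc_time_s is None else sched.roc_time_s
        if recording.artifact_mask is not None:
            f.create_dataset("artifact_mask", data=recording.artifact_mask)


def load_session(path) -> SessionRecording:
    """Read a recording from the HDF5 interchange container."""
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_labels"][()]]
        positions = f["channel_positions"][()]
        g = f["levels"]
        lvl_labels = [s.decode() if isinstance(s, bytes) else str(s) for s in g["label"][()]]
        levels = [
            Level(
                label=lab,
                start_s=float(s0),
                end_s=float(s1),
                dose=float(d),
                burst_suppression=bool(bs),
            )
            for lab, s0, s1, d, bs in zip(
                lvl_labels, g["start_s"][()], g["end_s"][()], g["dose"][()],
                g["burst_suppression"][()],
            )
        ]
        loc = float(f.attrs["loc_time_s"])
        roc = float(f.attrs["roc_time_s"])
        schedule = LevelSchedule(
            levels,
            loc_time_s=None if np.isnan(loc) else loc,
            roc_time_s=None if np.isnan(roc) else roc,
        )
        mask = f["artifact_mask"][()] if "artifact_mask" in f else None
        return SessionRecording(
            data=data,
            sample_rate_hz=float(f.attrs["sample_rate_hz"]),
            channel_labels=labels,
            channel_positions=positions,
            schedule=schedule,
            artifact_mask=mask,
            subject_id=str(f.attrs["subject_id"]),
        )


# ---------------------------------------------------------------------------
# Annotation CSV table
# ---------------------------------------------------------------------------

def write_annotations_csv(schedule: LevelSchedule, path) -> None:
    df = pd.DataFrame(
        {
            "label": [lv.label for lv in schedule.levels],
            "start_s": [lv.start_s for lv in schedule.levels],
            "end_s": [lv.end_s for lv in schedule.levels],
            "dose": [lv.dose for lv in schedule.levels],
            "burst_suppression": [lv.burst_suppression for lv in schedule.levels],
        }
    )
    df.attrs = {}
    header = f"# loc_time_s={schedule.loc_time_s},roc_time_s={schedule.roc_time_s}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_annotations_csv(path) -> LevelSchedule:
    with open(path) as fh:
        first = fh.readline()
        df = pd.read_csv(fh)
    loc = roc = None
    if first.startswith("#"):
        for part in first.lstrip("#").strip().split(","):
            key, _, val = part.partition("=")
            if val not in ("None", ""):
                if key.strip() == "loc_time_s":
                    loc = float(val)
                elif key.strip() == "roc_time_s":
                    roc = float(val)
    levels = [
        Level(
            label=str(row.label),
            start_s=float(row.start_s),
            end_s=float(row.end_s),
            dose=float(row.dose),
            burst_suppression=bool(row.burst_suppression),
        )
        for row in df.itertuples()
    ]
    return LevelSchedule(levels, loc_time_s=loc, roc_time_s=roc)
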
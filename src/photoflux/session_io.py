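"""Reading/writing session and event tables, and TTL clock alignment.

The photometry clock is canonical: behavioral event times are mapped onto it
by the offset between a TTL pulse as seen by the two acquisition systems.

CSV dialect: comma-separated, UTF-8, '.' decimal, header row required.
Sessions carry columns ``time_s, ch490, ch405``; event tables carry
``time_s, label``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PhotometrySession",
    "EventTable",
    "DEFAULT_VOCABULARY",
    "read_session",
    "write_session",
    "read_events",
    "write_events",
    "align_events",
    "validate_events",
]

DEFAULT_VOCABULARY = frozenset(
    {"CS_ON", "CS_OFF", "US_ON", "PUMP", "LIGHT_ON", "TONE_ON", "SHOCK_ON", "TTL"}
)

_SPACING_RTOL = 1e-6


@dataclass
class PhotometrySession:
    """Paired demodulated signal/reference traces at a common sampling rate."""

    time_s: np.ndarray
    ch490: np.ndarray
    ch405: np.ndarray
    fs: float
    ttl_offset_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ch490 = np.asarray(self.ch490, dtype=float)
        self.ch405 = np.asarray(self.ch405, dtype=float)
        if not (self.time_s.size == self.ch490.size == self.ch405.size):
            raise ValueError("time_s, ch490 and ch405 must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        _check_uniform(self.time_s, 1.0 / self.fs)

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    @property
    def edge_s(self) -> float:
        """Filter-edge guard interval flagged by the demodulator (0 if none)."""
        return float(self.meta.get("edge_s", 0.0))


def _check_uniform(time_s: np.ndarray, dt: float) -> None:
    if time_s.size < 2:
        return
    diffs = np.diff(time_s)
    bad = np.nonzero(np.abs(diffs - dt) > _SPACING_RTOL * dt)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"non-uniform sample spacing at index {i + 1}: "
            f"dt={diffs[i]:g} s, expected {dt:g} s"
        )


@dataclass
class EventTable:
    """Timestamped labeled events (behavioral markers, TTLs)."""

    time_s: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.label = np.asarray(self.label, dtype=object)
        if self.time_s.shape != self.label.shape:
            raise ValueError("time_s and label must have equal length")
        if self.time_s.size and np.any(np.diff(self.time_s) < 0):
            i = int(np.nonzero(np.diff(self.time_s) < 0)[0][0])
            raise ValueError(f"event times decrease at row {i + 1}")

    def __len__(self) -> int:
        return self.time_s.size

    def select(self, label: str) -> np.ndarray:
        """Times of all events carrying ``label``."""
        return self.time_s[self.label == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "label": self.label})


def read_session(path) -> PhotometrySession:
    """Read a session CSV; the sampling rate is inferred from the median spacing."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "ch490", "ch405"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("session must contain at least 2 samples")
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise ValueError("non-increasing time column")
    _check_uniform(t, dt)
    return PhotometrySession(
        time_s=t,
        ch490=df["ch490"].to_numpy(dtype=float),
        ch405=df["ch405"].to_numpy(dtype=float),
        fs=1.0 / dt,
    )


def write_session(session: PhotometrySession, path) -> None:
    pd.DataFrame(
        {"time_s": session.time_s, "ch490": session.ch490, "ch405": session.ch405}
    ).to_csv(path, index=False)


def read_events(path) -> EventTable:
    df = pd.read_csv(path, dtype={"label": str}, float_precision="round_trip")
    for col in ("time_s", "label"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    times = np.empty(len(df), dtype=float)
    for i, v in enumerate(df["time_s"]):
        try:
            times[i] = float(v)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"unparseable time {v!r} at row {i + 1}") from exc
    return EventTable(time_s=times, label=df["label"].to_numpy(dtype=object))


def write_events(events: EventTable, path) -> None:
    events.to_frame().to_csv(path, index=False)


def validate_events(events: EventTable, vocabulary=DEFAULT_VOCABULARY) -> dict:
    """Return a validation report; unknown labels are flagged, not rejected."""
    unknown = sorted({str(l) for l in events.label} - set(vocabulary))
    return {
        "n_events": int(len(events)),
        "unknown_labels": unknown,
        "ok": not unknown,
    }


def align_events(
    events: EventTable, ttl_time_photometry_s: float, ttl_time_behavior_s: float
) -> EventTable:
    """Shift behavioral event times onto the photometry clock.

    Every event time is shifted by
    ``ttl_time_photometry_s - ttl_time_behavior_s``; ordering is preserved.
    Applying the negated offset restores the original table exactly.
    """
    if not (np.isfinite(ttl_time_photometry_s) and np.isfinite(ttl_time_behavior_s)):
        raise ValueError("TTL times must be finite")
    offset = ttl_time_photometry_s - ttl_time_behavior_s
    return EventTable(time_s=events.time_s + offset, label=events.label.copy())
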
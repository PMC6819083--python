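"""Behavioral quantification: lick bouts, learning rate, outcome timing, freezing.

A lick bout begins at the first lick of any run in which at least
``rate_threshold * window`` licks fall inside a sliding 1 s window
(operationalizing the "exceeds five licks per second" rule), extends while
inter-lick gaps stay below the bout gap (3 s), and is merged with any
activity closer than that gap.  Reward consumption onset ("US timing") is
the start of the first bout at or after reward presentation.  Learning and
freezing-acquisition rates are OLS slopes of per-trial counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "detect_lick_bouts",
    "us_time_from_licks",
    "learning_rate",
    "count_cs_licks",
    "count_anticipatory_licks",
    "freezing_acquisition",
    "FreezingSummary",
]


def detect_lick_bouts(
    licks,
    rate_threshold: float = 5.0,
    gap_s: float = 3.0,
    min_licks: int = 5,
    window_s: float = 1.0,
) -> pd.DataFrame:
    """Segment a lick timestamp train into bouts.

    Returns a frame with columns ``start_s, end_s, n_licks,
    peak_rate_licks_per_s``.  Bouts are non-overlapping and separated by at
    least ``gap_s``; runs below the rate criterion never open a bout.
    """
    t = np.asarray(licks, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("lick timestamps must be sorted")
    # licks required inside the sliding window to open a bout; the default
    # rate rule (5/s over 1 s) coincides with the default minimum bout size,
    # and an explicitly smaller min_licks relaxes the opening count with it
    run = max(1, min(min_licks, int(np.ceil(rate_threshold * window_s))))
    bouts = []
    i = 0
    n = t.size
    while i < n:
        # can a bout open at lick i? need `run` licks within window_s
        if i + run - 1 < n and t[i + run - 1] - t[i] <= window_s:
            j = i
            while j + 1 < n and t[j + 1] - t[j] < gap_s:
                j += 1
            seg = t[i : j + 1]
            if seg.size >= min_licks:
                peak = _peak_rate(seg, window_s)
                bouts.append(
                    {
                        "start_s": float(seg[0]),
                        "end_s": float(seg[-1]),
                        "n_licks": int(seg.size),
                        "peak_rate_licks_per_s": peak,
                    }
                )
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(bouts, columns=["start_s", "end_s", "n_licks", "peak_rate_licks_per_s"])


def _peak_rate(seg: np.ndarray, window_s: float) -> float:
    best = 1
    for i in range(seg.size):
        j = np.searchsorted(seg, seg[i] + window_s, side="right")
        best = max(best, j - i)
    return best / window_s


def us_time_from_licks(bouts: pd.DataFrame, reward_time_s: float) -> float | None:
    """Start of the first lick bout at or after reward presentation.

    Returns ``None`` when no bout follows the reward (a missing value, not
    an error); bouts that started before the reward do not count even if
    they are still ongoing.
    """
    if not np.isfinite(reward_time_s):
        raise ValueError("reward_time_s must be finite")
    if len(bouts) == 0:
        return None
    after = bouts.loc[bouts["start_s"] >= reward_time_s, "start_s"]
    return float(after.iloc[0]) if len(after) else None


def learning_rate(cs_licks) -> float:
    """OLS slope of per-trial CS lick counts over 1-based trial index."""
    y = np.asarray(cs_licks, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 trials")
    x = np.arange(1, y.size + 1, dtype=float)
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def count_cs_licks(licks, cs_onset_s: float, cs_offset_s: float) -> int:
    """Licks during cue presentation, [onset, offset)."""
    t = np.asarray(licks, dtype=float)
    return int(np.count_nonzero((t >= cs_onset_s) & (t < cs_offset_s)))


def count_anticipatory_licks(licks, cs_onset_s: float, us_time_s: float) -> int:
    """Licks between cue onset and outcome delivery, [cs_onset, us_time)."""
    t = np.asarray(licks, dtype=float)
    return int(np.count_nonzero((t >= cs_onset_s) & (t < us_time_s)))


@dataclass(frozen=True)
class FreezingSummary:
    acquisition_slope: float  # seconds frozen per trial over the early trials
    mean_freeze_s: float  # plateau mean over the late trials
    mean_latency_s: float


def freezing_acquisition(
    freeze_time_s,
    latency_s,
    acquisition_trials: tuple[int, int] = (1, 7),
    plateau_trials: tuple[int, int] = (8, 15),
) -> FreezingSummary:
    """Early-trial acquisition slope and late-trial plateau of cued freezing.

    Trials are 1-based; the default split fits the slope on trials 1-7 and
    averages freezing and latency over trials 8-15.
    """
    f = np.asarray(freeze_time_s, dtype=float)
    lat = np.asarray(latency_s, dtype=float)
    if f.size != lat.size:
        raise ValueError("freeze_time_s and latency_s must have equal length")
    if f.size < plateau_trials[1]:
        raise ValueError(
            f"need at least {plateau_trials[1]} trials for the "
            f"{acquisition_trials}/{plateau_trials} split, got {f.size}"
        )
    a0, a1 = acquisition_trials
    p0, p1 = plateau_trials
    x = np.arange(a0, a1 + 1, dtype=float)
    slope, _ = np.polyfit(x, f[a0 - 1 : a1], 1)
    return FreezingSummary(
        acquisition_slope=float(slope),
        mean_freeze_s=float(f[p0 - 1 : p1].mean()),
        mean_latency_s=float(lat[p0 - 1 : p1].mean()),
    )
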
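"""Event-aligned trial matrices and per-trial response features.

Trials are exact slices of the session-normalized z trace around labeled
events (no resampling, no per-trial renormalization).  Per-trial features
are taken in configurable time windows relative to the alignment event:

* ``cs_peak``      max z in [0, 2] s after cue onset
* ``us_peak``      max z in [0, 1] s after outcome onset
* ``us_antipeak``  signed min in [0.5, 2.5] s (the post-outcome dip)
* ``rebound_auc``  trapezoidal integral of z over [2, 8] s (the slower
  recovery transient that follows the dip)

The defaults reflect the typical waveform around an aversive outcome: an
initial positive transient, a 1-2 s negative anti-peak, then a broader
rebound; all windows are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import ZTrace
from .session_io import EventTable
from .stats import TestResult, paired_t

__all__ = [
    "PeriEventMatrix",
    "FeatureWindows",
    "extract_perievent",
    "extract_trial_features",
    "omission_contrast",
    "feature_trend",
    "TrendFit",
]


@dataclass
class PeriEventMatrix:
    """trials x time array of z samples aligned to one event label."""

    data: np.ndarray  # (n_trials, n_time)
    t: np.ndarray  # seconds relative to the event, length n_time
    event_times: np.ndarray
    event_label: str
    fs: float
    dropped: list = field(default_factory=list)  # (event_index, event_time_s)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=[f"{x:.6g}" for x in self.t])


def extract_perievent(
    z: ZTrace,
    events: EventTable,
    label: str,
    pre_s: float,
    post_s: float,
    baseline_window_s: tuple[float, float] | None = None,
) -> PeriEventMatrix:
    """Slice the z trace around every event carrying ``label``.

    Events whose window would be truncated by the trace boundary are
    dropped and reported in ``dropped``, never padded.  If
    ``baseline_window_s`` is given, the mean over that (event-relative)
    window is subtracted per trial.
    """
    if pre_s < 0 or post_s < 0:
        raise ValueError("pre_s and post_s must be >= 0")
    times = events.select(label)
    n_pre = int(round(pre_s * z.fs))
    n_post = int(round(post_s * z.fs))
    t_rel = np.arange(-n_pre, n_post + 1) / z.fs
    t0 = float(z.time_s[0])
    rows, kept, dropped = [], [], []
    for k, et in enumerate(times):
        center = int(round((et - t0) * z.fs))
        if center - n_pre < 0 or center + n_post >= z.z.size:
            dropped.append((k, float(et)))
            continue
        rows.append(z.z[center - n_pre : center + n_post + 1])
        kept.append(et)
    data = np.asarray(rows, dtype=float) if rows else np.empty((0, t_rel.size))
    if baseline_window_s is not None and data.size:
        a, b = baseline_window_s
        mask = (t_rel >= a) & (t_rel <= b)
        if not mask.any():
            raise ValueError("empty baseline window")
        data = data - data[:, mask].mean(axis=1, keepdims=True)
    return PeriEventMatrix(
        data=data,
        t=t_rel,
        event_times=np.asarray(kept, dtype=float),
        event_label=label,
        fs=z.fs,
        dropped=dropped,
    )


@dataclass(frozen=True)
class FeatureWindows:
    """Event-relative windows (seconds) for per-trial feature extraction."""

    cs_peak: tuple[float, float] = (0.0, 2.0)
    us_peak: tuple[float, float] = (0.0, 1.0)
    us_antipeak: tuple[float, float] = (0.5, 2.5)
    rebound_auc: tuple[float, float] = (2.0, 8.0)
    baseline: tuple[float, float] = (-2.0, 0.0)


def _window_mask(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    a, b = window
    mask = (t >= a - 1e-12) & (t <= b + 1e-12)
    if not mask.any():
        raise ValueError(f"empty feature window ({a:g}, {b:g}) s")
    return mask


def extract_trial_features(
    mat: PeriEventMatrix, windows: FeatureWindows = FeatureWindows()
) -> pd.DataFrame:
    """Per-trial peak/anti-peak/AUC features; ties break to the earliest sample."""
    out = []
    masks = {
        name: _window_mask(mat.t, getattr(windows, name))
        for name in ("cs_peak", "us_peak", "us_antipeak", "rebound_auc", "baseline")
    }
    for i in range(mat.n_trials):
        row = mat.data[i]
        out.append(
            {
                "trial": i,
                "event_time_s": mat.event_times[i],
                "cs_peak_z": float(row[masks["cs_peak"]].max()),
                "us_peak_z": float(row[masks["us_peak"]].max()),
                "us_antipeak_z": float(row[masks["us_antipeak"]].min()),
                "rebound_auc_zs": float(
                    np.trapezoid(row[masks["rebound_auc"]], mat.t[masks["rebound_auc"]])
                ),
                "baseline_mean_z": float(row[masks["baseline"]].mean()),
            }
        )
    return pd.DataFrame(out)


@dataclass
class OmissionContrast:
    subjects: list
    rewarded_mean: np.ndarray
    omission_mean: np.ndarray
    test: TestResult | None
    excluded: list


def omission_contrast(
    features_rewarded: dict, features_omission: dict, column: str = "us_peak_z"
) -> OmissionContrast:
    """Paired per-subject comparison of outcome peaks: rewarded vs omission.

    Both arguments map subject id -> TrialFeatures frame (or array of
    values).  Subjects present in only one condition are excluded and
    reported.  The paired t statistic is computed on the per-subject means.
    """

    def mean_of(v):
        if isinstance(v, pd.DataFrame):
            return float(v[column].mean())
        return float(np.mean(v))

    common = sorted(set(features_rewarded) & set(features_omission))
    excluded = sorted(set(features_rewarded) ^ set(features_omission))
    rewarded = np.array([mean_of(features_rewarded[s]) for s in common])
    omission = np.array([mean_of(features_omission[s]) for s in common])
    test = paired_t(rewarded, omission) if len(common) >= 2 else None
    return OmissionContrast(
        subjects=common,
        rewarded_mean=rewarded,
        omission_mean=omission,
        test=test,
        excluded=excluded,
    )


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r2: float


def feature_trend(values, index=None) -> TrendFit:
    """OLS line of a feature over trial (or session) index.

    The slope is the "rate of change" statistic used for feature-behavior
    correlations.  A zero-variance residual baseline (constant series)
    reports r2 = 0.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 points for a trend")
    x = np.arange(1, y.size + 1, dtype=float) if index is None else np.asarray(index, float)
    if x.size != y.size:
        raise ValueError("index and values must have equal length")
    if np.ptp(y) == 0:  # constant series: slope exactly 0, r2 defined as 0
        return TrendFit(slope=0.0, intercept=float(y[0]), r2=0.0)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(((y - fitted) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return TrendFit(slope=float(slope), intercept=float(intercept), r2=r2)
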
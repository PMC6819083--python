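"""Synthetic acquisition: raw modulated photometry, trial schedules, licks, trees.

Every input the pipeline consumes can be generated here with known ground
truth, so all downstream stages are testable without recorded data.

The raw signal model is

    raw(t) = noise(t) + bleach(t) * [ A490 * (1 + dff(t) + motion(t)) * sin(2*pi*f490*t)
                                     + A405 * (1 + motion(t)) * sin(2*pi*f405*t) ]

with carriers at 211 and 531 Hz, dff(t) a sum of difference-of-exponential
transient kernels at Poisson event times, a multiplicative exponential
photobleaching envelope shared by both channels, and a slow additive motion
artifact identical across channels (the physical assumption that justifies
isosbestic correction).  Acquisition runs at an integer multiple of the
382 Hz output rate so decimation is exact.

All randomness flows from one seed; per-component sub-streams are derived
deterministically from it, so an identical config is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import signal

from .demodulation import RawRecording
from .morphology import NeuronTree
from .session_io import EventTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "TrialSchedule",
    "generate_session",
    "generate_trial_schedule",
    "generate_lick_train",
    "generate_morphology",
    "transient_kernel_peak_delay_s",
    "write_raw_recording",
    "write_ground_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a simulated two-channel recording session.

    Defaults emulate a 10-minute baseline recording: 0.5 Hz spontaneous
    transients of 6% dF/F with 50 ms rise / 500 ms decay, a 1200 s
    photobleaching time constant, 2% shared motion artifact, and 0.5%
    detector noise — a signal-dominated regime (dF/F-domain peak SNR of
    roughly 35 after 25 Hz lock-in filtering, once the reference-channel
    noise amplified by the fit slope is included) in which the robust-z
    scale reflects dopamine dynamics rather than sensor noise.
    """

    duration_s: float = 600.0
    fs_raw: float = 6112.0  # 16 x 382 so decimation is an exact integer factor
    fs_out: float = 382.0
    carrier_490_hz: float = 211.0
    carrier_405_hz: float = 531.0
    amp_490: float = 1.0  # carrier amplitudes in detector volts
    amp_405: float = 0.5
    transient_rate_hz: float = 0.5
    transient_amp: float = 0.06  # dF/F units at the kernel peak
    transient_tau_rise_s: float = 0.05
    transient_tau_decay_s: float = 0.5
    bleach_tau_s: float = 1200.0  # np.inf disables bleaching
    bleach_tau2_s: float = np.inf  # optional slow component
    bleach_frac: float = 1.0  # weight of the fast component
    motion_amp: float = 0.02  # sd of the fractional shared artifact
    motion_cutoff_hz: float = 2.0
    noise_sd: float = 0.005  # detector-noise sd in volts (~0.5% of the carrier)
    seed: int = 0

    def validate(self) -> None:
        ratio = self.fs_raw / self.fs_out
        if self.fs_out <= 0 or abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError("fs_raw must be a positive integer multiple of fs_out")
        for name in ("carrier_490_hz", "carrier_405_hz"):
            f = getattr(self, name)
            if f >= self.fs_raw / 2:
                raise ValueError(
                    f"{name}={f:g} Hz at or above Nyquist of fs_raw ({self.fs_raw / 2:g} Hz)"
                )
        for name in (
            "duration_s",
            "transient_rate_hz",
            "transient_amp",
            "transient_tau_rise_s",
            "transient_tau_decay_s",
            "bleach_tau_s",
            "motion_amp",
            "noise_sd",
            "amp_490",
            "amp_405",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.transient_tau_decay_s <= self.transient_tau_rise_s:
            raise ValueError("transient_tau_decay_s must exceed transient_tau_rise_s")


@dataclass
class GroundTruth:
    """Latent components of a generated session, at the output rate."""

    transient_times: np.ndarray  # kernel onset times, s, strictly increasing
    true_dff: np.ndarray
    motion_trace: np.ndarray
    bleach_trace: np.ndarray
    fs: float


def transient_kernel_peak_delay_s(config: SimulationConfig) -> float:
    """Delay from kernel onset to kernel peak (analytic, difference of exps)."""
    tr, td = config.transient_tau_rise_s, config.transient_tau_decay_s
    return float(np.log(td / tr) * tr * td / (td - tr))


def _transient_kernel(config: SimulationConfig, fs: float) -> np.ndarray:
    tr, td = config.transient_tau_rise_s, config.transient_tau_decay_s
    t = np.arange(0, 7 * td, 1.0 / fs)
    k = np.exp(-t / td) - np.exp(-t / tr)
    peak = k.max()
    return config.transient_amp * k / peak if peak > 0 else k


def _add_kernels(n: int, fs: float, onsets: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = np.zeros(n)
    for t0 in onsets:
        i0 = int(round(t0 * fs))
        if i0 >= n:
            continue
        seg = kernel[: n - i0]
        out[i0 : i0 + seg.size] += seg
    return out


def _bleach(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    fast = np.exp(-t / config.bleach_tau_s) if np.isfinite(config.bleach_tau_s) else np.ones_like(t)
    if config.bleach_frac >= 1.0:
        return fast
    slow = (
        np.exp(-t / config.bleach_tau2_s)
        if np.isfinite(config.bleach_tau2_s)
        else np.ones_like(t)
    )
    return config.bleach_frac * fast + (1.0 - config.bleach_frac) * slow


def generate_session(config: SimulationConfig) -> tuple[RawRecording, GroundTruth]:
    """Simulate one raw recording and record every latent component."""
    config.validate()
    factor = int(round(config.fs_raw / config.fs_out))
    n_out = int(round(config.duration_s * config.fs_out))
    n_raw = n_out * factor
    t_raw = np.arange(n_raw) / config.fs_raw
    t_out = np.arange(n_out) / config.fs_out

    ss = np.random.SeedSequence(config.seed)
    rng_events, rng_motion, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    # Poisson event times: N ~ Poisson(rate*T), times uniform given N
    n_events = rng_events.poisson(config.transient_rate_hz * config.duration_s)
    times = np.sort(rng_events.uniform(0, config.duration_s, size=n_events))
    times = np.unique(times)

    dff_raw = _add_kernels(n_raw, config.fs_raw, times, _transient_kernel(config, config.fs_raw))
    dff_out = _add_kernels(n_out, config.fs_out, times, _transient_kernel(config, config.fs_out))

    if config.motion_amp > 0:
        white = rng_motion.standard_normal(n_out)
        sos = signal.butter(2, config.motion_cutoff_hz, fs=config.fs_out, output="sos")
        motion_out = signal.sosfiltfilt(sos, white)
        sd = motion_out.std()
        motion_out = motion_out * (config.motion_amp / sd) if sd > 0 else motion_out
    else:
        motion_out = np.zeros(n_out)
    motion_raw = np.interp(t_raw, t_out, motion_out)

    bleach_raw = _bleach(config, t_raw)
    bleach_out = _bleach(config, t_out)

    carrier_490 = np.sin(2 * np.pi * config.carrier_490_hz * t_raw)
    carrier_405 = np.sin(2 * np.pi * config.carrier_405_hz * t_raw)
    raw = bleach_raw * (
        config.amp_490 * (1.0 + dff_raw + motion_raw) * carrier_490
        + config.amp_405 * (1.0 + motion_raw) * carrier_405
    )
    if config.noise_sd > 0:
        raw = raw + rng_noise.normal(0.0, config.noise_sd, size=n_raw)

    recording = RawRecording(
        time_s=t_raw,
        detector=raw,
        fs_raw=config.fs_raw,
        meta={"config": asdict(config)},
    )
    truth = GroundTruth(
        transient_times=times,
        true_dff=dff_out,
        motion_trace=motion_out,
        bleach_trace=bleach_out,
        fs=config.fs_out,
    )
    return recording, truth


TRIAL_KINDS = ("pavlovian", "fear", "stimulus")


@dataclass
class TrialSchedule:
    """Trial onsets with stimulus timing for one conditioning session."""

    trial_onsets: np.ndarray
    cs_duration_s: float
    us_offset_s: float | None  # seconds from CS onset; None for no US
    labels: np.ndarray  # per-trial category tags
    iti_bounds_s: tuple[float, float]
    kind: str
    us_duration_s: float = 0.0

    def __post_init__(self) -> None:
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if np.any(np.diff(self.trial_onsets) <= 0):
            raise ValueError("trial onsets must be strictly increasing")
        gaps = np.diff(self.trial_onsets)
        min_gap = self.cs_duration_s + self.iti_bounds_s[0]
        if gaps.size and gaps.min() < min_gap - 1e-9:
            raise ValueError("inter-onset interval below cs_duration + minimum ITI")

    @property
    def n_trials(self) -> int:
        return self.trial_onsets.size

    def to_events(self) -> EventTable:
        """Flatten to a labeled event table (CS onsets, US onsets)."""
        times, labels = [], []
        for onset, lab in zip(self.trial_onsets, self.labels):
            if self.kind == "stimulus":
                times.append(onset)
                labels.append(lab)
                continue
            times.append(onset)
            labels.append("CS_ON")
            if self.us_offset_s is not None:
                times.append(onset + self.us_offset_s)
                labels.append("US_ON" if self.kind == "pavlovian" else "SHOCK_ON")
        order = np.argsort(times, kind="stable")
        return EventTable(
            time_s=np.asarray(times, dtype=float)[order],
            label=np.asarray(labels, dtype=object)[order],
        )


def generate_trial_schedule(
    kind: str,
    n_trials: int,
    seed: int,
    start_s: float = 60.0,
    iti_bounds_s: tuple[float, float] = (75.0, 105.0),
) -> TrialSchedule:
    """Draw a conditioning schedule with i.i.d. uniform inter-trial intervals.

    ``pavlovian``: 10 s CS with the reward delivered 7 s after CS onset.
    ``fear``: 10 s CS with a 1 s foot shock at CS offset.
    ``stimulus``: 10 s light or tone presentations, equal probability.
    """
    if kind not in TRIAL_KINDS:
        raise ValueError(f"unknown kind {kind!r}; valid kinds: {', '.join(TRIAL_KINDS)}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cs_duration = 10.0
    itis = rng.uniform(iti_bounds_s[0], iti_bounds_s[1], size=n_trials - 1)
    onsets = start_s + np.concatenate([[0.0], np.cumsum(cs_duration + itis)])
    if kind == "pavlovian":
        us_offset, us_duration = 7.0, 0.0
        labels = np.array(["CS_ON"] * n_trials, dtype=object)
    elif kind == "fear":
        us_offset, us_duration = cs_duration, 1.0
        labels = np.array(["CS_ON"] * n_trials, dtype=object)
    else:
        us_offset, us_duration = None, 0.0
        labels = rng.choice(["LIGHT_ON", "TONE_ON"], size=n_trials).astype(object)
    return TrialSchedule(
        trial_onsets=onsets,
        cs_duration_s=cs_duration,
        us_offset_s=us_offset,
        labels=labels,
        iti_bounds_s=iti_bounds_s,
        kind=kind,
        us_duration_s=us_duration,
    )


def generate_lick_train(
    bout_onsets,
    bout_rates,
    bout_durations,
    seed: int,
    jitter_sd_s: float = 0.01,
) -> np.ndarray:
    """Lick timestamps: regularly spaced licks with small jitter inside bouts.

    Bouts must not overlap; no licks are emitted outside bouts.
    """
    onsets = np.asarray(bout_onsets, dtype=float)
    rates = np.asarray(bout_rates, dtype=float)
    durations = np.asarray(bout_durations, dtype=float)
    if not (onsets.size == rates.size == durations.size):
        raise ValueError("bout vectors must have equal length")
    if onsets.size == 0:
        return np.array([], dtype=float)
    if np.any(rates <= 0):
        raise ValueError("bout rates must be positive")
    order = np.argsort(onsets)
    onsets, rates, durations = onsets[order], rates[order], durations[order]
    if np.any(onsets[1:] < onsets[:-1] + durations[:-1]):
        raise ValueError("overlapping bouts")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    licks = []
    for t0, rate, dur in zip(onsets, rates, durations):
        n = int(round(rate * dur))
        base = t0 + np.arange(n) / rate
        jit = rng.normal(0.0, jitter_sd_s, size=n) if jitter_sd_s > 0 else 0.0
        times = np.clip(base + jit, t0, t0 + dur)
        licks.append(np.sort(times))
    return np.concatenate(licks)


def generate_morphology(
    kind: str,
    length_um: float = 30.0,
    branch_at_um: float = 12.0,
    step_um: float = 1.0,
) -> NeuronTree:
    """Toy SWC-representable trees with known geometry.

    ``radial``: a straight chain from the soma at the origin along +x.
    ``y_branch``: a trunk to ``branch_at_um`` then two straight branches
    whose tips lie exactly ``length_um`` (Euclidean) from the soma.
    ``soma_only``: a single node.
    """
    kinds = ("radial", "y_branch", "soma_only")
    if kind not in kinds:
        raise ValueError(f"unknown kind {kind!r}; valid kinds: {', '.join(kinds)}")
    if length_um < 0 or branch_at_um < 0:
        raise ValueError("lengths must be >= 0")

    nodes: list[tuple[float, float, float]] = [(0.0, 0.0, 0.0)]
    parents: list[int] = [-1]
    types: list[int] = [1]  # soma

    def add_ray(start_xyz, direction, ray_len, parent_idx):
        direction = np.asarray(direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
        n_steps = max(1, int(np.ceil(ray_len / step_um)))
        prev = parent_idx
        for k in range(1, n_steps + 1):
            s = min(k * step_um, ray_len)
            p = np.asarray(start_xyz) + s * direction
            nodes.append(tuple(p))
            types.append(3)  # dendrite
            parents.append(prev)
            prev = len(nodes) - 1
        return prev

    if kind == "radial" and length_um > 0:
        add_ray((0, 0, 0), (1, 0, 0), length_um, 0)
    elif kind == "y_branch":
        if not 0 < branch_at_um < length_um:
            raise ValueError("branch point must lie strictly between soma and tip")
        bp = add_ray((0, 0, 0), (1, 0, 0), branch_at_um, 0)
        theta = np.deg2rad(30.0)
        for sign in (+1.0, -1.0):
            u = np.array([np.cos(theta), sign * np.sin(theta), 0.0])
            # ray length s solving |branch + s*u| = length_um
            b = branch_at_um * np.cos(theta)
            s = -b + np.sqrt(b**2 + length_um**2 - branch_at_um**2)
            add_ray((branch_at_um, 0, 0), u, s, bp)

    xyz = np.asarray(nodes, dtype=float)
    n = xyz.shape[0]
    return NeuronTree(
        ids=np.arange(1, n + 1),
        type_code=np.asarray(types, dtype=int),
        xyz=xyz,
        radius=np.full(n, 0.5),
        parent_id=np.asarray([p + 1 if p >= 0 else -1 for p in parents], dtype=int),
    )


def write_raw_recording(recording: RawRecording, csv_path, sidecar_path=None) -> None:
    """CSV (time_s, detector_v) with an optional JSON config sidecar."""
    import pandas as pd

    pd.DataFrame({"time_s": recording.time_s, "detector_v": recording.detector}).to_csv(
        csv_path, index=False
    )
    if sidecar_path is not None:
        meta = {k: v for k, v in recording.meta.items()}
        meta["fs_raw"] = recording.fs_raw
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2, default=float)


def write_ground_truth(truth: GroundTruth, csv_path) -> None:
    import pandas as pd

    t = np.arange(truth.true_dff.size) / truth.fs
    pd.DataFrame(
        {
            "time_s": t,
            "true_dff": truth.true_dff,
            "motion": truth.motion_trace,
            "bleach": truth.bleach_trace,
        }
    ).to_csv(csv_path, index=False)
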
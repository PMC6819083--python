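"""Lock-in recovery of fluorescence envelopes from amplitude-modulated raw signals.

Two LEDs (signal excitation and isosbestic reference) are sinusoidally
modulated at distinct carrier frequencies and collected on a single
photodetector.  Each channel's slowly varying fluorescence envelope is
recovered by quadrature lock-in demodulation: the raw trace is mixed with
sine and cosine references at the carrier frequency, low-pass filtered, and
combined as ``2 * sqrt(I**2 + Q**2)`` so that a carrier ``A*sin(2*pi*f*t +
phi)`` with slowly varying ``A`` yields ``A`` independent of phase.

The factor-2 quadrature convention (output equals carrier amplitude, not
RMS) is used throughout.  A sine-reference demodulator is implemented; the
original acquisition hardware may have used a square-wave reference, which
differs only by a scale factor absorbed into the reference fit downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "RawRecording",
    "lowpass_zero_phase",
    "lock_in_demodulate",
    "decimate_to",
    "demodulate_session",
]

#: seconds at each end of a demodulated envelope treated as filter-edge
#: contaminated and excluded from summary metrics downstream
EDGE_GUARD_S = 1.0


@dataclass
class RawRecording:
    """Single photodetector trace containing amplitude-modulated carriers.

    Attributes
    ----------
    time_s : np.ndarray
        Sample times in seconds, uniformly spaced at ``1/fs_raw``.
    detector : np.ndarray
        Photodetector samples (volts, arbitrary gain).
    fs_raw : float
        Acquisition rate in Hz.
    """

    time_s: np.ndarray
    detector: np.ndarray
    fs_raw: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.detector = np.asarray(self.detector, dtype=float)
        if self.time_s.shape != self.detector.shape:
            raise ValueError("time_s and detector must have equal length")
        if self.fs_raw <= 0:
            raise ValueError("fs_raw must be positive")
        if self.time_s.size >= 2:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, 1.0 / self.fs_raw, rtol=1e-6, atol=0):
                raise ValueError("raw recording is not uniformly sampled at fs_raw")

    @property
    def duration_s(self) -> float:
        return self.detector.size / self.fs_raw


def lowpass_zero_phase(
    x: np.ndarray, fs: float, cutoff_hz: float, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward then backward).

    The forward-backward pass squares the magnitude response, so the DC gain
    is exactly 1 and the amplitude gain at ``cutoff_hz`` is 1/2 for the
    default second-order filter.  Net phase distortion is zero, hence the
    cross-correlation between input and output peaks at lag 0.
    """
    x = np.asarray(x, dtype=float)
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(
            f"cutoff_hz must lie in (0, fs/2) = (0, {fs / 2:g}); got {cutoff_hz:g}"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def lock_in_demodulate(
    raw: RawRecording, carrier_hz: float, lp_cutoff_hz: float = 25.0
) -> np.ndarray:
    """Recover the amplitude envelope of one carrier, sampled at ``fs_raw``.

    Parameters
    ----------
    raw : RawRecording
    carrier_hz : float
        Modulation frequency of the channel to recover.  Must be below the
        raw Nyquist frequency.
    lp_cutoff_hz : float
        Post-mixing low-pass cutoff; sets the envelope bandwidth.  Must be
        below the carrier frequency, otherwise the envelope is not separable
        from the mixing image.
    """
    if carrier_hz >= raw.fs_raw / 2:
        raise ValueError(
            f"carrier {carrier_hz:g} Hz at or above Nyquist ({raw.fs_raw / 2:g} Hz)"
        )
    if lp_cutoff_hz >= carrier_hz:
        raise ValueError(
            f"lock-in cutoff {lp_cutoff_hz:g} Hz must be below the carrier "
            f"{carrier_hz:g} Hz (envelope not separable)"
        )
    phase = 2 * np.pi * carrier_hz * raw.time_s
    i_comp = lowpass_zero_phase(raw.detector * np.sin(phase), raw.fs_raw, lp_cutoff_hz)
    q_comp = lowpass_zero_phase(raw.detector * np.cos(phase), raw.fs_raw, lp_cutoff_hz)
    return 2.0 * np.hypot(i_comp, q_comp)


def decimate_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-alias filter then keep every ``fs_in/fs_out``-th sample.

    ``fs_in`` must be an integer multiple of ``fs_out``.  The anti-alias
    low-pass cutoff is ``0.4 * fs_out``; output length is
    ``floor(len(x) / factor)``.
    """
    x = np.asarray(x, dtype=float)
    ratio = fs_in / fs_out
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"fs_in ({fs_in:g}) must be an integer multiple of fs_out ({fs_out:g})"
        )
    if factor == 1:
        return x.copy()
    y = lowpass_zero_phase(x, fs_in, 0.4 * fs_out, order=8)
    n_out = x.size // factor
    return y[::factor][:n_out]


def demodulate_session(
    raw: RawRecording,
    carrier_490_hz: float = 211.0,
    carrier_405_hz: float = 531.0,
    fs_out: float = 382.0,
    lp_cutoff_hz: float = 25.0,
):
    """Full demodulation pipeline: both carriers -> envelopes -> decimation.

    Returns a :class:`photoflux.session_io.PhotometrySession` at ``fs_out``
    with ``meta['edge_s']`` marking the filter-edge guard interval.
    """
    from .session_io import PhotometrySession

    env490 = decimate_to(
        lock_in_demodulate(raw, carrier_490_hz, lp_cutoff_hz), raw.fs_raw, fs_out
    )
    env405 = decimate_to(
        lock_in_demodulate(raw, carrier_405_hz, lp_cutoff_hz), raw.fs_raw, fs_out
    )
    time_s = np.arange(env490.size) / fs_out + raw.time_s[0]
    return PhotometrySession(
        time_s=time_s,
        ch490=env490,
        ch405=env405,
        fs=fs_out,
        meta={"edge_s": EDGE_GUARD_S, **raw.meta},
    )
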
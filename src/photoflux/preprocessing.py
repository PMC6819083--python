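"""Isosbestic reference fitting, dF/F, and robust z-score normalization.

The reference (isosbestic) channel tracks motion and photobleaching but is
insensitive to the analyte, so after a whole-session least-squares fit of
the signal channel on the reference, the fractional fluorescence change

    dF/F = (ch490 - fitted405) / fitted405

cancels artifacts shared by the two channels to first order.  Traces are
then standardized with a robust z-score

    z = (x - median(x)) / MAD(x),    MAD(x) = median(|x - median(x)|)

with NO Gaussian-consistency factor by default (``consistency=True``
multiplies the MAD by 1.4826 for those who want sigma-comparable units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReferenceFit",
    "DffTrace",
    "ZTrace",
    "fit_reference",
    "compute_dff",
    "robust_z",
    "process_session",
]

MAD_CONSISTENCY = 1.4826022185056018  # 1 / Phi^-1(3/4)


@dataclass
class ReferenceFit:
    slope: float
    intercept: float
    fitted405: np.ndarray


@dataclass
class DffTrace:
    """Fractional fluorescence change with the reference-fit parameters."""

    time_s: np.ndarray
    dff: np.ndarray
    fs: float
    fit_slope: float = np.nan
    fit_intercept: float = np.nan
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.time_s.shape != self.dff.shape:
            raise ValueError("time_s and dff must have equal length")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff contains non-finite values")

    def __len__(self) -> int:
        return self.dff.size

    @property
    def edge_s(self) -> float:
        return float(self.meta.get("edge_s", 0.0))


@dataclass
class ZTrace:
    """Robust z-scored trace; ``center``/``scale`` are the source median/MAD."""

    time_s: np.ndarray
    z: np.ndarray
    center: float
    scale: float
    fs: float
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.z.size

    @property
    def edge_s(self) -> float:
        return float(self.meta.get("edge_s", 0.0))


def fit_reference(ch490: np.ndarray, ch405: np.ndarray) -> ReferenceFit:
    """Ordinary least squares of the signal channel on the reference channel.

    The fit is computed once over the whole session.  Residuals are
    orthogonal to the reference by construction.
    """
    ch490 = np.asarray(ch490, dtype=float)
    ch405 = np.asarray(ch405, dtype=float)
    if ch490.size != ch405.size:
        raise ValueError("channels must have equal length")
    if ch490.size < 3:
        raise ValueError("need at least 3 samples for the reference fit")
    if np.ptp(ch405) == 0:
        raise ValueError("constant reference channel: degenerate design")
    slope, intercept = np.polyfit(ch405, ch490, 1)
    return ReferenceFit(
        slope=float(slope),
        intercept=float(intercept),
        fitted405=slope * ch405 + intercept,
    )


def compute_dff(ch490: np.ndarray, fitted405: np.ndarray) -> np.ndarray:
    """Elementwise ``(ch490 - fitted405) / fitted405``.

    The fitted reference must be strictly positive everywhere (it is the
    denominator); violations are rejected with the affected sample count.
    """
    ch490 = np.asarray(ch490, dtype=float)
    fitted405 = np.asarray(fitted405, dtype=float)
    n_bad = int(np.count_nonzero(fitted405 <= 0))
    if n_bad:
        raise ValueError(
            f"fitted reference is non-positive at {n_bad} sample(s); dF/F undefined"
        )
    return (ch490 - fitted405) / fitted405


def robust_z(x: np.ndarray, consistency: bool = False) -> tuple[np.ndarray, float, float]:
    """Robust z-score; returns ``(z, center, scale)``.

    ``center`` is the median, ``scale`` the (raw) MAD.  A constant or
    half-constant trace has MAD 0 and is rejected.  The transform is
    invariant under positive affine maps of the input.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    center = float(np.median(x))
    scale = float(np.median(np.abs(x - center)))
    if consistency:
        scale *= MAD_CONSISTENCY
    if scale == 0:
        raise ValueError("MAD is zero (constant or half-constant trace)")
    return (x - center) / scale, center, scale


def process_session(session, consistency: bool = False) -> tuple[DffTrace, ZTrace]:
    """Reference fit -> dF/F -> robust z for a whole PhotometrySession."""
    fit = fit_reference(session.ch490, session.ch405)
    dff = compute_dff(session.ch490, fit.fitted405)
    dff_trace = DffTrace(
        time_s=session.time_s,
        dff=dff,
        fs=session.fs,
        fit_slope=fit.slope,
        fit_intercept=fit.intercept,
        meta=dict(session.meta),
    )
    z, center, scale = robust_z(dff, consistency=consistency)
    z_trace = ZTrace(
        time_s=session.time_s,
        z=z,
        center=center,
        scale=scale,
        fs=session.fs,
        meta=dict(session.meta),
    )
    return dff_trace, z_trace
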
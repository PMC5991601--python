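"""CMAP feature extraction from trigger-aligned EMG.

A stimulation trial delivers four pulse trains at 100%, 110%, 120% and 130%
of the motor threshold (MT), four pulses per level at roughly 500 ms
inter-stimulus interval, while EMG is recorded (2 kHz in the reference
protocol) together with a trigger channel.  Per level, the four
trigger-aligned sweeps are grand-averaged; the peak-to-peak voltage of each
grand average gives the CMAP amplitude and the time of its largest peak the
latency.  The four amplitudes are normalised to

    NCMAP_k = (CMAP_k - CMAP_1) / (CMAP_4 - CMAP_1) * 100        (percent)

which pins NCMAP_1 = 0 and NCMAP_4 = 100 and removes subject-dependent
amplitude scaling.  The normalised amplitudes against the stimulus currents
form the linear nerve-muscle model NCMAP = theta1 * i + theta2, solved by
ordinary least squares; (theta1, theta2) summarise the recruitment response
of one trial.  The motor threshold itself is found by a stepped ascending
current search for the first detectable response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateRange,
    IncompleteWindow,
    NoResponse,
    ShapeMismatch,
    SingularDesign,
    ThresholdNotFound,
)

__all__ = [
    "StimulusSeries",
    "EMGRecording",
    "CMAPFeatureSet",
    "MotorThresholdResult",
    "segment_by_trigger",
    "grand_average",
    "extract_amplitude_latency",
    "normalize_cmaps",
    "fit_linear_nerve_model",
    "find_motor_threshold",
]

#: Fractional steps of the four stimulus levels relative to MT.
LEVEL_FRACTIONS = (1.0, 1.10, 1.20, 1.30)

#: Default post-trigger search window (s): skips the 0-2 ms stimulus
#: artifact, ends at 50 ms (standard intraoperative-monitoring practice).
DEFAULT_SEARCH_WINDOW = (0.002, 0.050)


@dataclass(frozen=True)
class StimulusSeries:
    """Four stimulus currents at 100/110/120/130% of the motor threshold."""

    i_mt: float
    levels: tuple[float, float, float, float]
    pulses_per_level: int = 4
    isi: float = 0.5

    @classmethod
    def from_mt(
        cls, i_mt: float, *, pulses_per_level: int = 4, isi: float = 0.5
    ) -> "StimulusSeries":
        if i_mt <= 0:
            raise ValueError("motor threshold must be positive")
        levels = tuple(f * i_mt for f in LEVEL_FRACTIONS)
        return cls(i_mt=i_mt, levels=levels,
                   pulses_per_level=pulses_per_level, isi=isi)


@dataclass(frozen=True)
class EMGRecording:
    """Continuous EMG with stimulus trigger instants."""

    signal: np.ndarray
    sample_rate: float
    trigger_times: np.ndarray

    def __post_init__(self):
        trig = np.asarray(self.trigger_times, dtype=float)
        if trig.size and (np.any(np.diff(trig) <= 0) or trig[0] < 0):
            raise ValueError("trigger times must be non-negative and strictly increasing")
        duration = len(self.signal) / self.sample_rate
        if trig.size and trig[-1] >= duration:
            raise ValueError("all triggers must fall inside the recording")


@dataclass(frozen=True)
class CMAPFeatureSet:
    """Per-trial CMAP features across the four stimulus levels."""

    vpp: tuple[float, float, float, float]       # volts, grand averages
    ncmap: tuple[float, float, float, float]     # percent
    theta1: float                                # percent per ampere
    theta2: float                                # percent
    lin_r_squared: float
    t_l: float                                   # seconds, mean latency


@dataclass(frozen=True)
class MotorThresholdResult:
    """Outcome of the ascending motor-threshold search."""

    i_mt: float
    at_floor: bool = field(default=False)  # responded at the starting current
    n_steps: int = 0


def segment_by_trigger(rec: EMGRecording, window: float) -> np.ndarray:
    """Cut one fixed-length post-trigger segment per stimulus pulse.

    Returns an array of shape ``(n_triggers, floor(window * fs))`` where
    sample 0 of each row is the trigger instant.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    fs = rec.sample_rate
    n = int(np.floor(window * fs))
    signal = np.asarray(rec.signal, dtype=float)
    segments = []
    for k, t in enumerate(np.asarray(rec.trigger_times, dtype=float)):
        start = int(round(t * fs))
        if start + n > signal.size:
            raise IncompleteWindow(
                f"trigger {k} at {t:.4f} s: window of {n} samples runs past "
                f"the end of the recording ({signal.size} samples)"
            )
        segments.append(signal[start : start + n])
    return np.stack(segments) if segments else np.empty((0, n))


def grand_average(segments: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Pointwise mean of equal-length stimulus-aligned segments."""
    segs = [np.asarray(s, dtype=float) for s in segments]
    if not segs:
        raise ValueError("need at least one segment")
    length = segs[0].size
    for k, s in enumerate(segs):
        if s.size != length:
            raise ShapeMismatch(
                f"segment {k} has {s.size} samples, expected {length}"
            )
    return np.mean(np.stack(segs), axis=0)


def extract_amplitude_latency(
    avg: np.ndarray,
    sample_rate: float,
    *,
    search_window: tuple[float, float] = DEFAULT_SEARCH_WINDOW,
    threshold: float = 0.0,
) -> tuple[float, float]:
    """Peak-to-peak amplitude and peak latency of a grand-averaged segment.

    ``avg`` must be aligned so sample 0 is the trigger instant.  The search
    is restricted to ``search_window`` (seconds after the trigger); amplitude
    is max - min over the window and latency the time of the largest-
    magnitude sample.

    Raises :class:`NoResponse` when the amplitude does not exceed
    ``threshold`` (callers typically pass a multiple of the baseline noise
    SD; the flat default rejects only an identically-flat window).
    """
    avg = np.asarray(avg, dtype=float)
    i0 = int(round(search_window[0] * sample_rate))
    i1 = min(avg.size, int(round(search_window[1] * sample_rate)))
    if i1 - i0 < 2:
        raise ValueError("search window too short for this segment")
    seg = avg[i0:i1]
    vpp = float(seg.max() - seg.min())
    if vpp <= threshold:
        raise NoResponse(
            f"peak-to-peak {vpp:.3e} V does not exceed threshold {threshold:.3e} V"
        )
    latency = (int(np.argmax(np.abs(seg))) + i0) / sample_rate
    return vpp, latency


def normalize_cmaps(vpp) -> np.ndarray:
    """Normalise four CMAP amplitudes to percent of the level-1..4 span.

    ``ncmap_k = (vpp_k - vpp_1) / (vpp_4 - vpp_1) * 100``; the first and
    last entries are exactly 0 and 100 by construction.
    """
    vpp = np.asarray(vpp, dtype=float)
    if vpp.shape != (4,):
        raise ValueError("expected exactly four amplitudes")
    span = vpp[3] - vpp[0]
    if span == 0.0:
        raise DegenerateRange("CMAP4 equals CMAP1; normalization undefined")
    return (vpp - vpp[0]) / span * 100.0


def fit_linear_nerve_model(levels, ncmap) -> tuple[float, float, float]:
    """Ordinary least squares of normalised amplitude on stimulus current.

    Solves ``theta = (X^T X)^{-1} X^T y`` for the line
    ``ncmap = theta1 * i + theta2`` and returns
    ``(theta1, theta2, r_squared)``.
    """
    levels = np.asarray(levels, dtype=float)
    ncmap = np.asarray(ncmap, dtype=float)
    if levels.size != ncmap.size or levels.size < 2:
        raise ValueError("need >= 2 paired (current, ncmap) points")
    if np.ptp(levels) == 0.0:
        raise SingularDesign("all stimulus currents equal; slope undefined")
    X = np.column_stack([levels, np.ones_like(levels)])
    coef, _, _, _ = np.linalg.lstsq(X, ncmap, rcond=None)
    theta1, theta2 = float(coef[0]), float(coef[1])
    resid = ncmap - X @ coef
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ncmap - ncmap.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return theta1, theta2, r_squared


def find_motor_threshold(
    stimulate,
    start: float,
    step: float,
    max_current: float,
    *,
    threshold: float = 0.0,
) -> MotorThresholdResult:
    """Ascending-staircase motor-threshold search.

    ``stimulate(current) -> vpp`` is a trial oracle returning the measured
    peak-to-peak response amplitude (0 when nothing is detectable).  Currents
    are tested on the grid ``start, start + step, ...`` up to ``max_current``
    and the first current whose response exceeds ``threshold`` is returned as
    the motor threshold.  ``at_floor`` is set when the very first current
    already responds (the true threshold may lie below the grid).

    Raises :class:`ThresholdNotFound` when nothing responds up to
    ``max_current`` (no nerve in range, or the safety limit).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if start >= max_current:
        raise ValueError("start must be below max_current")
    k = 0
    while True:
        current = start + k * step
        if current > max_current * (1 + 1e-12):
            raise ThresholdNotFound(
                f"no response up to the maximum current {max_current:.3e} A"
            )
        vpp = stimulate(current)
        if vpp > threshold:
            return MotorThresholdResult(i_mt=current, at_floor=(k == 0), n_steps=k + 1)
        k += 1
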
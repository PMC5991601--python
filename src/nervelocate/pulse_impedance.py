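"""Tissue equivalent-circuit estimation from constant-current pulse responses.

A monopolar stimulating probe driving a constant-current pulse ``i`` into
tissue sees, to first order, a series access resistance ``Rs`` in line with a
parallel membrane/interface pair ``Rp || Cp``.  The driven voltage waveform of
one pulse then follows

    V(t) = i*Rs + i*Rp * (1 - exp(-(t - t0)/tau)),    tau = Rp*Cp,

rising instantaneously to ``V0 = i*Rs`` at the pulse onset ``t0`` and
saturating at ``Vx = i*(Rs + Rp)``.  Inverting those three landmarks gives the
circuit:

    Rs = V0 / i
    Rp = Vx / i - Rs
    Cp = tau / Rp

with ``tau`` estimated by one-parameter nonlinear least squares on the
charging segment.  The impedance magnitude at a probing frequency ``f`` is
that of the same topology, ``|Rs + Rp / (1 + j*2*pi*f*Rp*Cp)|``.

This module performs the full estimation from a sampled waveform: edge/plateau
landmark detection, the closed-form resistance estimates, the time-constant
fit, and the derived impedance magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    AmbiguousPulse,
    FitNotConverged,
    NoPulseDetected,
    UndefinedCapacitance,
)

__all__ = [
    "PulseResponse",
    "TissueRC",
    "detect_pulse_edges",
    "fit_rc_from_pulse",
    "impedance_magnitude",
    "charging_curve",
]

#: Default frequency (Hz) at which impedance magnitude is reported.
DEFAULT_IMPEDANCE_FREQ_HZ = 500e3


@dataclass(frozen=True)
class PulseResponse:
    """One constant-current pulse response with detected landmarks.

    Attributes
    ----------
    time, voltage : ndarray
        Uniformly sampled waveform (seconds, volts).
    current : float
        Constant pulse amplitude ``i`` in amperes.
    sample_rate : float
        Sampling rate in Hz.
    t0, tx : float
        Rising-edge time and start of the saturated plateau (seconds).
    v0, vx : float
        Voltage immediately after the rising edge and the plateau
        (saturation) voltage estimate (volts).
    """

    time: np.ndarray
    voltage: np.ndarray
    current: float
    sample_rate: float
    t0: float
    tx: float
    v0: float
    vx: float


@dataclass(frozen=True)
class TissueRC:
    """Estimated equivalent circuit: series Rs with parallel Rp || Cp.

    ``cp`` and ``tau`` are NaN when the charging segment is degenerate
    (purely resistive load, ``vx ~ v0``); ``rp`` is then 0.
    ``r_squared`` is the coefficient of determination of the time-constant
    fit (NaN when no fit was performed).
    """

    rs: float
    rp: float
    cp: float
    tau: float
    r_squared: float

    @property
    def cp_defined(self) -> bool:
        return np.isfinite(self.cp)


def charging_curve(
    t: np.ndarray, v0: float, vx: float, tau: float
) -> np.ndarray:
    """Closed-form RC charging curve ``v0 + (vx - v0)*(1 - exp(-t/tau))``.

    ``t`` is measured from the rising edge; the curve starts at ``v0`` and
    saturates at ``vx``.
    """
    return v0 + (vx - v0) * (1.0 - np.exp(-np.asarray(t, dtype=float) / tau))


def _validate_waveform(time: np.ndarray, voltage: np.ndarray) -> float:
    time = np.asarray(time, dtype=float)
    voltage = np.asarray(voltage, dtype=float)
    if time.ndim != 1 or voltage.ndim != 1 or time.size != voltage.size:
        raise ValueError("time and voltage must be 1-D arrays of equal length")
    if time.size < 16:
        raise ValueError("waveform must have at least 16 samples")
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise ValueError("time must be strictly increasing")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > 1e-6 * step + 1e-15:
        raise ValueError("time must be uniformly sampled (within 1 ppm)")
    return step


def detect_pulse_edges(
    time: np.ndarray,
    voltage: np.ndarray,
    current: float,
    *,
    edge_threshold_factor: float = 10.0,
    plateau_slope_frac: float = 0.01,
    v0_samples: int = 1,
) -> PulseResponse:
    """Locate the rising edge, plateau and landmark voltages of one pulse.

    The rising edge is the largest forward difference, accepted only if it
    exceeds ``edge_threshold_factor`` times the pre-pulse noise SD.  ``v0`` is
    the voltage at the first in-pulse sample (median of ``v0_samples`` samples
    when > 1, for robustness on noisy traces).  The plateau starts where the
    smoothed slope falls below ``plateau_slope_frac`` of the initial slope (or
    below the slope noise floor, whichever is larger); ``vx`` is the mean of
    the final 10% of the plateau.

    Raises
    ------
    NoPulseDetected
        When no rising edge exceeds the noise threshold.
    AmbiguousPulse
        When more than one separated rising edge is present.
    """
    time = np.asarray(time, dtype=float)
    voltage = np.asarray(voltage, dtype=float)
    dt = _validate_waveform(time, voltage)
    if current <= 0:
        raise ValueError("current must be positive")

    d = np.diff(voltage)
    i_rise = int(np.argmax(d))
    jump = d[i_rise]

    # The largest forward difference may be the first *charging* increment
    # rather than the onset step itself (fast time constants, small Rs):
    # walk back over the contiguous run of significant positive diffs so the
    # edge is the first sample of the pulse.
    noise_sd0 = float(np.std(voltage[:i_rise])) if i_rise >= 4 else 0.0
    back_floor = max(edge_threshold_factor * noise_sd0, 1e-9 * abs(jump))
    while i_rise > 0 and d[i_rise - 1] > back_floor:
        i_rise -= 1

    # Pre-pulse noise level, from the samples preceding the edge.
    noise_sd = float(np.std(voltage[:i_rise])) if i_rise >= 4 else 0.0
    if jump <= 0 or jump <= edge_threshold_factor * noise_sd:
        raise NoPulseDetected(
            "no rising edge exceeds the noise threshold "
            f"(max jump {jump:.3e} V, threshold "
            f"{edge_threshold_factor * noise_sd:.3e} V)"
        )

    # Ambiguity: separated clusters of comparably large positive jumps.
    strong = np.flatnonzero(
        (d > 0.5 * jump) & (d > edge_threshold_factor * noise_sd)
    )
    if strong.size > 1 and np.max(np.diff(strong)) > 16:
        raise AmbiguousPulse(
            f"{strong.size} separated rising edges detected; expected one pulse"
        )

    n0 = i_rise + 1  # first in-pulse sample
    t0 = time[n0]
    if v0_samples <= 1:
        v0 = float(voltage[n0])
    else:
        v0 = float(np.median(voltage[n0 : n0 + v0_samples]))

    # Falling edge (end of pulse), if present in the record.
    d_after = d[n0:]
    if d_after.size:
        j = int(np.argmin(d_after)) + n0
        n_end = j if d_after.min() < -0.5 * jump else voltage.size - 1
    else:
        n_end = voltage.size - 1
    if n_end <= n0:
        n_end = voltage.size - 1

    # Plateau onset: smoothed slope below 1% of the initial slope, or below
    # the slope noise floor (3 SD of the smoothed pre-pulse slope) - the raw
    # 1% rule is unusable under measurement noise because the true slope near
    # saturation is far below the sample-to-sample noise.
    n_pulse = n_end - n0
    w = max(1, n_pulse // 50)
    kernel = np.ones(w) / w
    vs = np.convolve(voltage, kernel, mode="same")
    ds = np.diff(vs)
    s0 = (voltage[min(n0 + w, n_end)] - voltage[n0]) / max(w, 1)
    if i_rise > 3 * w:
        noise_floor = 3.0 * float(np.std(np.diff(vs[: i_rise - w])))
    else:
        noise_floor = 0.0
    slope_thresh = max(plateau_slope_frac * s0, noise_floor)

    m_plateau = n_end
    if s0 <= 0:
        m_plateau = n0  # ideal step: flat top begins immediately
    else:
        for m in range(min(n0 + w, n_end), n_end):
            if abs(ds[m]) < slope_thresh:
                m_plateau = m
                break
    tx = time[m_plateau]

    k0 = m_plateau + int(np.floor(0.9 * (n_end - m_plateau)))
    vx = float(np.mean(voltage[k0 : n_end + 1]))

    return PulseResponse(
        time=time,
        voltage=voltage,
        current=float(current),
        sample_rate=1.0 / dt,
        t0=float(t0),
        tx=float(tx),
        v0=v0,
        vx=vx,
    )


def fit_rc_from_pulse(
    pulse: PulseResponse,
    *,
    degenerate_rel_tol: float = 1e-3,
) -> TissueRC:
    """Estimate (Rs, Rp, Cp, tau) from a pulse response with valid landmarks.

    Rs and Rp come from the closed-form landmark relations; tau from a
    bounded one-parameter nonlinear least-squares fit of the charging curve
    over [t0, tx] with V0 and Vx held at the landmark values, initialised at
    the 63.2% rise time.  Cp = tau / Rp.

    A purely resistive response (``vx ~ v0`` within ``degenerate_rel_tol``
    relative) returns ``rp = 0`` with ``cp``/``tau`` undefined (NaN).
    """
    i = pulse.current
    rs = pulse.v0 / i
    dv = pulse.vx - pulse.v0
    scale = max(abs(pulse.vx), abs(pulse.v0), 1e-300)
    if abs(dv) <= degenerate_rel_tol * scale:
        return TissueRC(rs=rs, rp=0.0, cp=np.nan, tau=np.nan, r_squared=np.nan)

    rp = pulse.vx / i - rs

    mask = (pulse.time >= pulse.t0) & (pulse.time <= pulse.tx)
    tt = pulse.time[mask] - pulse.t0
    vv = pulse.voltage[mask]
    if tt.size < 4:
        raise FitNotConverged(
            "too few samples in the charging window [t0, tx] for a tau fit",
            diagnostics={"n_window": int(tt.size)},
        )

    # Initial tau: time to reach 63.2% of the rise.
    target = pulse.v0 + 0.632 * dv
    crossed = np.flatnonzero(vv >= target) if dv > 0 else np.flatnonzero(vv <= target)
    dt = 1.0 / pulse.sample_rate
    tau0 = float(tt[crossed[0]]) if crossed.size else (pulse.tx - pulse.t0) / 3.0
    t_span = pulse.time[-1] - pulse.t0
    tau0 = float(np.clip(tau0, dt, t_span))

    def resid(theta: np.ndarray) -> np.ndarray:
        return charging_curve(tt, pulse.v0, pulse.vx, theta[0]) - vv

    sol = least_squares(
        resid, x0=[tau0], bounds=([dt], [t_span]), method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        raise FitNotConverged(
            f"tau fit did not converge: {sol.message}",
            diagnostics={"tau_candidate": float(sol.x[0]), "cost": float(sol.cost)},
        )
    tau = float(sol.x[0])

    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((vv - vv.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    if t_span < 5.0 * tau:
        warnings.warn(
            f"pulse duration {t_span:.3g} s is below 5x the apparent time "
            f"constant {tau:.3g} s; Rp and Cp estimates may be biased",
            stacklevel=2,
        )

    cp = tau / rp
    return TissueRC(rs=rs, rp=rp, cp=cp, tau=tau, r_squared=r_squared)


def impedance_magnitude(
    rc: TissueRC, frequency: float = DEFAULT_IMPEDANCE_FREQ_HZ
) -> float:
    """Impedance magnitude ``|Rs + Rp / (1 + j*2*pi*f*Rp*Cp)|`` in ohms.

    At f = 0 the capacitor is open and the result is ``Rs + Rp`` regardless
    of Cp.  For f > 0 an undefined Cp raises :class:`UndefinedCapacitance`.
    """
    if frequency < 0:
        raise ValueError("frequency must be non-negative")
    if frequency == 0:
        return rc.rs + rc.rp
    if not rc.cp_defined:
        raise UndefinedCapacitance(
            "Cp is undefined for this circuit; impedance at f > 0 unavailable"
        )
    omega = 2.0 * np.pi * frequency
    z = rc.rs + rc.rp / (1.0 + 1j * omega * rc.rp * rc.cp)
    return float(np.abs(z))
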
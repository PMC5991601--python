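"""Seeded electrophysiology phantom: synthetic bench data for the pipeline.

The phantom emulates the reference bench protocol end to end so that every
stage - pulse-response impedance estimation, motor-threshold search, CMAP
feature extraction and the distance regression - runs with no external
data.  The default study design is 12 subjects x 4 mock materials x 5
probe-to-nerve distances (0-4 mm), i.e. 240 trials.  Per trial:

* a constant-current pulse response of the subject's mock-material RC
  circuit is synthesised (1 MHz sampling) and pushed through the *real*
  impedance pipeline to obtain the estimated circuit and |Z| at 500 kHz;
* the motor threshold is found by the real ascending search against a
  simulated stimulate-and-record oracle; the true threshold follows a
  monotone law in distance and impedance,
      i_thresh = a0 * (1 + a1 * d_eff) * (1 + a2 / Z);
* four stimulus levels (100-130% MT, four sweeps each at 500 ms ISI,
  2 kHz EMG) elicit a biphasic CMAP whose amplitude follows the generative
  amplitude law  CMAP = lambda1 * iMT / (d_eff * Z)  scaled by a mildly
  saturating recruitment factor across levels, and whose latency follows
  tL = t_base + lambda2 * Z * d_eff;
* the real segmentation / grand-averaging / normalisation / linear-model
  pipeline turns the EMG into a :class:`FeatureRecord`.

``d_eff = d + d_offset`` (default 0.5 mm electrode standoff) keeps the
inverse-distance amplitude law finite at probe contact.  The CMAP template
is biphasic with *flat-topped* lobes longer than one EMG sample period, so
that in the noiseless limit the sampled peak-to-peak amplitude equals the
generative amplitude exactly and extracted features match the generative
laws up to latency quantisation.  The quantitative law coefficients are
synthetic choices spanning realistic ranges (tens to hundreds of uA
thresholds, mV CMAPs, ~7 ms latencies); they are configuration, not
measured claims about tissue.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cmap_features as cf
from . import pulse_impedance as pi
from .errors import NoResponse, NoResponsePossible, ThresholdNotFound
from .nerve_model import FeatureRecord

__all__ = [
    "PhantomConfig",
    "PhantomDataset",
    "cmap_template",
    "simulate_pulse_response",
    "simulate_trial",
    "generate_dataset",
]

#: Representative mock-material equivalent circuits (Rs ohm, Rp ohm, Cp F)
#: spanning the gelatin %NaCl series from highest to lowest impedance.
DEFAULT_MATERIALS = (
    ("mat1", 1087.36, 19520.0, 0.82e-9),
    ("mat2", 858.11, 7360.0, 5.67e-9),
    ("mat3", 577.51, 6720.0, 7.83e-9),
    ("mat4", 330.75, 6480.0, 10.39e-9),
)


@dataclass(frozen=True)
class PhantomConfig:
    """Study design, generative laws and noise levels of the phantom.

    Noise fields are 1-sigma levels of the corresponding disturbance; all
    are multiplied by ``noise_scale`` (0 gives the noiseless limit).
    ``rc_jitter_rel`` is between-subject heterogeneity of the material
    circuits, not measurement noise, and is unaffected by ``noise_scale``.
    """

    n_subjects: int = 12
    materials: tuple = DEFAULT_MATERIALS
    distances_mm: tuple = (0.0, 1.0, 2.0, 3.0, 4.0)
    d_offset_mm: float = 0.5          # electrode standoff added to d

    # generative law coefficients (synthetic, see module docstring)
    lambda1: float = 2.0e4            # V*ohm*mm/A, amplitude law gain
    lambda2: float = 5.0e-7           # s/(ohm*mm), latency law gain
    latency_base_s: float = 7.0e-3    # propagation delay at contact
    recruit_gain: float = 2.0         # recruitment slope over MT..130%MT
    recruit_curv: float = 0.8         # mild saturation of recruitment
    mt_a0: float = 2.0e-5             # A, threshold at contact, no shunt
    mt_a1: float = 1.0                # 1/mm, distance coefficient
    mt_a2: float = 200.0              # ohm, impedance (shunting) coefficient

    # acquisition
    waveform_sample_rate: float = 1.0e6
    pulse_width_s: float = 1.0e-3
    pulse_pre_s: float = 2.0e-4
    pulse_post_s: float = 2.0e-4
    stim_current_a: float = 2.5e-4    # impedance-measurement pulse current
    emg_sample_rate: float = 2000.0
    isi_s: float = 0.5
    pulses_per_level: int = 4
    cmap_window_s: float = 0.05
    impedance_freq_hz: float = 500e3

    # motor-threshold search grid
    mt_start_a: float = 1.0e-5
    mt_step_a: float = 5.0e-6
    mt_max_a: float = 5.0e-4
    mt_detect_factor: float = 10.0    # x baseline SD, single-sweep detection

    # noise (1 sigma)
    waveform_noise_sd_v: float = 2.0e-3
    emg_noise_sd_v: float = 2.0e-5
    amp_jitter_rel: float = 0.05
    latency_jitter_sd_s: float = 2.0e-4
    mt_jitter_rel: float = 0.05
    noise_scale: float = 1.0
    rc_jitter_rel: float = 0.05

    seed: int = 0

    def noiseless(self) -> "PhantomConfig":
        """Copy of this config with all noise sources switched off."""
        return replace(self, noise_scale=0.0)


@dataclass
class PhantomDataset:
    """Generated trials: extracted features, ground truth, and flags.

    ``records``, ``truth`` and ``flags`` are aligned per trial; a trial
    whose threshold exceeded the current limit keeps its slot with a
    ``None`` record and a flag string (flagged, not dropped).
    """

    config: PhantomConfig
    records: list[FeatureRecord | None]
    truth: list[dict]
    flags: list[str | None]

    @property
    def valid_records(self) -> list[FeatureRecord]:
        return [r for r in self.records if r is not None]

    def to_frame(self) -> pd.DataFrame:
        from .io import records_to_frame

        return records_to_frame(self.valid_records)

    @property
    def n_valid(self) -> int:
        return sum(f is None for f in self.flags)


# --- waveform synthesis -----------------------------------------------------

def simulate_pulse_response(
    rs: float,
    rp: float,
    cp: float,
    current: float,
    *,
    duration_s: float = 1.0e-3,
    sample_rate: float = 1.0e6,
    pre_s: float = 2.0e-4,
    post_s: float = 2.0e-4,
    noise_sd_v: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled driven-voltage waveform of one constant-current pulse.

    Zero baseline before and after the pulse; during the pulse
    ``V(t) = i*Rs + i*Rp*(1 - exp(-(t - t_on)/(Rp*Cp)))``, with the pulse
    onset aligned to the sample grid.  Additive white Gaussian noise of SD
    ``noise_sd_v``.  Returns ``(time, voltage)``.
    """
    if min(rs, rp, cp) < 0:
        raise ValueError("circuit parameters must be non-negative")
    dt = 1.0 / sample_rate
    n_pre = int(round(pre_s * sample_rate))
    n_on = int(round(duration_s * sample_rate))
    n_post = int(round(post_s * sample_rate))
    n = n_pre + n_on + n_post
    time = np.arange(n) * dt
    voltage = np.zeros(n)
    if current != 0.0 and n_on > 0:
        t_rel = (np.arange(n_on)) * dt
        v0 = current * rs
        if rp > 0 and cp > 0:
            voltage[n_pre : n_pre + n_on] = v0 + current * rp * (
                1.0 - np.exp(-t_rel / (rp * cp))
            )
        else:
            voltage[n_pre : n_pre + n_on] = v0 + current * rp
    if noise_sd_v > 0:
        rng = rng or np.random.default_rng()
        voltage = voltage + rng.normal(0.0, noise_sd_v, size=n)
    return time, voltage


# --- CMAP template ----------------------------------------------------------

# Biphasic template timing (s), relative to the positive flat-top onset.
# Both lobes are flat for 0.6 ms (> one EMG sample at 2 kHz), so the sampled
# extrema equal the continuous extrema for any sub-sample alignment.
_T_RISE = 0.4e-3
_T_FLAT = 0.6e-3
_T_CROSS = 0.6e-3
_POS, _NEG = 0.6, -0.4  # lobe amplitudes; peak-to-peak = 1


def cmap_template(t: np.ndarray) -> np.ndarray:
    """Unit-peak-to-peak biphasic CMAP shape.

    ``t`` is time relative to the positive peak (flat-top onset).  The shape
    spans [-0.4 ms, +2.2 ms]: linear rise, +0.6 flat top, crossing to a
    -0.4 flat trough, linear recovery.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    seg = (t >= -_T_RISE) & (t < 0)
    out[seg] = _POS * (t[seg] + _T_RISE) / _T_RISE
    seg = (t >= 0) & (t < _T_FLAT)
    out[seg] = _POS
    seg = (t >= _T_FLAT) & (t < _T_FLAT + _T_CROSS)
    out[seg] = _POS + (_NEG - _POS) * (t[seg] - _T_FLAT) / _T_CROSS
    seg = (t >= _T_FLAT + _T_CROSS) & (t < 2 * _T_FLAT + _T_CROSS)
    out[seg] = _NEG
    seg = (t >= 2 * _T_FLAT + _T_CROSS) & (t < 2 * _T_FLAT + _T_CROSS + _T_RISE)
    out[seg] = _NEG * (1.0 - (t[seg] - 2 * _T_FLAT - _T_CROSS) / _T_RISE)
    return out


def _add_cmap(
    signal: np.ndarray,
    fs: float,
    onset_s: float,
    amplitude_v: float,
    latency_s: float,
) -> None:
    """Add one CMAP of given amplitude at ``onset + latency`` in place."""
    t = np.arange(signal.size) / fs
    lo = onset_s + latency_s - 2 * _T_RISE
    hi = onset_s + latency_s + 2 * _T_FLAT + _T_CROSS + 2 * _T_RISE
    idx = np.flatnonzero((t >= lo) & (t <= hi))
    signal[idx] += amplitude_v * cmap_template(t[idx] - onset_s - latency_s)


# --- trial simulation -------------------------------------------------------

def _true_threshold(cfg: PhantomConfig, d_eff: float, z: float,
                    rng: np.random.Generator) -> float:
    mt = cfg.mt_a0 * (1.0 + cfg.mt_a1 * d_eff) * (1.0 + cfg.mt_a2 / z)
    jitter = cfg.mt_jitter_rel * cfg.noise_scale
    if jitter > 0:
        mt *= float(np.exp(rng.normal(0.0, jitter)))
    return mt


def _recruit_factor(cfg: PhantomConfig, level_frac: float) -> float:
    """Amplitude multiplier at a stimulus of ``level_frac`` x MT."""
    x = level_frac - 1.0
    return 1.0 + cfg.recruit_gain * x - cfg.recruit_curv * x * x


def _sweep_recording(
    cfg: PhantomConfig,
    triggers: np.ndarray,
    amps: np.ndarray,
    lats: np.ndarray,
    rng: np.random.Generator,
) -> cf.EMGRecording:
    fs = cfg.emg_sample_rate
    duration = triggers[-1] + cfg.cmap_window_s + 0.01
    n = int(np.ceil(duration * fs))
    noise_sd = cfg.emg_noise_sd_v * cfg.noise_scale
    signal = (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n))
    for trig, amp, lat in zip(triggers, amps, lats):
        if amp > 0:
            _add_cmap(signal, fs, trig, amp, lat)
    return cf.EMGRecording(signal=signal, sample_rate=fs,
                           trigger_times=np.asarray(triggers, dtype=float))


def simulate_trial(
    subject: int,
    material: tuple,
    distance_mm: float,
    cfg: PhantomConfig,
    rng: np.random.Generator,
    rc_true: tuple[float, float, float] | None = None,
) -> tuple[FeatureRecord, dict]:
    """Simulate one (subject, material, distance) trial through the pipeline.

    Generates the impedance-measurement waveform and the per-level EMG, then
    extracts every feature with the real analysis chain (edge detection, RC
    fit, MT search, segmentation, grand averages, normalisation, linear
    model).  Returns the extracted :class:`FeatureRecord` and a ground-truth
    dict with the generative quantities.

    Raises :class:`NoResponsePossible` when the trial's true threshold
    exceeds the configured maximum current.
    """
    name = material[0]
    rs_t, rp_t, cp_t = rc_true if rc_true is not None else material[1:4]
    z_true = pi.impedance_magnitude(
        pi.TissueRC(rs=rs_t, rp=rp_t, cp=cp_t, tau=rp_t * cp_t, r_squared=1.0),
        cfg.impedance_freq_hz,
    )
    d_eff = distance_mm + cfg.d_offset_mm

    # 1. impedance measurement through the real pulse pipeline
    time, volts = simulate_pulse_response(
        rs_t, rp_t, cp_t, cfg.stim_current_a,
        duration_s=cfg.pulse_width_s, sample_rate=cfg.waveform_sample_rate,
        pre_s=cfg.pulse_pre_s, post_s=cfg.pulse_post_s,
        noise_sd_v=cfg.waveform_noise_sd_v * cfg.noise_scale, rng=rng,
    )
    pulse = pi.detect_pulse_edges(time, volts, cfg.stim_current_a)
    rc_est = pi.fit_rc_from_pulse(pulse)
    z_est = pi.impedance_magnitude(rc_est, cfg.impedance_freq_hz)

    # 2. motor threshold via the real ascending search
    mt_true = _true_threshold(cfg, d_eff, z_true, rng)
    if mt_true > cfg.mt_max_a:
        raise NoResponsePossible(
            f"true threshold {mt_true:.3e} A exceeds the maximum "
            f"{cfg.mt_max_a:.3e} A"
        )
    noise_sd = cfg.emg_noise_sd_v * cfg.noise_scale
    detect_thresh = cfg.mt_detect_factor * noise_sd

    def amp_at(current: float) -> float:
        if current < mt_true:
            return 0.0
        return cfg.lambda1 * current / (d_eff * z_true)

    trig0 = 0.02

    def stimulate(current: float) -> float:
        amp = amp_at(current)
        lat = cfg.latency_base_s + cfg.lambda2 * z_true * d_eff
        jitter = cfg.latency_jitter_sd_s * cfg.noise_scale
        if jitter > 0:
            lat = max(1e-3, lat + rng.normal(0.0, jitter))
        arel = cfg.amp_jitter_rel * cfg.noise_scale
        if arel > 0 and amp > 0:
            amp *= float(np.exp(rng.normal(0.0, arel)))
        rec = _sweep_recording(cfg, np.array([trig0]), np.array([amp]),
                               np.array([lat]), rng)
        seg = cf.segment_by_trigger(rec, cfg.cmap_window_s)[0]
        try:
            vpp, _ = cf.extract_amplitude_latency(seg, cfg.emg_sample_rate)
        except NoResponse:
            return 0.0
        return vpp

    try:
        mt = cf.find_motor_threshold(
            stimulate, cfg.mt_start_a, cfg.mt_step_a, cfg.mt_max_a,
            threshold=detect_thresh,
        )
    except ThresholdNotFound as exc:
        raise NoResponsePossible(str(exc)) from exc
    i1 = mt.i_mt
    levels = np.array(cf.LEVEL_FRACTIONS) * i1

    # 3. per-level stimulation trains and feature extraction
    amp_mt = cfg.lambda1 * i1 / (d_eff * z_true)
    lat_true = cfg.latency_base_s + cfg.lambda2 * z_true * d_eff
    vpps, lats_meas = [], []
    for frac, level in zip(cf.LEVEL_FRACTIONS, levels):
        base_amp = (amp_mt * _recruit_factor(cfg, frac)
                    if level >= mt_true else 0.0)
        triggers = trig0 + np.arange(cfg.pulses_per_level) * cfg.isi_s
        amps = np.full(cfg.pulses_per_level, base_amp)
        lats = np.full(cfg.pulses_per_level, lat_true)
        arel = cfg.amp_jitter_rel * cfg.noise_scale
        ljit = cfg.latency_jitter_sd_s * cfg.noise_scale
        if arel > 0:
            amps = amps * np.exp(rng.normal(0.0, arel, size=amps.size))
        if ljit > 0:
            lats = np.maximum(1e-3, lats + rng.normal(0.0, ljit, size=lats.size))
        rec = _sweep_recording(cfg, triggers, amps, lats, rng)
        segments = cf.segment_by_trigger(rec, cfg.cmap_window_s)
        avg = cf.grand_average(segments)
        try:
            vpp, lat = cf.extract_amplitude_latency(avg, cfg.emg_sample_rate)
        except NoResponse:
            vpp, lat = 0.0, np.nan
        vpps.append(vpp)
        lats_meas.append(lat)

    ncmap = cf.normalize_cmaps(vpps)
    theta1, theta2, lin_r2 = cf.fit_linear_nerve_model(levels, ncmap)
    t_l = float(np.nanmean(lats_meas))

    record = FeatureRecord(
        i_mt=float(i1),
        cmap_amp=float(vpps[0]),
        z=float(z_est),
        t_l=t_l,
        theta1=theta1,
        theta2=theta2,
        lin_r_squared=lin_r2,
        rs=rc_est.rs,
        rp=rc_est.rp,
        cp=rc_est.cp,
        tau_r_squared=rc_est.r_squared,
        distance_mm=float(distance_mm),
        subject=subject,
        material=name,
    )
    truth = {
        "subject": subject,
        "material": name,
        "distance_mm": float(distance_mm),
        "d_eff_mm": float(d_eff),
        "rs_true": rs_t,
        "rp_true": rp_t,
        "cp_true": cp_t,
        "z_true": float(z_true),
        "mt_true": float(mt_true),
        "i_mt_grid": float(i1),
        "amp_mt_true": float(amp_mt),
        "latency_true": float(lat_true),
    }
    return record, truth


def generate_dataset(cfg: PhantomConfig) -> PhantomDataset:
    """Full-factorial phantom dataset: subjects x materials x distances.

    Every record is produced by the real extraction pipeline applied to the
    synthetic raw signals.  Trials whose true threshold exceeds the maximum
    current are kept with a flag (their record is ``None``-free but marked)
    rather than silently dropped.  Regeneration with the same config is
    bit-identical.
    """
    ss = np.random.SeedSequence(cfg.seed)
    n_trials = cfg.n_subjects * len(cfg.materials) * len(cfg.distances_mm)
    children = ss.spawn(1 + n_trials)
    rng_rc = np.random.default_rng(children[0])

    # per (subject, material) circuit heterogeneity
    rc_table: dict[tuple[int, str], tuple[float, float, float]] = {}
    for s in range(cfg.n_subjects):
        for mat in cfg.materials:
            name, rs, rp, cp = mat
            if cfg.rc_jitter_rel > 0:
                f = np.exp(rng_rc.normal(0.0, cfg.rc_jitter_rel, size=3))
            else:
                f = np.ones(3)
            rc_table[(s, name)] = (rs * f[0], rp * f[1], cp * f[2])

    records: list[FeatureRecord] = []
    truths: list[dict] = []
    flags: list[str | None] = []
    trial = 0
    for s in range(cfg.n_subjects):
        for mat in cfg.materials:
            for d in cfg.distances_mm:
                rng = np.random.default_rng(children[1 + trial])
                trial += 1
                try:
                    rec, truth = simulate_trial(
                        s, mat, d, cfg, rng, rc_true=rc_table[(s, mat[0])]
                    )
                    flags.append(None)
                except NoResponsePossible as exc:
                    rec = None
                    truth = {"subject": s, "material": mat[0],
                             "distance_mm": float(d)}
                    flags.append(str(exc))
                records.append(rec)
                truths.append(truth)
    return PhantomDataset(config=copy.deepcopy(cfg), records=records,
                          truth=truths, flags=flags)
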
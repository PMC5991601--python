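"""Tabular I/O and run configuration.

All tables are plain CSV with SI units encoded in the column names
(``_s``, ``_V``, ``_A``, ``_ohm``, ``_F``) except distances, which are in
millimetres (``_mm``) to match clinical usage.  Feature tables round-trip
losslessly (17 significant digits).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cmap_features import EMGRecording
from .errors import MalformedInput
from .nerve_model import FeatureRecord

__all__ = [
    "RunConfig",
    "read_waveform_table",
    "read_emg_table",
    "read_feature_table",
    "write_feature_table",
    "records_to_frame",
    "frame_to_records",
]

logger = logging.getLogger("nervelocate")

WAVEFORM_COLUMNS = ("time_s", "voltage_V")
EMG_COLUMNS = ("time_s", "emg_V", "trigger")

#: Stable feature-table column order.
FEATURE_COLUMNS = (
    "subject",
    "material",
    "distance_mm",
    "i_mt_A",
    "cmap_amp_V",
    "z_ohm",
    "t_l_s",
    "theta1",
    "theta2",
    "lin_r_squared",
    "rs_ohm",
    "rp_ohm",
    "cp_F",
    "tau_r_squared",
)

_FIELD_FOR_COLUMN = {
    "subject": "subject",
    "material": "material",
    "distance_mm": "distance_mm",
    "i_mt_A": "i_mt",
    "cmap_amp_V": "cmap_amp",
    "z_ohm": "z",
    "t_l_s": "t_l",
    "theta1": "theta1",
    "theta2": "theta2",
    "lin_r_squared": "lin_r_squared",
    "rs_ohm": "rs",
    "rp_ohm": "rp",
    "cp_F": "cp",
    "tau_r_squared": "tau_r_squared",
}


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; serialises to YAML/JSON."""

    impedance_freq_hz: float = 500e3
    cmap_window_s: float = 0.05
    cmap_search_start_s: float = 0.002
    detect_factor: float = 5.0
    variant: str = "extended"
    latency_reading: str = "ratio"
    x1_imt_rp_reading: str = "ratio"
    x2_rs_cp_reading: str = "ratio"
    cv_k: int = 10
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise MalformedInput(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = open(path).read()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise MalformedInput(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith(".json"):
                json.dump(asdict(self), fh, indent=2)
            else:
                yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise MalformedInput(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedInput(f"{path}: missing required columns {missing}")
    if df.empty:
        raise MalformedInput(f"{path}: no data rows")
    return df


def read_waveform_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a pulse-response waveform CSV with ``time_s, voltage_V`` columns."""
    df = _read_csv(path, WAVEFORM_COLUMNS)
    time = df["time_s"].to_numpy(dtype=float)
    volts = df["voltage_V"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(time) | ~np.isfinite(volts))
    if bad.size:
        raise MalformedInput(f"{path}: non-finite value at data row {bad[0]}")
    nonmono = np.flatnonzero(np.diff(time) <= 0)
    if nonmono.size:
        raise MalformedInput(
            f"{path}: time not strictly increasing at data row {nonmono[0] + 1}"
        )
    return time, volts


def read_emg_table(path) -> EMGRecording:
    """Read an EMG CSV with ``time_s, emg_V, trigger`` (trigger in {0,1})."""
    df = _read_csv(path, EMG_COLUMNS)
    time = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(time) <= 0):
        raise MalformedInput(f"{path}: time not strictly increasing")
    dt = np.diff(time)
    fs = 1.0 / float(np.median(dt))
    trig = df["trigger"].to_numpy()
    if not np.isin(trig, (0, 1)).all():
        raise MalformedInput(f"{path}: trigger column must be 0/1")
    edges = np.flatnonzero(np.diff(np.concatenate([[0], trig])) == 1)
    return EMGRecording(
        signal=df["emg_V"].to_numpy(dtype=float),
        sample_rate=fs,
        trigger_times=time[edges] - time[0],
    )


def records_to_frame(records: Sequence[FeatureRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({col: getattr(r, attr) for col, attr in _FIELD_FOR_COLUMN.items()})
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[FeatureRecord]:
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col, attr in _FIELD_FOR_COLUMN.items():
            val = row[col] if col in row.index else None
            if col == "material":
                kwargs[attr] = None if pd.isna(val) else str(val)
            elif col == "subject":
                kwargs[attr] = None if pd.isna(val) else int(val)
            elif col == "distance_mm":
                kwargs[attr] = None if pd.isna(val) else float(val)
            else:
                kwargs[attr] = float(val) if val is not None else float("nan")
        records.append(FeatureRecord(**kwargs))
    return records


def write_feature_table(records: Sequence[FeatureRecord], path) -> None:
    """Write records as CSV in the stable column order (lossless floats)."""
    if not records:
        logger.warning("writing header-only feature table to %s", path)
    df = records_to_frame(records)
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> list[FeatureRecord]:
    """Read a feature CSV back into records (inverse of write)."""
    df = _read_csv(path, [c for c in FEATURE_COLUMNS if c not in ("subject", "material", "distance_mm")])
    return frame_to_records(df)
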
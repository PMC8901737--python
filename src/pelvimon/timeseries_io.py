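"""CSV + JSON-sidecar serialization of recordings and traces.

Time series are stored as plain CSV with a header row and values written to
12 significant digits; per-file metadata (object type, sampling parameters,
chain configuration snapshot, seed) lives in a JSON sidecar next to the CSV
(``<name>.json``).  Round-tripping preserves values to 12 significant
digits and all metadata.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .analog_frontend import ChainConfig, RawRecording
from .errors import ValidationError
from .lockin_demod import ImpedanceTrace
from .tissue_sim import ContractionState, TissueImpedanceTrace
from .trace_analysis import NormalizedTrace

_FLOAT_FMT = "%.12g"

Serializable = Union[RawRecording, ImpedanceTrace, NormalizedTrace]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _config_to_dict(config: ChainConfig | None) -> dict | None:
    return dataclasses.asdict(config) if config is not None else None


def write_timeseries_csv(obj: Serializable, path: str | Path) -> Path:
    """Write a recording or trace to CSV with a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, RawRecording):
        df = pd.DataFrame({"time_s": obj.time_s, "volts": obj.samples_v})
        meta = {
            "type": "RawRecording",
            "sample_rate_hz": obj.sample_rate_hz,
            "t0_s": obj.t0_s,
            "channel": obj.channel,
            "seed": obj.seed,
            "chain_filtered": obj.chain_filtered,
            "config": _config_to_dict(obj.config),
        }
    elif isinstance(obj, ImpedanceTrace):
        cols = {"time_s": obj.time_s, "U_volts": obj.U_v}
        if obj.phase_deg is not None:
            cols["phase_deg"] = obj.phase_deg
        if obj.phase_valid is not None:
            cols["phase_valid"] = obj.phase_valid.astype(int)
        if obj.artifact_mask is not None:
            cols["artifact"] = obj.artifact_mask.astype(int)
        df = pd.DataFrame(cols)
        meta = {
            "type": "ImpedanceTrace",
            "version": obj.version,
            "config": _config_to_dict(obj.config),
        }
    elif isinstance(obj, NormalizedTrace):
        cols = {"time_s": obj.time_s, "u": obj.u}
        if obj.artifact_mask is not None:
            cols["artifact"] = obj.artifact_mask.astype(int)
        df = pd.DataFrame(cols)
        meta = {
            "type": "NormalizedTrace",
            "baseline_window_s": list(obj.baseline_window_s),
            "U0_v": obj.U0_v,
            "noise_sigma": obj.noise_sigma,
        }
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def export_contraction_csv(
    state: ContractionState, z_trace: TissueImpedanceTrace, path: str | Path
) -> Path:
    """Export a contraction/impedance simulation (time_s, c, q, z_abs_ohm,
    z_phase_deg) as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "time_s": state.time_s,
            "c": state.c,
            "q": state.q,
            "z_abs_ohm": z_trace.magnitude,
            "z_phase_deg": z_trace.phase_deg,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def _read_csv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty or headerless CSV") from exc
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"{path}: malformed CSV ({exc})") from exc
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    for col in df.columns:
        if col in ("phase_valid", "artifact"):
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric value in column {col!r} at data line {bad[0] + 2}"
            )
        df[col] = vals
    return df


def read_timeseries_csv(path: str | Path) -> Serializable:
    """Read a CSV written by :func:`write_timeseries_csv`.

    A missing sidecar produces a warning and type inference from the
    columns with default metadata.
    """
    path = Path(path)
    df = _read_csv(path)
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
    else:
        warnings.warn(f"{side} missing; inferring metadata from columns", stacklevel=2)
        if "volts" in df.columns:
            meta = {"type": "RawRecording", "config": None}
        elif "U_volts" in df.columns:
            meta = {"type": "ImpedanceTrace", "version": "v2", "config": None}
        else:
            meta = {"type": "NormalizedTrace"}

    kind = meta.get("type")
    config = ChainConfig(**meta["config"]) if meta.get("config") else None
    if kind == "RawRecording":
        t = df["time_s"].to_numpy()
        fs = meta.get("sample_rate_hz") or 1.0 / (t[1] - t[0])
        return RawRecording(
            samples_v=df["volts"].to_numpy(),
            sample_rate_hz=fs,
            t0_s=meta.get("t0_s", float(t[0])),
            channel=meta.get("channel", "bladder"),
            config=config,
            seed=meta.get("seed"),
            chain_filtered=meta.get("chain_filtered", True),
        )
    if kind == "ImpedanceTrace":
        return ImpedanceTrace(
            time_s=df["time_s"].to_numpy(),
            U_v=df["U_volts"].to_numpy(),
            version=meta.get("version", "v2"),
            config=config or ChainConfig(),
            phase_deg=df["phase_deg"].to_numpy() if "phase_deg" in df else None,
            phase_valid=df["phase_valid"].to_numpy().astype(bool)
            if "phase_valid" in df
            else None,
            artifact_mask=df["artifact"].to_numpy().astype(bool)
            if "artifact" in df
            else None,
        )
    if kind == "NormalizedTrace":
        return NormalizedTrace(
            time_s=df["time_s"].to_numpy(),
            u=df["u"].to_numpy(),
            baseline_window_s=tuple(meta.get("baseline_window_s", (0.0, 0.0))),
            U0_v=meta.get("U0_v", float("nan")),
            noise_sigma=meta.get("noise_sigma", float("nan")),
            artifact_mask=df["artifact"].to_numpy().astype(bool)
            if "artifact" in df
            else None,
        )
    raise ValidationError(f"{side}: unknown object type {kind!r}")
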
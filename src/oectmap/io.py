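"""On-disk formats.

Traces are plain delimited text with ``#``-prefixed metadata header lines
(``# key: <json>``) followed by ``t,i_ds`` columns in seconds and amperes;
ground truth travels in a separate JSON sidecar so quantification cannot
accidentally read it.  Sweeps are 2-column ``v_gs,i_ds`` text (V, A);
standard-addition tables are ``concentration_nM,delta_v_mV``; device
parameters and run configs are JSON/YAML.  Every writer embeds the hash of
the configuration that produced the file when one is supplied.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .device import DeviceParams, TransferCurve
from .errors import FormatError
from .pipeline import ReleaseEstimate
from .trace import DEFAULT_DT, RecordingTrace, ReleaseEvent

__all__ = [
    "read_trace",
    "write_trace",
    "read_ground_truth",
    "write_ground_truth",
    "read_device_params",
    "write_device_params",
    "read_sweep",
    "write_sweep",
    "read_calibration_table",
    "write_calibration_table",
    "estimates_frame",
    "write_estimates",
    "read_estimates",
    "RunConfig",
    "config_hash",
]

logger = logging.getLogger("oectmap")

_FLOAT_FMT = "%.12g"  # 12 significant digits round-trip the analysis losslessly


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def write_trace(trace: RecordingTrace, path, config_hash_: str | None = None) -> None:
    path = Path(path)
    header = {
        "site_id": trace.site_id,
        "dt": trace.dt,
        "v_gs": trace.v_gs_operating,
        "v_ds": trace.v_ds,
        "stim_epochs": trace.stim_epochs,
        "meta": trace.meta,
    }
    if config_hash_:
        header["config_hash"] = config_hash_
    lines = [f"# {k}: {json.dumps(v)}" for k, v in header.items()]
    lines.append("t,i_ds")
    t = trace.times
    for ti, ii in zip(t, trace.i_ds):
        lines.append(f"{_FLOAT_FMT % ti},{_FLOAT_FMT % ii}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path) -> RecordingTrace:
    path = Path(path)
    header: dict = {}
    data_start = None
    lines = path.read_text().splitlines()
    for ln, line in enumerate(lines):
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" not in body:
                raise FormatError(f"malformed header line {line!r}", line=ln + 1)
            key, _, val = body.partition(":")
            try:
                header[key.strip()] = json.loads(val.strip())
            except json.JSONDecodeError as exc:
                raise FormatError(f"invalid JSON in header: {exc}", line=ln + 1) from exc
        elif line.strip():
            data_start = ln
            break
    if data_start is None:
        raise FormatError("trace file contains no data rows")
    if lines[data_start].strip() != "t,i_ds":
        raise FormatError(
            f"expected column header 't,i_ds', got {lines[data_start]!r}", line=data_start + 1
        )
    if "stim_epochs" not in header:
        raise FormatError("missing required header field 'stim_epochs'")
    if "dt" not in header:
        logger.warning("%s: no dt in header; defaulting to %g s", path.name, DEFAULT_DT)
    i_vals = []
    for ln, line in enumerate(lines[data_start + 1 :], start=data_start + 2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(f"expected 2 columns, got {len(parts)}", line=ln)
        try:
            i_vals.append(float(parts[1]))
        except ValueError as exc:
            raise FormatError(f"non-numeric current {parts[1]!r}", line=ln) from exc
    return RecordingTrace(
        site_id=str(header.get("site_id", path.stem)),
        i_ds=np.asarray(i_vals),
        v_gs_operating=float(header.get("v_gs", 0.0)),
        v_ds=float(header.get("v_ds", 0.0)),
        stim_epochs=[tuple(e) for e in header["stim_epochs"]],
        dt=float(header.get("dt", DEFAULT_DT)),
        meta=dict(header.get("meta", {})),
    )


def write_ground_truth(trace: RecordingTrace, path) -> None:
    events = [
        {
            "site_id": ev.site_id,
            "onset": ev.onset,
            "peak_concentration": ev.peak_concentration,
            "rise_tau": ev.rise_tau,
            "decay_tau": ev.decay_tau,
        }
        for ev in (trace.ground_truth or [])
    ]
    Path(path).write_text(json.dumps({"site_id": trace.site_id, "events": events}, indent=1))


def read_ground_truth(path) -> list[ReleaseEvent]:
    payload = json.loads(Path(path).read_text())
    return [ReleaseEvent(**ev) for ev in payload["events"]]


# ---------------------------------------------------------------------------
# device / sweep / calibration
# ---------------------------------------------------------------------------


def write_device_params(params: DeviceParams, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=1))


def read_device_params(path) -> DeviceParams:
    return DeviceParams.from_dict(json.loads(Path(path).read_text()))


def write_sweep(sweep: TransferCurve, path) -> None:
    lines = [f"# v_ds: {json.dumps(sweep.v_ds)}", f"# source: {json.dumps(sweep.source.value)}"]
    lines.append("v_gs,i_ds")
    for v, i in zip(sweep.v_gs_grid, sweep.i_ds_values):
        lines.append(f"{_FLOAT_FMT % v},{_FLOAT_FMT % i}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sweep(path) -> TransferCurve:
    path = Path(path)
    v_ds, source = 0.0, "measured"
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("#"):
            body = line[1:].strip()
            key, _, val = body.partition(":")
            if key.strip() == "v_ds":
                v_ds = float(json.loads(val))
            elif key.strip() == "source":
                source = json.loads(val)
        elif line.strip() and line.strip() != "v_gs,i_ds":
            parts = line.split(",")
            if len(parts) != 2:
                raise FormatError(f"expected 2 columns, got {len(parts)}", line=ln)
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise FormatError("sweep file contains no samples")
    arr = np.asarray(rows)
    return TransferCurve(arr[:, 0], arr[:, 1], v_ds=v_ds, source=source)


def write_calibration_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_calibration_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = {"concentration_nM", "delta_v_mV"} - set(df.columns)
    if missing:
        raise FormatError(f"calibration table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# estimates
# ---------------------------------------------------------------------------


def estimates_frame(estimates: list[ReleaseEstimate]) -> pd.DataFrame:
    rows = []
    for k, e in enumerate(estimates):
        rows.append(
            {
                "site_id": e.site_id,
                "trial": e.meta.get("trial", k),
                "stim_site": e.meta.get("stim_site", ""),
                "condition": e.meta.get("condition", ""),
                "baseline_i_A": e.baseline_i,
                "peak_i_A": e.peak_i,
                "peak_time_s": e.peak_time,
                "delta_v_mV": e.delta_v_geff * 1e3,
                "concentration_nM": e.concentration,
                "snr": e.snr,
                "below_lod": e.below_lod,
                "extrapolated": e.extrapolated,
            }
        )
    return pd.DataFrame(rows)


def write_estimates(estimates: list[ReleaseEstimate], path, config_hash_: str | None = None) -> None:
    df = estimates_frame(estimates)
    with open(path, "w") as fh:
        if config_hash_:
            fh.write(f"# config_hash: {config_hash_}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_estimates(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Global run configuration: scenario/pipeline blocks plus seed and output.

    Round-trips losslessly through YAML or JSON; every stochastic step of a
    run derives its stream from ``seed``.
    """

    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "oectmap_out"
    scenario: dict = field(default_factory=dict)
    pipeline: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "log_level": self.log_level,
            "out_dir": self.out_dir,
            "scenario": self.scenario,
            "pipeline": self.pipeline,
            "stats": self.stats,
        }

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls(**data)

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))
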
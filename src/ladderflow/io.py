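"""Trace and table I/O.

Traces are stored either as delimited text (a time column in seconds plus
one mV column per channel) or as a columnar Parquet container; a JSON
sidecar next to the trace carries the sample rate, channel names and any
provenance (seed, config hash).  Both representations round-trip float64
values exactly (text uses 17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CHANNEL_NAMES, GroundTruthCell, RawTrace

__all__ = ["write_trace", "read_trace", "write_ground_truth",
           "read_ground_truth", "sidecar_path"]


def sidecar_path(path: Path | str) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def write_trace(trace: RawTrace, path: Path | str,
                meta: dict | None = None) -> Path:
    """Write a trace as .tsv (delimited text) or .parquet (columnar)."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times_s})
    for c, name in enumerate(trace.channel_names):
        df[f"{name}_mV"] = trace.values[c]
    if path.suffix == ".tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        raise ValueError(f"unsupported trace format {path.suffix!r}")
    side = {"sample_rate_hz": trace.sample_rate_hz,
            "channel_names": list(trace.channel_names)}
    side.update(meta or {})
    sidecar_path(path).write_text(json.dumps(side, indent=1))
    return path


def read_trace(path: Path | str) -> RawTrace:
    path = Path(path)
    if path.suffix == ".tsv":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    elif path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        raise ValueError(f"unsupported trace format {path.suffix!r}")
    side = json.loads(sidecar_path(path).read_text())
    names = tuple(side.get("channel_names", CHANNEL_NAMES))
    values = np.vstack([df[f"{name}_mV"].to_numpy() for name in names])
    return RawTrace(values=values, sample_rate_hz=float(side["sample_rate_hz"]),
                    channel_names=names)


def write_ground_truth(cells: list[GroundTruthCell], path: Path | str) -> Path:
    path = Path(path)
    rows = [{
        "cell_id": i,
        "arrival_time_s": c.arrival_time_s,
        "copies_fitc": c.copies[0],
        "copies_pe": c.copies[1],
        "copies_percp": c.copies[2],
        "diameter_um": c.diameter_um,
        "velocity_um_per_ms": c.velocity_um_per_ms,
    } for i, c in enumerate(cells)]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path


def read_ground_truth(path: Path | str) -> list[GroundTruthCell]:
    df = pd.read_csv(path)
    return [
        GroundTruthCell(
            copies=(int(r.copies_fitc), int(r.copies_pe), int(r.copies_percp)),
            diameter_um=float(r.diameter_um),
            velocity_um_per_ms=float(r.velocity_um_per_ms),
            arrival_time_s=float(r.arrival_time_s),
        )
        for r in df.itertuples()
    ]
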
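"""Readers and writers for spike-time files and reports.

Spike files are plain text: one ascending timestamp in seconds per
line; blank lines and ``#`` comments are ignored. Simulated trains get
a JSON sidecar recording the generation parameters and the true
per-interval rates.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .simulate import SpikeTrain

__all__ = [
    "read_spike_times",
    "write_spike_times",
    "read_metadata_csv",
    "write_json_report",
    "to_jsonable",
]


def read_spike_times(path, source_id: Optional[str] = None) -> SpikeTrain:
    """Load a spike-time text file (seconds, ascending)."""
    path = Path(path)
    times = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                times.append(float(line))
            except ValueError as exc:
                raise ValidationError(f"{path}:{ln}: not a timestamp: {line!r}") from exc
    if len(times) < 2:
        raise ValidationError(f"{path}: fewer than 2 spike times")
    meta: dict[str, Any] = {"id": source_id or path.stem}
    sidecar = path.with_suffix(".json")
    rates = None
    if sidecar.exists():
        with open(sidecar) as fh:
            side = json.load(fh)
        meta.update(side.get("params", {}))
        if "rates_hz" in side:
            rates = np.asarray(side["rates_hz"], dtype=float)
    return SpikeTrain(times=np.asarray(times), metadata=meta, rates_hz=rates)


def write_spike_times(train: SpikeTrain, path, sidecar: bool = True) -> None:
    """Write timestamps (seconds, one per line) plus an optional JSON
    sidecar with generation parameters and true per-interval rates."""
    path = Path(path)
    with open(path, "w") as fh:
        for t in train.times:
            fh.write(f"{t:.9f}\n")
    if sidecar:
        payload: dict[str, Any] = {"params": to_jsonable(train.metadata)}
        if train.rates_hz is not None:
            payload["rates_hz"] = [round(float(r), 9) for r in train.rates_hz]
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(payload, fh)
            fh.write("\n")


def read_metadata_csv(path) -> pd.DataFrame:
    """Neuron metadata table: columns id, depth_um, spike_width_ms, label
    (extra columns pass through)."""
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValidationError(f"{path}: metadata CSV needs an 'id' column")
    return df.set_index("id")


def to_jsonable(obj: Any) -> Any:
    """Recursively convert dataclasses / numpy values for json.dump."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json_report(obj: Any, path) -> None:
    with open(path, "w") as fh:
        json.dump(to_jsonable(obj), fh, indent=2)
        fh.write("\n")
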
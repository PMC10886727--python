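"""File formats: HDF5 epoch container, CSV tables, YAML/JSON configs.

The epoch container stores one group per (subject, session, condition) cell::

    /subject0/Pre/L/data      float64 (channels, trials, samples)
    attrs: fs, time0, channel_labels (JSON), session, condition, subject_id,
           metadata (JSON)

Root attributes carry the generator seed when the file was simulated.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import h5py
import numpy as np
import yaml

from .preprocess import EpochedRecording

__all__ = ["write_epochs", "read_epochs", "sha256_file", "load_yaml", "dump_yaml"]


def write_epochs(
    path: str | Path,
    recordings: Mapping[tuple[int, str, str], EpochedRecording],
    root_attrs: dict[str, Any] | None = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for k, v in (root_attrs or {}).items():
            f.attrs[k] = v
        for (subj, session, condition), rec in recordings.items():
            grp = f.require_group(f"subject{subj}/{session}/{condition}")
            grp.create_dataset("data", data=rec.data, compression="gzip", compression_opts=1)
            grp.attrs["fs"] = rec.fs
            grp.attrs["time0"] = rec.time0
            grp.attrs["channel_labels"] = json.dumps(list(rec.channel_labels))
            grp.attrs["session"] = session
            grp.attrs["condition"] = condition
            grp.attrs["subject_id"] = subj
            grp.attrs["metadata"] = json.dumps(rec.metadata, default=_json_fallback)
    return path


def read_epochs(path: str | Path) -> dict[tuple[int, str, str], EpochedRecording]:
    out: dict[tuple[int, str, str], EpochedRecording] = {}
    with h5py.File(path, "r") as f:
        for sname, sgrp in f.items():
            if not sname.startswith("subject"):
                continue
            for session, sessgrp in sgrp.items():
                for condition, grp in sessgrp.items():
                    rec = EpochedRecording(
                        data=grp["data"][()],
                        fs=float(grp.attrs["fs"]),
                        channel_labels=tuple(json.loads(grp.attrs["channel_labels"])),
                        session=session,
                        condition=condition,
                        subject_id=int(grp.attrs["subject_id"]),
                        time0=float(grp.attrs["time0"]),
                        metadata=json.loads(grp.attrs.get("metadata", "{}")),
                    )
                    out[(rec.subject_id, session, condition)] = rec
    return out


def _json_fallback(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for block in iter(lambda: f.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def load_yaml(path: str | Path) -> dict[str, Any]:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def dump_yaml(obj: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)
    return path
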
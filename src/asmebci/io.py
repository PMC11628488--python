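"""Recording container I/O and BrainVision interchange.

The internal container is HDF5 with datasets ``/data`` (channels x samples,
float64 µV) and ``/events`` (one dataset per column) plus root attributes
(``sampling_rate``, ``channel_names``, ``run_index``, ``schema_version``).
Round trips through it are lossless.  BrainVision export writes the usual
triplet (.vhdr/.vmrk/.eeg, float32 multiplexed) for interoperability with
other toolboxes; import is read-only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .paradigm import TrialPlan
from .synthetic import Recording

__all__ = [
    "ParseError",
    "SessionManifest",
    "save_recording",
    "load_recording",
    "write_brainvision",
    "read_brainvision",
]

SCHEMA_VERSION = 1
_EVENT_COLUMNS = (
    "sample", "onset_s", "stream", "stimulus_id", "role",
    "frequency_hz", "label", "tag", "trial", "run",
)


class ParseError(IOError):
    """File is missing, truncated, or not a recognized recording."""


@dataclass
class SessionManifest:
    """Paths, plans and seeds of one simulated or recorded session."""

    paradigm: str
    run_files: list[str]
    plans: list[TrialPlan]
    master_seed: int
    sampling_rate: float
    n_stimuli_per_trial: int
    extra: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        payload = {
            "paradigm": self.paradigm,
            "run_files": self.run_files,
            "plans": [asdict(p) for p in self.plans],
            "master_seed": self.master_seed,
            "sampling_rate": self.sampling_rate,
            "n_stimuli_per_trial": self.n_stimuli_per_trial,
            "extra": self.extra,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @staticmethod
    def load(path: str | Path) -> "SessionManifest":
        raw = json.loads(Path(path).read_text())
        raw["plans"] = [TrialPlan(**p) for p in raw["plans"]]
        return SessionManifest(**raw)


def save_recording(rec: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        g = f.create_group("events")
        for col in rec.events.columns:
            vals = rec.events[col].to_numpy()
            if vals.dtype.kind in ("O", "U"):
                g.create_dataset(col, data=np.array(vals, dtype=h5py.string_dtype()))
            else:
                g.create_dataset(col, data=vals)
        g.attrs["columns"] = json.dumps(list(rec.events.columns))
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["channel_names"] = json.dumps(list(rec.channel_names))
        f.attrs["run_index"] = rec.run_index


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        with h5py.File(path, "r") as f:
            if "data" not in f or "events" not in f:
                raise ParseError(f"{path} is not a recording container")
            data = f["data"][()]
            cols = json.loads(f["events"].attrs["columns"])
            events = {}
            for col in cols:
                vals = f["events"][col][()]
                if vals.dtype.kind in ("S", "O"):
                    vals = np.array([v.decode() for v in vals])
                events[col] = vals
            rec = Recording(
                data=data,
                sampling_rate=float(f.attrs["sampling_rate"]),
                channel_names=tuple(json.loads(f.attrs["channel_names"])),
                events=pd.DataFrame(events, columns=cols),
                run_index=int(f.attrs["run_index"]),
            )
    except (OSError, KeyError) as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    return rec


def write_brainvision(rec: Recording, basename: str | Path) -> tuple[Path, Path, Path]:
    """Export as BrainVision triplet (float32 multiplexed, unit µV)."""
    base = Path(basename)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    n_ch = len(rec.channel_names)
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / rec.sampling_rate:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(rec.channel_names, start=1):
        lines.append(f"Ch{i}={ch},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    for i, (_, ev) in enumerate(rec.events.iterrows(), start=2):
        mlines.append(
            f"Mk{i}=Stimulus,{ev['stimulus_id']},{int(ev['sample']) + 1},1,0"
        )
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    rec.data.T.astype("<f4").tofile(eeg)
    return vhdr, vmrk, eeg


def read_brainvision(vhdr_path: str | Path) -> Recording:
    """Minimal read-only BrainVision import (float32/int16 multiplexed)."""
    vhdr_path = Path(vhdr_path)
    if not vhdr_path.exists():
        raise ParseError(f"no such file: {vhdr_path}")
    kv: dict[str, str] = {}
    channels: list[str] = []
    for line in vhdr_path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if "=" in line and not line.startswith(";"):
            key, val = line.split("=", 1)
            if key.startswith("Ch") and key[2:].isdigit():
                channels.append(val.split(",")[0])
            else:
                kv[key] = val
    try:
        fs = 1e6 / float(kv["SamplingInterval"])
        n_ch = int(kv["NumberOfChannels"])
        data_file = vhdr_path.parent / kv["DataFile"]
        fmt = kv.get("BinaryFormat", "IEEE_FLOAT_32")
    except KeyError as exc:
        raise ParseError(f"malformed header {vhdr_path}: missing {exc}") from exc
    if len(channels) != n_ch:
        raise ParseError("channel list does not match NumberOfChannels")
    dtype = {"IEEE_FLOAT_32": "<f4", "INT_16": "<i2"}.get(fmt)
    if dtype is None:
        raise ParseError(f"unsupported BinaryFormat {fmt}")
    raw = np.fromfile(data_file, dtype=dtype)
    if raw.size % n_ch:
        raise ParseError(f"{data_file} is truncated")
    data = raw.reshape(-1, n_ch).T.astype(float)

    samples, stim_ids = [], []
    vmrk = vhdr_path.parent / kv.get("MarkerFile", "")
    if vmrk.exists():
        for line in vmrk.read_text(encoding="utf-8").splitlines():
            if line.startswith("Mk") and "=" in line:
                parts = line.split("=", 1)[1].split(",")
                if parts[0] == "Stimulus":
                    stim_ids.append(parts[1])
                    samples.append(int(parts[2]) - 1)
    events = pd.DataFrame({"sample": samples, "stimulus_id": stim_ids})
    return Recording(
        data=data,
        sampling_rate=fs,
        channel_names=tuple(channels),
        events=events,
    )
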
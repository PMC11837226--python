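"""Shared domain types and seeding utilities.

Conventions used throughout the package:

* image coordinates — origin top-left, y increases downward;
* frame rate is an explicit parameter everywhere (default 40 fps);
* flaring labels are integers 0 = none, 1 = partial, 2 = full;
* binary flaring means label != 0 (partial and full both count).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FLARE_CLASSES = ("none", "partial", "full")
FLARE_NONE, FLARE_PARTIAL, FLARE_FULL = 0, 1, 2

DEFAULT_FRAME_RATE = 40.0

_MASK64 = (1 << 64) - 1


def subseed(master: int, *indices: int) -> int:
    """Derive a deterministic sub-seed from a master seed and an index path.

    A splitmix64-style mixer: stable across platforms and documented so
    that per-fish / per-stage seeds can be reproduced from run metadata.
    """
    x = (int(master) ^ 0x9E3779B97F4A7C15) & _MASK64
    for idx in indices:
        x = (x + 0x9E3779B97F4A7C15 + int(idx)) & _MASK64
        x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
        x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
        x = x ^ (x >> 31)
    return x & _MASK64


@dataclass
class FeatureSeries:
    """Multichannel per-frame kinematic features at a fixed frame rate.

    ``data`` holds one column per channel, one row per frame.  ``units``
    maps channel name -> unit string; ``meta`` carries free-form metadata
    (e.g. smoothing window) that is written to the JSON sidecar.
    """

    data: pd.DataFrame
    frame_rate: float = DEFAULT_FRAME_RATE
    units: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def to_csv(self, path, sidecar: bool = True) -> None:
        path = Path(path)
        self.data.to_csv(path, index_label="frame")
        if sidecar:
            side = {
                "frame_rate": self.frame_rate,
                "units": self.units,
                "meta": self.meta,
            }
            path.with_suffix(".json").write_text(json.dumps(side, indent=2))

    @classmethod
    def from_csv(cls, path) -> "FeatureSeries":
        path = Path(path)
        data = pd.read_csv(path, index_col="frame")
        frame_rate, units, meta = DEFAULT_FRAME_RATE, {}, {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            side = json.loads(sidecar.read_text())
            frame_rate = side.get("frame_rate", DEFAULT_FRAME_RATE)
            units = side.get("units", {})
            meta = side.get("meta", {})
        return cls(data=data.reset_index(drop=True), frame_rate=frame_rate,
                   units=units, meta=meta)


@dataclass
class Ethogram:
    """Per-frame 3-class flaring labels plus the derived binary series."""

    labels: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    provenance: str = "manual"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D sequence")
        if self.labels.size and not np.isin(self.labels, [0, 1, 2]).all():
            raise ValueError("labels must be in {0 (none), 1 (partial), 2 (full)}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.provenance not in ("manual", "predicted", "simulated"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def binary(self) -> np.ndarray:
        """Combined flaring indicator: partial and full both count."""
        return (self.labels != FLARE_NONE).astype(np.int8)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "frame": np.arange(len(self)),
            "label": [FLARE_CLASSES[i] for i in self.labels],
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_rate: float = DEFAULT_FRAME_RATE,
                 provenance: str = "manual") -> "Ethogram":
        df = pd.read_csv(path)
        name_to_id = {n: i for i, n in enumerate(FLARE_CLASSES)}
        labels = np.array([name_to_id[str(v)] for v in df["label"]], dtype=np.int8)
        return cls(labels=labels, frame_rate=frame_rate, provenance=provenance)

    def to_events(self) -> pd.DataFrame:
        """Convert to an event log (time_s, behavior, status START/STOP)."""
        rows = []
        lab = self.labels
        for cls_id in (FLARE_PARTIAL, FLARE_FULL):
            on = (lab == cls_id).astype(np.int8)
            d = np.diff(on, prepend=0, append=0)
            starts = np.flatnonzero(d == 1)
            stops = np.flatnonzero(d == -1)
            for s, e in zip(starts, stops):
                rows.append((s / self.frame_rate, FLARE_CLASSES[cls_id], "START"))
                rows.append((e / self.frame_rate, FLARE_CLASSES[cls_id], "STOP"))
        df = pd.DataFrame(rows, columns=["time_s", "behavior", "status"])
        return df.sort_values(["time_s", "status"], kind="stable").reset_index(drop=True)

    @classmethod
    def from_events(cls, events: pd.DataFrame, n_frames: int,
                    frame_rate: float = DEFAULT_FRAME_RATE,
                    provenance: str = "manual") -> "Ethogram":
        labels = np.zeros(n_frames, dtype=np.int8)
        name_to_id = {n: i for i, n in enumerate(FLARE_CLASSES)}
        for behavior, grp in events.groupby("behavior"):
            cls_id = name_to_id[str(behavior)]
            if cls_id == FLARE_NONE:
                continue
            starts = grp.loc[grp["status"] == "START", "time_s"].to_numpy()
            stops = grp.loc[grp["status"] == "STOP", "time_s"].to_numpy()
            for s, e in zip(np.sort(starts), np.sort(stops)):
                i0 = int(round(s * frame_rate))
                i1 = int(round(e * frame_rate))
                labels[max(i0, 0):min(i1, n_frames)] = cls_id
        return cls(labels=labels, frame_rate=frame_rate, provenance=provenance)
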
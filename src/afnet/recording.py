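"""Multichannel electrogram container and delimited-text I/O.

A recording is a samples x channels voltage matrix plus sampling rate and
channel labels.  Files are plain TSV with a header row of channel labels;
a YAML sidecar carries sampling rate, seed and (for synthetic data) the
planted truth adjacency as an edge list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class MultiChannelRecording:
    """Samples x channels voltage matrix with sampling rate and labels."""

    data: np.ndarray
    fs_hz: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D samples x channels matrix")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite values")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("label count does not match channel count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel(self, label: str) -> np.ndarray:
        return self.data[:, self.labels.index(label)]

    def copy(self) -> "MultiChannelRecording":
        return MultiChannelRecording(self.data.copy(), self.fs_hz, list(self.labels))


def write_recording(
    rec: MultiChannelRecording,
    path: str | Path,
    *,
    metadata: dict | None = None,
) -> None:
    """Write a recording as TSV (header = labels) plus a ``.meta.yaml`` sidecar."""
    path = Path(path)
    header = "\t".join(rec.labels)
    np.savetxt(path, rec.data, delimiter="\t", header=header, comments="")
    meta = {"fs_hz": float(rec.fs_hz), "labels": list(rec.labels)}
    if metadata:
        meta.update(metadata)
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))


def read_recording(path: str | Path, fs_hz: float | None = None) -> MultiChannelRecording:
    """Read a TSV recording; sampling rate from the sidecar unless given."""
    path = Path(path)
    with open(path) as fh:
        labels = fh.readline().strip().split("\t")
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if fs_hz is None:
        sidecar = path.with_suffix(path.suffix + ".meta.yaml")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no sampling rate given and no sidecar found at {sidecar}"
            )
        meta = yaml.safe_load(sidecar.read_text())
        fs_hz = float(meta["fs_hz"])
    return MultiChannelRecording(data, fs_hz, labels)
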
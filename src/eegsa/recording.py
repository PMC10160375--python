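"""The raw multi-channel EEG recording container and its plain-text I/O.

A recording is a set of equally long amplitude series (µV), one per
channel, each channel tagged with a scalp region code: frontal (F),
central (C), parietal (P), temporal (T) or occipital (O).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REGIONS = ("F", "C", "P", "T", "O")

#: Group labels for the binary situation-awareness state.
GROUPS = ("high", "low")


@dataclass
class ArtifactEvent:
    """One injected high-amplitude transient (bookkeeping for validation)."""

    channel: int
    start_s: float
    duration_s: float
    peak_uv: float


@dataclass
class RawRecording:
    """Multi-channel amplitude series with region labels.

    Parameters
    ----------
    subject_id
        Unique subject identifier.
    channels
        Sequence of ``(label, region)`` pairs; region must be one of
        :data:`REGIONS`.
    sampling_rate
        Sampling frequency in Hz.
    data
        Array of shape ``(n_channels, n_samples)`` in µV.
    group
        Optional situation-awareness group label, ``"high"`` or ``"low"``.
    artifacts
        Log of injected artifact events (synthetic recordings only).
    """

    subject_id: str
    channels: list[tuple[str, str]]
    sampling_rate: float
    data: np.ndarray
    group: str | None = None
    artifacts: list[ArtifactEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.channels)} channels"
            )
        for label, region in self.channels:
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r} for channel {label!r}")
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def region_channels(self, region: str) -> list[int]:
        """Indices of the channels belonging to ``region``."""
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return [i for i, (_, r) in enumerate(self.channels) if r == region]

    @property
    def regions(self) -> list[str]:
        """Region codes present, in first-appearance order."""
        seen: list[str] = []
        for _, r in self.channels:
            if r not in seen:
                seen.append(r)
        return seen

    def copy_with(self, data: np.ndarray) -> "RawRecording":
        """A copy of this recording carrying new sample data."""
        return RawRecording(
            subject_id=self.subject_id,
            channels=list(self.channels),
            sampling_rate=self.sampling_rate,
            data=np.array(data, dtype=float),
            group=self.group,
            artifacts=list(self.artifacts),
        )


def write_csv(rec: RawRecording, path: str | Path) -> None:
    """Serialize a recording as CSV: first column time (s), then one column
    per channel with header ``label@region``."""
    t = np.arange(rec.n_samples) / rec.sampling_rate
    cols = {"time": t}
    for i, (label, region) in enumerate(rec.channels):
        cols[f"{label}@{region}"] = rec.data[i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def read_csv(
    path: str | Path,
    subject_id: str | None = None,
    group: str | None = None,
) -> RawRecording:
    """Load a recording from the CSV dialect written by :func:`write_csv`.

    The sampling rate is inferred from the time column, which must be
    uniformly spaced.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("recording CSV needs a time column and >=1 channel")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("time column must have >= 2 samples")
    # endpoints average out per-row rounding of the written timestamps
    dt = (t[-1] - t[0]) / (len(t) - 1)
    if dt <= 0 or not np.allclose(np.diff(t), dt, atol=max(1e-5, 1e-3 * dt)):
        raise ValueError("time column must be uniformly spaced")
    fs = round(1.0 / dt, 3)
    channels: list[tuple[str, str]] = []
    for col in df.columns[1:]:
        label, sep, region = col.partition("@")
        if not sep:
            raise ValueError(f"channel header {col!r} is not 'label@region'")
        channels.append((label, region))
    data = df.iloc[:, 1:].to_numpy(dtype=float).T
    if subject_id is None:
        subject_id = Path(path).stem
    return RawRecording(
        subject_id=subject_id,
        channels=channels,
        sampling_rate=float(fs),
        data=data,
        group=group,
    )
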
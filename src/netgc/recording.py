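"""Sensor-space recordings and their on-disk representation.

A :class:`SensorRecording` is the common currency between the synthetic
generator, the preprocessing chain and the connectivity inference: a
channels x samples array with a sampling rate and subject/visit/group/
lesion metadata.  Recordings are serialized as HDF5 (datasets ``data``,
``fs``, ``channel_names``; subject metadata as root attributes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

__all__ = ["SensorRecording", "write_recording", "read_recording", "from_fif"]


@dataclass
class SensorRecording:
    """Multichannel sensor time series with acquisition metadata.

    Parameters
    ----------
    data
        Array of shape (n_channels, n_samples), sensor units.
    fs
        Sampling rate in Hz.
    subject_id
        Subject identifier, e.g. ``"patient_01"`` or ``"control_02"``.
    visit
        Visit index (1-based).
    group
        ``"patient"`` or ``"control"``.
    lesion_hemisphere
        ``"left"`` / ``"right"`` for patients, ``None`` for controls.
    channel_names
        Optional channel labels; defaults to ``MEG 000 ...``.
    """

    data: np.ndarray
    fs: float
    subject_id: str = "unknown"
    visit: int = 1
    group: str = "unknown"
    lesion_hemisphere: str | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"MEG {i:03d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "SensorRecording":
        """Return a copy with selected fields replaced (data is copied)."""
        out = replace(self, **kwargs)
        if "data" not in kwargs:
            out.data = self.data.copy()
        out.channel_names = list(out.channel_names)
        return out


def write_recording(path: str | Path, rec: SensorRecording) -> None:
    """Write a recording to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset(
            "channel_names",
            data=np.array(rec.channel_names, dtype=h5py.string_dtype()),
        )
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["visit"] = int(rec.visit)
        f.attrs["group"] = rec.group
        f.attrs["lesion_hemisphere"] = (
            rec.lesion_hemisphere if rec.lesion_hemisphere is not None else "none"
        )


def read_recording(path: str | Path) -> SensorRecording:
    """Read a recording written by :func:`write_recording`."""
    with h5py.File(path, "r") as f:
        lesion = str(f.attrs["lesion_hemisphere"])
        return SensorRecording(
            data=f["data"][()],
            fs=float(f["fs"][()]),
            channel_names=[s.decode() if isinstance(s, bytes) else str(s)
                           for s in f["channel_names"][()]],
            subject_id=str(f.attrs["subject_id"]),
            visit=int(f.attrs["visit"]),
            group=str(f.attrs["group"]),
            lesion_hemisphere=None if lesion == "none" else lesion,
        )


def from_fif(path: str | Path, **metadata) -> SensorRecording:
    """Adapter: load an MEG FIF file into the in-memory recording contract.

    Requires the optional ``mne`` dependency.  Only the data array, sampling
    rate and channel names are taken from the file; study metadata (subject,
    visit, group, lesion side) is supplied by the caller.
    """
    import mne  # optional dependency, imported lazily

    raw = mne.io.read_raw_fif(str(path), preload=True, verbose="error")
    return SensorRecording(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        **metadata,
    )
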
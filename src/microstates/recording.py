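"""The :class:`Recording` container and plain-text / EDF input-output.

A recording is a channels × samples potential matrix (µV) with channel
labels, a sampling rate, subject/session identity and epoch bookkeeping.
Epochs are stored as half-open ``(start, stop)`` sample intervals into the
(possibly concatenated) data matrix; they become discontinuous after
artifact rejection, which is why all peak picking downstream is done
within epochs only.

Delimited recordings are tab-separated: a single ``#``-prefixed JSON
metadata line, a channel-label header, then one row per sample.  EDF files
are read through MNE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Recording", "read_delimited", "write_delimited", "read_edf"]


@dataclass
class Recording:
    data: np.ndarray  # (n_channels, n_samples), µV
    channel_labels: tuple[str, ...]
    sampling_rate: float
    subject_id: str = "S01"
    session_id: str = "ses1"
    epochs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels × samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("row count must match number of channel labels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.epochs:
            self.epochs = [(0, self.data.shape[1])]
        prev = 0
        for start, stop in self.epochs:
            if not (prev <= start < stop <= self.data.shape[1]):
                raise ValueError(f"bad epoch bounds ({start}, {stop})")
            prev = stop

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        """Total retained duration in seconds (sum of epoch lengths)."""
        return sum(stop - start for start, stop in self.epochs) / self.sampling_rate

    def with_data(self, data: np.ndarray, **changes) -> "Recording":
        """Copy with new data (and optionally other fields) re-validated."""
        return replace(self, data=data, **changes)

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(), epochs=list(self.epochs))


def write_delimited(recording: Recording, path: "str | Path") -> None:
    path = Path(path)
    meta = {
        "sampling_rate": recording.sampling_rate,
        "subject_id": recording.subject_id,
        "session_id": recording.session_id,
        "epochs": [list(e) for e in recording.epochs],
    }
    with path.open("w") as fh:
        fh.write("#" + json.dumps(meta) + "\n")
        fh.write("\t".join(recording.channel_labels) + "\n")
        np.savetxt(fh, recording.data.T, fmt="%.6f", delimiter="\t")


def read_delimited(path: "str | Path") -> Recording:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing metadata line")
        meta = json.loads(first[1:])
        labels = tuple(fh.readline().strip().split("\t"))
        data = np.loadtxt(fh, delimiter="\t", ndmin=2).T
    return Recording(
        data=data,
        channel_labels=labels,
        sampling_rate=float(meta["sampling_rate"]),
        subject_id=str(meta.get("subject_id", "S01")),
        session_id=str(meta.get("session_id", "ses1")),
        epochs=[tuple(e) for e in meta.get("epochs", [])],
    )


def read_edf(path: "str | Path", subject_id: str = "S01",
             session_id: str = "ses1") -> Recording:
    """Read an EDF file into a :class:`Recording` (potentials in µV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads volts
    return Recording(
        data=data,
        channel_labels=tuple(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        subject_id=subject_id,
        session_id=session_id,
    )
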
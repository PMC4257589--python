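"""Electrode montages of the 10-20/10-10 system.

The package works with three nested montages: a 30-channel analysis set
(a 32-channel cap minus the reference and ground electrodes), a standard
19-channel clinical subset, and a minimal 8-channel subset.  Each channel
carries a fixed 2-D position obtained by azimuthal-equidistant projection
of its standard scalp coordinate onto the horizontal plane (x = right,
y = anterior, vertex near the origin, unit radius ≈ the 10-20 head
circumference line).  The 2-D positions are used by the synthetic-data
generator to build spatially smooth topographies and noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Montage",
    "CHANNELS_30",
    "CHANNELS_19",
    "CHANNELS_8",
    "get_montage",
]

# Azimuthal-equidistant 2-D projection of standard 10-10 positions.
_COORDS_2D: dict[str, tuple[float, float]] = {
    "AF3": (-0.314, +0.858),
    "AF4": (+0.309, +0.856),
    "F7": (-0.858, +0.730),
    "F3": (-0.444, +0.617),
    "Fz": (-0.006, +0.583),
    "F4": (+0.442, +0.631),
    "F8": (+0.851, +0.740),
    "FC5": (-0.793, +0.373),
    "FC1": (-0.262, +0.330),
    "FC2": (+0.255, +0.338),
    "FC6": (+0.789, +0.384),
    "T7": (-1.124, +0.029),
    "C3": (-0.548, +0.054),
    "Cz": (-0.004, +0.062),
    "C4": (+0.550, +0.061),
    "T8": (+1.126, +0.043),
    "CP5": (-0.782, -0.275),
    "CP1": (-0.253, -0.201),
    "CP2": (+0.260, -0.201),
    "CP6": (+0.786, -0.267),
    "P7": (-0.854, -0.642),
    "P3": (-0.438, -0.491),
    "Pz": (-0.005, -0.444),
    "P4": (+0.439, -0.485),
    "P8": (+0.851, -0.649),
    "PO3": (-0.330, -0.727),
    "PO4": (+0.318, -0.736),
    "O1": (-0.305, -0.943),
    "O2": (+0.291, -0.948),
    "Oz": (-0.009, -0.953),
}

CHANNELS_30: tuple[str, ...] = tuple(_COORDS_2D)

CHANNELS_19: tuple[str, ...] = (
    "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "C4",
    "T8", "Cz", "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)

CHANNELS_8: tuple[str, ...] = ("F3", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4")

_BY_SIZE = {30: CHANNELS_30, 19: CHANNELS_19, 8: CHANNELS_8}


@dataclass(frozen=True)
class Montage:
    """A named electrode set with 2-D schematic positions."""

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)  # (n_channels, 2)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("channel labels must be unique")
        if self.positions.shape != (len(self.labels), 2):
            raise ValueError("positions must be (n_channels, 2)")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index_of(self, labels: "list[str] | tuple[str, ...]") -> np.ndarray:
        """Indices of *labels* within this montage, in the given order."""
        lut = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.array([lut[lab] for lab in labels], dtype=int)
        except KeyError as err:
            raise KeyError(f"channel {err.args[0]!r} not in montage") from None


def get_montage(spec: "int | list[str] | tuple[str, ...]") -> Montage:
    """Build a :class:`Montage` from a size (30, 19 or 8) or explicit labels.

    Raises
    ------
    KeyError
        If a requested label has no built-in 2-D coordinate.
    ValueError
        If an integer spec is not one of the supported montage sizes.
    """
    if isinstance(spec, int):
        try:
            labels = _BY_SIZE[spec]
        except KeyError:
            raise ValueError(
                f"unsupported montage size {spec}; choose from {sorted(_BY_SIZE)}"
            ) from None
    else:
        labels = tuple(spec)
    missing = [lab for lab in labels if lab not in _COORDS_2D]
    if missing:
        raise KeyError(f"no built-in coordinates for channel(s) {missing}")
    pos = np.array([_COORDS_2D[lab] for lab in labels], dtype=float)
    return Montage(labels=labels, positions=pos)
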
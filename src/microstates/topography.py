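"""Topographic primitives: GFP, GFP peaks, spatial correlation, GMD.

Global field power (GFP) is the spatial standard deviation of an
average-referenced potential map — the root mean square of the channel
values after removing the per-sample channel mean.  Local maxima of the
GFP time course mark the instants of highest topographic signal-to-noise;
the maps at those instants ("original maps") are the inputs to all
clustering and back-fitting.

Resting-state microstate topographies are polarity-invariant: a map and
its negation represent the same microstate, so cluster assignment and
back-fitting use the absolute spatial correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import Recording

__all__ = [
    "gfp",
    "gfp_series",
    "local_gfp_maxima",
    "find_gfp_peaks",
    "spatial_correlation",
    "abs_correlation",
    "gfp_normalize",
    "gmd",
    "PeakSet",
]


def gfp(values: np.ndarray) -> "float | np.ndarray":
    """Global field power: spatial SD across electrodes.

    *values* is a single map ``(n_channels,)`` → scalar, or a matrix
    ``(n_channels, n_samples)`` → per-sample vector.  At least two
    electrodes are required.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim not in (1, 2) or values.shape[0] < 2:
        raise ValueError("need a (n_channels,) or (n_channels, n_samples) "
                         "array with >= 2 electrodes")
    centered = values - values.mean(axis=0, keepdims=values.ndim == 2)
    out = np.sqrt(np.mean(centered**2, axis=0))
    return float(out) if values.ndim == 1 else out


def gfp_series(recording: Recording) -> np.ndarray:
    """Per-sample GFP of a recording (µV)."""
    return gfp(recording.data)


def local_gfp_maxima(values: np.ndarray,
                     epochs: "list[tuple[int, int]] | None" = None) -> np.ndarray:
    """Indices of strict local maxima, evaluated within each epoch.

    A sample is a peak iff it is strictly greater than both neighbours;
    epoch-edge samples and plateau members are never peaks.
    """
    values = np.asarray(values, dtype=float)
    if epochs is None:
        epochs = [(0, len(values))]
    out: list[np.ndarray] = []
    for start, stop in epochs:
        seg = values[start:stop]
        if len(seg) < 3:
            continue
        inner = np.flatnonzero((seg[1:-1] > seg[:-2]) & (seg[1:-1] > seg[2:]))
        out.append(inner + start + 1)
    if not out:
        return np.array([], dtype=int)
    return np.concatenate(out)


@dataclass
class PeakSet:
    """Original maps: topographies sampled at local GFP maxima."""

    maps: np.ndarray  # (n_peaks, n_channels)
    sample_indices: np.ndarray  # into the source recording's data
    gfp_values: np.ndarray
    epoch_index: np.ndarray  # which epoch each peak belongs to
    channel_labels: tuple[str, ...]
    sampling_rate: float
    subject_id: str = "S01"
    session_id: str = "ses1"
    epochs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.sample_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def n_peaks(self) -> int:
        return len(self.sample_indices)

    @property
    def times_ms(self) -> np.ndarray:
        return self.sample_indices / self.sampling_rate * 1000.0

    def to_frame(self) -> pd.DataFrame:
        """Delimited-table view: one row per peak, electrodes as columns."""
        base = pd.DataFrame({
            "subject": self.subject_id,
            "session": self.session_id,
            "sample_index": self.sample_indices,
            "time_ms": self.times_ms,
            "gfp": self.gfp_values,
            "epoch": self.epoch_index,
        })
        values = pd.DataFrame(self.maps, columns=list(self.channel_labels))
        return pd.concat([base, values], axis=1)


def find_gfp_peaks(recording: Recording) -> PeakSet:
    """Extract original maps at strict local GFP maxima, per epoch."""
    series = gfp_series(recording)
    idx = local_gfp_maxima(series, recording.epochs)
    starts = np.array([s for s, _ in recording.epochs])
    epoch_ix = np.searchsorted(starts, idx, side="right") - 1
    return PeakSet(
        maps=recording.data[:, idx].T.copy(),
        sample_indices=idx,
        gfp_values=series[idx],
        epoch_index=epoch_ix,
        channel_labels=recording.channel_labels,
        sampling_rate=recording.sampling_rate,
        subject_id=recording.subject_id,
        session_id=recording.session_id,
        epochs=list(recording.epochs),
    )


def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation between two maps across electrodes.

    For average-referenced maps this equals the cosine of the angle
    between the two potential vectors.  Maps are mean-centered here
    regardless, so non-referenced inputs are handled identically.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("maps must be 1-D and share a montage")
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.linalg.norm(uc)
    nv = np.linalg.norm(vc)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("spatial correlation undefined for a constant map")
    return float(np.clip(uc @ vc / (nu * nv), -1.0, 1.0))


def abs_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Polarity-invariant spatial correlation |r| ∈ [0, 1]."""
    return abs(spatial_correlation(u, v))


def gfp_normalize(values: np.ndarray) -> np.ndarray:
    """Return the zero-mean, unit-GFP version of a map."""
    values = np.asarray(values, dtype=float)
    centered = values - values.mean()
    power = gfp(centered)
    if power == 0.0:
        raise ValueError("cannot GFP-normalize a constant map")
    return centered / power


def _check_normalized(values: np.ndarray, tol: float = 1e-6) -> None:
    if abs(float(np.mean(values))) > tol or abs(gfp(values) - 1.0) > tol:
        raise ValueError("gmd requires GFP-normalized (zero-mean, unit-GFP) maps")


def gmd(u: np.ndarray, v: np.ndarray) -> float:
    """Global map dissimilarity between two GFP-normalized maps.

    GMD = sqrt(mean_i (u_i − v_i)²) ∈ [0, 2]; identical maps give 0,
    antipodal maps give 2.  Related to the spatial correlation C by
    GMD = sqrt(2·(1 − C)).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("maps must be 1-D and share a montage")
    _check_normalized(u)
    _check_normalized(v)
    return float(np.sqrt(np.mean((u - v) ** 2)))
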
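"""Back-fitting and feature extraction from the microstate time series.

Back-fitting labels every original map (GFP-peak topography) with the
template of highest absolute spatial correlation.  Runs of identically
labeled peaks form segments whose boundaries lie at the temporal midpoint
between the last peak of one run and the first peak of the next; the
first and last segments of each epoch are truncated at the epoch edges
and flagged as such.

Three features summarize the resulting sequence per class:
mean lifespan (ms), frequency of appearance (segments per second) and
coverage (fraction of total time).  With truncated segments included —
the default — the three are mutually consistent:
coverage = frequency × mean lifespan for every class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import MapSet, _normalize_rows
from .topography import PeakSet

__all__ = [
    "MicrostateSequence",
    "backfit",
    "build_segments",
    "extract_features",
    "features_for_recording",
]

logger = logging.getLogger(__name__)


@dataclass
class MicrostateSequence:
    """Per-peak class labels with times, from back-fitting one recording."""

    class_index: np.ndarray  # per peak
    correlation: np.ndarray  # |r| to the winning template
    class_names: tuple[str, ...]
    sample_indices: np.ndarray
    epoch_index: np.ndarray
    epochs: list[tuple[int, int]]
    sampling_rate: float
    subject_id: str
    session_id: str

    @property
    def times_ms(self) -> np.ndarray:
        return self.sample_indices / self.sampling_rate * 1000.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject": self.subject_id,
            "session": self.session_id,
            "sample_index": self.sample_indices,
            "time_ms": self.times_ms,
            "epoch": self.epoch_index,
            "class": [self.class_names[i] for i in self.class_index],
            "correlation": self.correlation,
        })


def _smooth_labels(labels: np.ndarray, corr2: np.ndarray,
                   epoch_index: np.ndarray, weight: float, window: int,
                   max_iter: int = 20) -> np.ndarray:
    """Besag-style relabeling of the peak sequence.

    Each peak's class score is its squared correlation to the template
    plus *weight* per same-labeled neighbour within ±*window* peaks of
    the same epoch; labels are updated simultaneously until stable.
    Isolated low-confidence flips get absorbed by their neighbourhood,
    while high-confidence labels are untouched.
    """
    lab = labels.copy()
    n = len(lab)
    for _ in range(max_iter):
        score = corr2.copy()
        for off in range(-window, window + 1):
            if off == 0:
                continue
            src = np.arange(n) + off
            valid = (src >= 0) & (src < n)
            same = valid.copy()
            same[valid] &= epoch_index[src[valid]] == epoch_index[valid]
            rows = np.flatnonzero(same)
            score[rows, lab[src[rows]]] += weight
        new = np.argmax(score, axis=1)
        if np.array_equal(new, lab):
            break
        lab = new
    return lab


def backfit(peakset: PeakSet, mapset: MapSet, smoothing_weight: float = 0.2,
            smoothing_window: int = 1) -> MicrostateSequence:
    """Assign each original map to the template of highest |correlation|.

    Ties break toward the first label in the map set's label order
    (A < B < C < D); tie counts are logged.  A light statistical
    smoothing of the label sequence (correlation² plus
    ``smoothing_weight`` per agreeing neighbour within
    ±``smoothing_window`` peaks) is applied by default; pass
    ``smoothing_weight=0`` for raw winner-take-all labels.
    """
    if peakset.n_peaks == 0:
        raise ValueError("cannot backfit an empty peak set")
    if mapset.maps.shape[1] != peakset.maps.shape[1]:
        raise ValueError("peak set and map set montages differ")
    X = _normalize_rows(peakset.maps)
    T = _normalize_rows(mapset.maps)
    corr = np.abs(X @ T.T) / X.shape[1]
    winner = np.argmax(corr, axis=1)  # first occurrence wins ties
    best = corr[np.arange(len(winner)), winner]
    n_ties = int(np.sum((corr >= best[:, None] - 1e-12).sum(axis=1) > 1))
    if n_ties:
        logger.info("backfit: %d of %d peaks had tied correlations "
                    "(broken by label order)", n_ties, peakset.n_peaks)
    if smoothing_weight > 0 and peakset.n_peaks > 1:
        winner = _smooth_labels(winner, corr**2, peakset.epoch_index,
                                smoothing_weight, smoothing_window)
        best = corr[np.arange(len(winner)), winner]
    return MicrostateSequence(
        class_index=winner, correlation=best,
        class_names=tuple(mapset.labels),
        sample_indices=peakset.sample_indices,
        epoch_index=peakset.epoch_index,
        epochs=list(peakset.epochs),
        sampling_rate=peakset.sampling_rate,
        subject_id=peakset.subject_id, session_id=peakset.session_id)


def build_segments(sequence: MicrostateSequence) -> pd.DataFrame:
    """Midpoint-rule segments of the labeled peak sequence, per epoch.

    Columns: class, onset_ms, offset_ms, lifespan_ms, truncated, epoch.
    Within an epoch, the boundary between two unlike-labeled consecutive
    peaks is their temporal midpoint; the first segment starts at the
    epoch start and the last ends at the epoch end (both truncated).
    Epochs without any peak contribute no segments.
    """
    ms_per_sample = 1000.0 / sequence.sampling_rate
    rows = []
    for e, (start, stop) in enumerate(sequence.epochs):
        sel = sequence.epoch_index == e
        if not sel.any():
            continue
        labels = sequence.class_index[sel]
        times = sequence.sample_indices[sel] * ms_per_sample
        t0, t1 = start * ms_per_sample, stop * ms_per_sample
        change = np.flatnonzero(labels[1:] != labels[:-1])
        bounds = [t0] + [(times[i] + times[i + 1]) / 2.0 for i in change] + [t1]
        run_starts = np.concatenate([[0], change + 1])
        for j, ri in enumerate(run_starts):
            rows.append({
                "class": sequence.class_names[labels[ri]],
                "onset_ms": bounds[j],
                "offset_ms": bounds[j + 1],
                "lifespan_ms": bounds[j + 1] - bounds[j],
                "truncated": j == 0 or j == len(run_starts) - 1,
                "epoch": e,
            })
    return pd.DataFrame(rows, columns=["class", "onset_ms", "offset_ms",
                                       "lifespan_ms", "truncated", "epoch"])


def extract_features(segments: pd.DataFrame,
                     class_names: "tuple[str, ...]" = ("A", "B", "C", "D"),
                     include_truncated: bool = True) -> pd.DataFrame:
    """Mean lifespan, frequency and coverage per class, plus an "All" row.

    Total time is the summed lifespan of all segments (the covered epoch
    time), so per-recording coverages sum to exactly 1 and
    coverage = frequency × mean lifespan holds identically.  A class that
    never appears gets a null lifespan and zero frequency/coverage.
    Truncated epoch-edge segments are included by default; excluding them
    breaks the identity and is offered for sensitivity analysis only.
    """
    if segments.empty:
        raise ValueError("no segments to extract features from")
    use = segments if include_truncated else segments[~segments["truncated"]]
    total_ms = use["lifespan_ms"].sum()
    total_s = total_ms / 1000.0
    rows = []
    for name in class_names:
        spans = use.loc[use["class"] == name, "lifespan_ms"]
        rows.append({
            "class": name,
            "mean_lifespan_ms": spans.mean() if len(spans) else np.nan,
            "frequency_hz": len(spans) / total_s,
            "coverage": spans.sum() / total_ms,
        })
    rows.append({
        "class": "All",
        "mean_lifespan_ms": use["lifespan_ms"].mean(),
        "frequency_hz": len(use) / total_s,
        "coverage": 1.0,
    })
    return pd.DataFrame(rows)


def features_for_recording(peakset: PeakSet, mapset: MapSet,
                           montage: "int | str" = "",
                           ) -> pd.DataFrame:
    """Backfit → segments → features for one recording, with identity
    columns attached (the row block of the study-level feature table)."""
    seq = backfit(peakset, mapset)
    segs = build_segments(seq)
    feats = extract_features(segs, class_names=tuple(mapset.labels))
    feats.insert(0, "subject", peakset.subject_id)
    feats.insert(1, "session", peakset.session_id)
    feats.insert(2, "montage", str(montage))
    feats.insert(3, "strategy", mapset.strategy)
    feats.insert(4, "algorithm", mapset.algorithm)
    return feats
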
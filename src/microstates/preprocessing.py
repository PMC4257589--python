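"""Signal conditioning from raw multichannel EEG to analysis-ready epochs.

The standard chain mirrors common resting-state microstate practice:
2-s epoching, downsampling, 55–65 Hz notch, 1–50 Hz broadband filtering
(2nd-order zero-phase Butterworth), amplitude-threshold epoch rejection,
average re-referencing, then a 1–30 Hz analysis band-pass and decimation
to 200 Hz for microstate analysis.  All filters operate per epoch, so
epochs that became discontinuous after rejection never leak into each
other.

Epoch rejection replaces manual artifact review with a deterministic
rule: an epoch is dropped if any channel exceeds the absolute amplitude
threshold (default ±100 µV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import Recording

__all__ = [
    "BANDS",
    "PreprocessConfig",
    "bandpass",
    "notch",
    "epoch",
    "reject_epochs",
    "average_reference",
    "downsample",
    "subset_channels",
    "band_power",
    "standard_chain",
]

logger = logging.getLogger(__name__)

#: Conventional EEG frequency bands (Hz).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.5),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}


@dataclass
class PreprocessConfig:
    epoch_s: float = 2.0
    intermediate_hz: float = 2000.0
    notch_band: tuple[float, float] = (55.0, 65.0)
    broadband: tuple[float, float] = (1.0, 50.0)
    analysis_band: tuple[float, float] = (1.0, 30.0)
    analysis_hz: float = 200.0
    reject_uv: float = 100.0
    filter_order: int = 2
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))


def _filtfilt_per_epoch(recording: Recording, sos: np.ndarray) -> Recording:
    out = recording.data.copy()
    for start, stop in recording.epochs:
        out[:, start:stop] = sps.sosfiltfilt(sos, recording.data[:, start:stop],
                                             axis=1)
    return recording.with_data(out)


def bandpass(recording: Recording, low_hz: float, high_hz: float,
             order: int = 2) -> Recording:
    """Zero-phase (forward-backward) Butterworth band-pass, per channel."""
    nyq = recording.sampling_rate / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz must satisfy "
                         f"0 < low < high < Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", output="sos",
                     fs=recording.sampling_rate)
    return _filtfilt_per_epoch(recording, sos)


def notch(recording: Recording, stop_low: float = 55.0,
          stop_high: float = 65.0, order: int = 2) -> Recording:
    """Zero-phase Butterworth band-stop (default 55–65 Hz line-noise notch)."""
    nyq = recording.sampling_rate / 2.0
    if not (0.0 < stop_low < stop_high < nyq):
        raise ValueError(f"stop band ({stop_low}, {stop_high}) Hz must satisfy "
                         f"0 < low < high < Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [stop_low, stop_high], btype="bandstop",
                     output="sos", fs=recording.sampling_rate)
    return _filtfilt_per_epoch(recording, sos)


def epoch(recording: Recording, epoch_s: float = 2.0) -> Recording:
    """Split the recording into consecutive fixed-length epochs.

    A trailing partial epoch is discarded.  Raises if no complete epoch
    fits.  Prior epoch boundaries are ignored (re-epoching a recording
    re-segments the concatenated data).
    """
    n_per = int(round(epoch_s * recording.sampling_rate))
    n_epochs = recording.n_samples // n_per
    if n_epochs == 0:
        raise ValueError(f"recording shorter ({recording.n_samples} samples) "
                         f"than one epoch ({n_per} samples)")
    data = recording.data[:, : n_epochs * n_per]
    bounds = [(i * n_per, (i + 1) * n_per) for i in range(n_epochs)]
    return recording.with_data(data, epochs=bounds)


def reject_epochs(recording: Recording, abs_amplitude_uv: float = 100.0) -> Recording:
    """Drop epochs where any channel exceeds the absolute threshold (µV)."""
    keep: list[np.ndarray] = []
    dropped = 0
    for start, stop in recording.epochs:
        seg = recording.data[:, start:stop]
        if np.max(np.abs(seg)) > abs_amplitude_uv:
            dropped += 1
        else:
            keep.append(seg)
    logger.info("reject_epochs: dropped %d of %d epochs (threshold %.1f µV)",
                dropped, len(recording.epochs), abs_amplitude_uv)
    if not keep:
        raise ValueError("no data remaining after epoch rejection")
    data = np.concatenate(keep, axis=1)
    bounds = []
    pos = 0
    for seg in keep:
        bounds.append((pos, pos + seg.shape[1]))
        pos += seg.shape[1]
    return recording.with_data(data, epochs=bounds)


def average_reference(recording: Recording) -> Recording:
    """Re-reference so the per-sample mean across channels is zero."""
    return recording.with_data(recording.data - recording.data.mean(axis=0))


def downsample(recording: Recording, target_hz: float) -> Recording:
    """Reduce the sampling rate (integer decimation, or polyphase resampling
    when the ratio is not integral).  Upsampling is refused; the pipeline
    order guarantees a prior low-pass below the new Nyquist."""
    src = recording.sampling_rate
    if target_hz > src:
        raise ValueError(f"cannot upsample {src} Hz -> {target_hz} Hz")
    if target_hz == src:
        return recording.copy()
    ratio = src / target_hz
    segs: list[np.ndarray] = []
    bounds: list[tuple[int, int]] = []
    pos = 0
    for start, stop in recording.epochs:
        seg = recording.data[:, start:stop]
        if abs(ratio - round(ratio)) < 1e-9:
            seg = seg[:, :: int(round(ratio))]
        else:
            from fractions import Fraction

            frac = Fraction(target_hz / src).limit_denominator(1000)
            seg = sps.resample_poly(seg, frac.numerator, frac.denominator, axis=1)
        segs.append(seg)
        bounds.append((pos, pos + seg.shape[1]))
        pos += seg.shape[1]
    return recording.with_data(np.concatenate(segs, axis=1),
                               sampling_rate=target_hz, epochs=bounds)


def subset_channels(recording: Recording,
                    montage: "int | list[str] | tuple[str, ...]") -> Recording:
    """Keep only the named channels (or a standard 30/19/8 montage subset),
    then re-average-reference over the remaining channels."""
    from .montage import get_montage

    labels = get_montage(montage).labels
    lut = {lab: i for i, lab in enumerate(recording.channel_labels)}
    missing = [lab for lab in labels if lab not in lut]
    if missing:
        raise KeyError(f"channel(s) {missing} not present in recording")
    idx = [lut[lab] for lab in labels]
    sub = recording.with_data(recording.data[idx], channel_labels=tuple(labels))
    return average_reference(sub)


def band_power(recording: Recording,
               bands: "dict[str, tuple[float, float]] | None" = None,
               total_band: tuple[float, float] = (1.0, 30.0)) -> pd.DataFrame:
    """Absolute (µV²) and relative band power, averaged across channels.

    The spectrum is the mean periodogram over epochs and channels (a
    Welch-style estimate whose segments are the 2-s epochs).  Relative
    power is each band's share of the total power in *total_band*.
    """
    bands = dict(BANDS) if bands is None else bands
    psds = []
    for start, stop in recording.epochs:
        freqs, psd = sps.periodogram(recording.data[:, start:stop],
                                     fs=recording.sampling_rate, axis=1,
                                     detrend="constant")
        psds.append(psd.mean(axis=0))
    psd = np.mean(psds, axis=0)

    def integrate(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    total = integrate(*total_band)
    rows = []
    for name, (lo, hi) in bands.items():
        absolute = integrate(lo, hi)
        rows.append({
            "subject": recording.subject_id,
            "session": recording.session_id,
            "band": name,
            "low_hz": lo,
            "high_hz": hi,
            "absolute_power": absolute,
            "relative_power": absolute / total if total > 0 else 0.0,
        })
    return pd.DataFrame(rows)


def standard_chain(recording: Recording,
                   config: "PreprocessConfig | None" = None,
                   return_broadband: bool = False,
                   ) -> "Recording | tuple[Recording, Recording]":
    """Full conditioning chain to 200 Hz average-referenced epochs.

    Order: epoch → downsample to the intermediate rate → notch →
    broadband 1–50 Hz → amplitude rejection → average reference →
    1–30 Hz analysis band → downsample to the analysis rate.  Downsample
    steps are skipped when the recording is already at or below the
    requested rate.

    With ``return_broadband=True`` also returns the intermediate
    broadband (1–50 Hz, artifact-rejected, average-referenced) recording,
    the stage on which spectral band powers are computed.
    """
    cfg = config or PreprocessConfig()
    rec = epoch(recording, cfg.epoch_s)
    if rec.sampling_rate > cfg.intermediate_hz:
        rec = downsample(rec, cfg.intermediate_hz)
    if cfg.notch_band[1] < rec.sampling_rate / 2.0:
        rec = notch(rec, *cfg.notch_band, order=cfg.filter_order)
    broadband_hi = min(cfg.broadband[1], rec.sampling_rate / 2.0 * 0.95)
    rec = bandpass(rec, cfg.broadband[0], broadband_hi, order=cfg.filter_order)
    rec = reject_epochs(rec, cfg.reject_uv)
    broadband = average_reference(rec)
    rec = bandpass(broadband, *cfg.analysis_band, order=cfg.filter_order)
    if rec.sampling_rate > cfg.analysis_hz:
        rec = downsample(rec, cfg.analysis_hz)
    return (rec, broadband) if return_broadband else rec
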
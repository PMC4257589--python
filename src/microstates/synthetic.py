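"""Synthetic resting-state EEG with known microstate ground truth.

The generator emulates a 10-subject × 3-session eyes-closed resting-state
study: four quasi-stable scalp topographies alternate according to a
first-order Markov chain, each dwell lasting a truncated-Gamma time with
mean ≈ 100 ms; within a dwell the active topography is amplitude-modulated
by an alpha-band (10 Hz) sinusoidal carrier, so the scalp polarity inverts
every half cycle while the (polarity-invariant) topography is stable.
Spatially smooth, temporally band-limited Gaussian noise is added at a
configurable signal-to-noise power ratio, and every sample is
average-referenced.

Between-subject variability enters as a per-subject multiplicative factor
on the mean dwell time, shared across that subject's sessions — this is
what gives the downstream test-retest statistics genuine between-subject
variance to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, signal as sps, special

from .montage import Montage, get_montage
from .recording import Recording
from .topography import gfp_normalize

__all__ = [
    "CLASS_NAMES",
    "SynthConfig",
    "GroundTruth",
    "SyntheticStudy",
    "make_template_maps",
    "generate_recording",
    "generate_study",
]

CLASS_NAMES: tuple[str, ...] = ("A", "B", "C", "D")

# Dipolar-gradient layouts of the four canonical resting-state classes:
# A right-anterior/left-posterior, B left-anterior/right-posterior,
# C symmetric anterior-posterior, D fronto-central.
_DIPOLE_POS = {
    "A": ((+0.85, +0.40), (-0.85, -0.40), 0.75),
    "B": ((-0.85, +0.40), (+0.85, -0.40), 0.75),
    "C": ((0.0, +0.95), (0.0, -0.95), 0.55),
}
_D_CENTER, _D_WIDTH = (0.0, 0.15), 0.45


def _uniform_offdiag(k: int = 4) -> np.ndarray:
    mat = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(mat, 0.0)
    return mat


@dataclass
class SynthConfig:
    """Study-level generative settings (defaults emulate the target design)."""

    n_subjects: int = 10
    n_sessions: int = 3
    n_channels: int = 30
    sampling_rate: float = 200.0
    record_length_s: float = 120.0
    mean_duration_ms: float = 100.0
    between_subject_sd_ms: float = 10.0
    carrier_frequency_hz: float = 10.0
    snr: float = 2.0
    gamma_shape: float = 4.0
    min_duration_ms: float = 30.0
    noise_spatial_scale: float = 0.5
    noise_band_hz: tuple[float, float] = (1.0, 15.0)
    signal_amplitude_uv: float = 10.0
    syntax_matrix: np.ndarray = field(default_factory=_uniform_offdiag)
    seed: int = 0

    def __post_init__(self) -> None:
        self.syntax_matrix = np.asarray(self.syntax_matrix, dtype=float)
        if self.syntax_matrix.shape != (4, 4):
            raise ValueError("syntax_matrix must be 4×4")
        if np.any(np.diag(self.syntax_matrix) != 0.0):
            raise ValueError("syntax_matrix diagonal must be zero")
        if not np.allclose(self.syntax_matrix.sum(axis=1), 1.0):
            raise ValueError("syntax_matrix rows must sum to 1")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.record_length_s * 1000.0 < self.min_duration_ms:
            raise ValueError("record too short for a single dwell")


@dataclass
class GroundTruth:
    """Generative truth for one recording."""

    templates: np.ndarray  # (4, n_channels), zero-mean, unit GFP
    label_sequence: np.ndarray  # class index per dwell segment
    segment_durations_ms: np.ndarray
    subject_factor: float
    seed: int
    class_names: tuple[str, ...] = CLASS_NAMES

    @property
    def onsets_ms(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.segment_durations_ms)[:-1]])

    def coverage(self) -> np.ndarray:
        """Ground-truth coverage fraction per class (sums to 1)."""
        total = self.segment_durations_ms.sum()
        return np.array([
            self.segment_durations_ms[self.label_sequence == k].sum() / total
            for k in range(len(self.class_names))
        ])

    def label_at(self, times_ms: np.ndarray) -> np.ndarray:
        """True class index at each queried time."""
        edges = np.cumsum(self.segment_durations_ms)
        ix = np.searchsorted(edges, np.asarray(times_ms), side="right")
        return self.label_sequence[np.clip(ix, 0, len(self.label_sequence) - 1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "onset_ms": self.onsets_ms,
            "duration_ms": self.segment_durations_ms,
            "class": [self.class_names[k] for k in self.label_sequence],
        })


def _smooth_kernel(montage: Montage, scale: float) -> np.ndarray:
    diff = montage.positions[:, None, :] - montage.positions[None, :, :]
    dist2 = (diff**2).sum(axis=-1)
    return np.exp(-dist2 / (2.0 * scale**2))


def make_template_maps(montage: "Montage | int | list[str]",
                       seed: int = 0) -> np.ndarray:
    """Four smooth dipolar template maps (zero mean, unit GFP) on a montage.

    The base layouts follow the canonical class geometries; a small
    spatially smooth seed-dependent perturbation individuates template
    sets while preserving pairwise |spatial correlation| < 0.7.
    """
    if not isinstance(montage, Montage):
        montage = get_montage(montage)
    pos = montage.positions

    def dipole(pp, pm, width):
        return (np.exp(-((pos - np.array(pp)) ** 2).sum(1) / (2 * width**2))
                - np.exp(-((pos - np.array(pm)) ** 2).sum(1) / (2 * width**2)))

    base = [dipole(*_DIPOLE_POS[c]) for c in ("A", "B", "C")]
    base.append(np.exp(-((pos - np.array(_D_CENTER)) ** 2).sum(1)
                       / (2 * _D_WIDTH**2)))
    base = np.array([gfp_normalize(m) for m in base])

    kernel = _smooth_kernel(montage, 0.6)
    ss = np.random.SeedSequence([int(seed), 0x7E4])
    for attempt in range(32):
        rng = np.random.default_rng(ss.spawn(1)[0] if attempt else ss)
        bump = kernel @ rng.standard_normal((montage.n_channels, 4))
        maps = np.array([
            gfp_normalize(base[k] + 0.08 * gfp_normalize(bump[:, k]))
            for k in range(4)
        ])
        corr = np.abs(maps @ maps.T) / montage.n_channels
        if np.all(corr[np.triu_indices(4, 1)] < 0.7):
            return maps
    raise RuntimeError("could not generate templates with pairwise |corr| < 0.7")


def _truncated_gamma_scale(mean: float, shape: float, lower: float) -> float:
    """Scale θ so the Gamma(shape, θ) left-truncated at *lower* has the
    requested mean."""

    def trunc_mean(theta: float) -> float:
        z = lower / theta
        surv_k = special.gammaincc(shape, z)
        if surv_k == 0.0:  # survival underflow: nearly all mass below cut
            return lower
        surv_k1 = special.gammaincc(shape + 1.0, z)
        return shape * theta * surv_k1 / surv_k

    naive = mean / shape
    f = lambda th: trunc_mean(th) - mean
    lo = naive * 1e-3
    if f(lo) > 0:  # truncation alone already exceeds the target mean
        raise ValueError(f"mean {mean} unattainable with lower bound {lower}")
    return float(optimize.brentq(f, lo, naive * 2.0, xtol=1e-10))


def _draw_durations(rng: np.random.Generator, total_ms: float, mean_ms: float,
                    shape: float, lower_ms: float) -> np.ndarray:
    theta = _truncated_gamma_scale(mean_ms, shape, lower_ms)
    out: list[float] = []
    acc = 0.0
    while acc < total_ms:
        d = rng.gamma(shape, theta)
        while d < lower_ms:
            d = rng.gamma(shape, theta)
        out.append(d)
        acc += d
    out[-1] -= acc - total_ms  # trim the last dwell to the record end
    if out[-1] <= 0:
        out.pop()
    return np.array(out)


def generate_recording(templates: np.ndarray, config: SynthConfig,
                       subject_id: str = "S01", session_id: str = "ses1",
                       subject_factor: float = 1.0,
                       seed: "int | np.random.SeedSequence | None" = None,
                       montage: "Montage | None" = None,
                       ) -> tuple[Recording, GroundTruth]:
    """Simulate one recording from template maps and a config.

    The per-channel signal within each dwell is
    ``template × A·sin(2π f t + φ)`` with a fresh random phase per dwell;
    noise is channel-wise Gaussian, spatially smoothed over electrode
    distance, band-limited to the analysis band, average-referenced and
    scaled so that signal power / noise power = ``config.snr``.
    """
    if montage is None:
        montage = get_montage(config.n_channels)
    templates = np.asarray(templates, dtype=float)
    if templates.shape != (4, montage.n_channels):
        raise ValueError("templates must be (4, n_channels) on the montage")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(config.seed if seed is None else seed))
    rng = np.random.default_rng(ss)

    total_ms = config.record_length_s * 1000.0
    durations = _draw_durations(rng, total_ms,
                                config.mean_duration_ms * subject_factor,
                                config.gamma_shape, config.min_duration_ms)
    n_seg = len(durations)
    labels = np.empty(n_seg, dtype=int)
    labels[0] = rng.integers(4)
    for i in range(1, n_seg):
        labels[i] = rng.choice(4, p=config.syntax_matrix[labels[i - 1]])

    n_samples = int(round(config.record_length_s * config.sampling_rate))
    t = np.arange(n_samples) / config.sampling_rate
    amp = config.signal_amplitude_uv
    onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]]) / 1000.0
    edges = np.searchsorted(t, np.cumsum(durations) / 1000.0)
    starts = np.concatenate([[0], edges[:-1]])

    signal = np.zeros((montage.n_channels, n_samples))
    for k, s0, s1 in zip(labels, starts, edges):
        if s1 <= s0:
            continue
        phase = rng.uniform(0, 2 * np.pi)
        carrier = amp * np.sin(2 * np.pi * config.carrier_frequency_hz
                               * t[s0:s1] + phase)
        signal[:, s0:s1] = templates[k][:, None] * carrier[None, :]

    if np.isfinite(config.snr):
        white = rng.standard_normal((montage.n_channels, n_samples))
        kernel = _smooth_kernel(montage, config.noise_spatial_scale)
        noise = kernel @ white
        lo, hi = config.noise_band_hz
        sos = sps.butter(2, [lo, min(hi, config.sampling_rate / 2 * 0.95)],
                         btype="bandpass", output="sos",
                         fs=config.sampling_rate)
        noise = sps.sosfiltfilt(sos, noise, axis=1)
        noise -= noise.mean(axis=0)  # average reference before scaling
        sig_power = float(np.mean(signal**2))
        noise_power = float(np.mean(noise**2))
        noise *= np.sqrt(sig_power / (config.snr * noise_power))
        data = signal + noise
    else:
        data = signal
    data -= data.mean(axis=0)

    rec = Recording(data=data, channel_labels=montage.labels,
                    sampling_rate=config.sampling_rate,
                    subject_id=subject_id, session_id=session_id)
    try:
        seed_val = int(ss.entropy)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        seed_val = -1  # spawned child; not representable as one integer
    truth = GroundTruth(templates=templates, label_sequence=labels,
                        segment_durations_ms=durations,
                        subject_factor=subject_factor, seed=seed_val)
    return rec, truth


@dataclass
class SyntheticStudy:
    """All recordings of a simulated multi-session study, plus the truth."""

    config: SynthConfig
    montage: Montage
    templates: np.ndarray
    subject_factors: np.ndarray
    recordings: list[Recording]
    truths: list[GroundTruth]

    def recording(self, subject_id: str, session_id: str) -> Recording:
        for rec in self.recordings:
            if rec.subject_id == subject_id and rec.session_id == session_id:
                return rec
        raise KeyError((subject_id, session_id))

    def export(self, outdir: "str | Path") -> None:
        """Write recordings and ground-truth segment tables as delimited text."""
        from .recording import write_delimited

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for rec, truth in zip(self.recordings, self.truths):
            stem = f"{rec.subject_id}_{rec.session_id}"
            write_delimited(rec, outdir / f"{stem}.tsv")
            truth.to_frame().to_csv(outdir / f"{stem}_truth.tsv", sep="\t",
                                    index=False)
        pd.DataFrame(self.templates, columns=list(self.montage.labels),
                     index=list(CLASS_NAMES)).to_csv(
            outdir / "templates.tsv", sep="\t")


def generate_study(config: "SynthConfig | None" = None) -> SyntheticStudy:
    """Simulate every subject × session recording of the configured study.

    Deterministic under ``config.seed``; the per-subject dwell-time factor
    is drawn once per subject and shared across that subject's sessions,
    which is what gives the study real between-subject variance.
    """
    config = config or SynthConfig()
    montage = get_montage(config.n_channels)
    root = np.random.SeedSequence(config.seed)
    template_ss, factor_ss, rec_root = root.spawn(3)
    templates = make_template_maps(montage, seed=config.seed)

    factor_rng = np.random.default_rng(factor_ss)
    rel_sd = config.between_subject_sd_ms / config.mean_duration_ms
    factors = factor_rng.normal(1.0, rel_sd, size=config.n_subjects)
    factors = np.clip(factors, 0.2, None)

    rec_seeds = rec_root.spawn(config.n_subjects * config.n_sessions)
    recordings: list[Recording] = []
    truths: list[GroundTruth] = []
    i = 0
    for s in range(config.n_subjects):
        for ses in range(config.n_sessions):
            rec, truth = generate_recording(
                templates, config,
                subject_id=f"S{s + 1:02d}", session_id=f"ses{ses + 1}",
                subject_factor=float(factors[s]), seed=rec_seeds[i],
                montage=montage)
            recordings.append(rec)
            truths.append(truth)
            i += 1
    return SyntheticStudy(config=config, montage=montage, templates=templates,
                          subject_factors=factors, recordings=recordings,
                          truths=truths)
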
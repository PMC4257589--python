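"""Study orchestration: synthesize or load data, run the full analysis grid.

``run_study`` drives the complete workflow for every requested montage ×
strategy × algorithm combination: preprocessing → GFP-peak extraction →
map derivation → back-fitting → feature extraction → reliability report,
plus cross-method consistency tables (algorithm as the repeated
measurement; montage as the repeated measurement), per-class TANOVA
between the TAAHC and k-means maps, feature–feature correlations and the
feature-on-band-power regression.

One study seed fans out deterministically to per-stage seeds, so reruns
with the same configuration are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, preprocessing, reliability, segmentation
from .clustering import MapSet
from .recording import Recording, read_delimited, read_edf
from .synthetic import SynthConfig, generate_study
from .topography import PeakSet, find_gfp_peaks, gfp_normalize

__all__ = ["StudyConfig", "StudyResult", "run_study", "consistency_analysis"]

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Configuration of a full analysis run."""

    input_mode: str = "synthetic"  # "synthetic" | "files"
    input_dir: "str | None" = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    prep: preprocessing.PreprocessConfig = field(
        default_factory=preprocessing.PreprocessConfig)
    montages: tuple[int, ...] = (30,)
    strategies: tuple[str, ...] = ("global",)
    algorithms: tuple[str, ...] = ("taahc",)
    k: int = 4
    kmeans_restarts: int = 300
    tanova_permutations: int = 5000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("K must be >= 2")
        if not (self.montages and self.strategies and self.algorithms):
            raise ValueError("montages, strategies and algorithms must be "
                             "non-empty")
        for s in self.strategies:
            if s not in ("global", "by_session", "by_recording"):
                raise ValueError(f"unknown strategy {s!r}")
        for a in self.algorithms:
            if a not in ("taahc", "kmeans"):
                raise ValueError(f"unknown algorithm {a!r}")

    @classmethod
    def ci_profile(cls, **overrides) -> "StudyConfig":
        """Desk-scale profile: fewer k-means restarts and permutations."""
        overrides.setdefault("kmeans_restarts", 50)
        overrides.setdefault("tanova_permutations", 1000)
        return cls(**overrides)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        prep = preprocessing.PreprocessConfig(**raw.pop("prep", {}))
        for key in ("montages", "strategies", "algorithms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synth=synth, prep=prep, **raw)


@dataclass
class StudyResult:
    config: StudyConfig
    features: pd.DataFrame
    band_powers: pd.DataFrame
    reliability: pd.DataFrame
    consistency_algorithms: pd.DataFrame
    consistency_montages: pd.DataFrame
    tanova: pd.DataFrame
    correlations: pd.DataFrame
    power_models: pd.DataFrame
    mapsets: dict
    manifest: dict
    #: the generated study (templates and ground truth) for synthetic runs
    synthetic_study: "object | None" = None

    def save(self, outdir: "str | Path") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "features.tsv": self.features,
            "band_powers.tsv": self.band_powers,
            "reliability.tsv": self.reliability,
            "consistency_algorithms.tsv": self.consistency_algorithms,
            "consistency_montages.tsv": self.consistency_montages,
            "tanova.tsv": self.tanova,
            "feature_correlations.tsv": self.correlations,
            "power_models.tsv": self.power_models,
        }
        for name, frame in tables.items():
            frame.to_csv(outdir / name, sep="\t", index=False,
                         float_format="%.10g")
        mapdir = outdir / "mapsets"
        mapdir.mkdir(exist_ok=True)
        for (montage, strategy, algorithm), sets in self.mapsets.items():
            for key, ms in sets.items():
                key_s = key if isinstance(key, str) else "_".join(key)
                ms.save(mapdir / f"{montage}ch_{strategy}_{algorithm}_"
                                 f"{key_s}.tsv")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True))


def _load_recordings(input_dir: "str | Path") -> list[Recording]:
    paths = sorted(Path(input_dir).glob("*"))
    recs = []
    for p in paths:
        if p.suffix.lower() == ".edf":
            recs.append(read_edf(p))
        elif p.suffix.lower() in (".tsv", ".txt", ".csv") and \
                not p.name.endswith("_truth.tsv") and p.name != "templates.tsv":
            recs.append(read_delimited(p))
    if not recs:
        raise FileNotFoundError(f"no recordings found in {input_dir}")
    return recs


def _stage_seed(root: np.random.SeedSequence, *key: int) -> int:
    """Deterministic per-stage integer seed below 2**31."""
    child = np.random.SeedSequence(list(root.entropy if isinstance(
        root.entropy, (list, tuple)) else [root.entropy]) + list(key))
    return int(child.generate_state(1)[0] % (2**31))


def _mapset_for_recording(mapsets: dict, strategy: str, rec_ps: PeakSet) -> MapSet:
    if strategy == "global":
        return mapsets["global"]
    if strategy == "by_session":
        return mapsets[rec_ps.session_id]
    return mapsets[(rec_ps.subject_id, rec_ps.session_id)]


def _subject_class_maps(level1_matched: "dict[tuple[str, str], MapSet]",
                        subjects: "list[str]", label: str) -> np.ndarray:
    """Per-subject class map: sign-aligned unit-GFP average of that
    subject's per-recording maps for one class."""
    rows = []
    for subj in subjects:
        maps = [ms.map_for(label) for (s, _), ms in level1_matched.items()
                if s == subj]
        maps = np.array([gfp_normalize(m) for m in maps])
        anchor = maps[0]
        signs = np.where(maps @ anchor < 0, -1.0, 1.0)
        rows.append(gfp_normalize((signs[:, None] * maps).mean(axis=0)))
    return np.array(rows)


def consistency_analysis(features: pd.DataFrame, measurement: str,
                         session: "str | None" = None) -> pd.DataFrame:
    """Cross-method consistency: Cronbach's α with *measurement*
    ("algorithm" or "montage") as the repeated measurement, computed in a
    single session (the first, by default)."""
    if session is None:
        session = sorted(features["session"].unique())[0]
    sub = features[features["session"] == session].copy()
    report = reliability.reliability_report(sub, measurement=measurement)
    report = report.rename(columns={"k": "n_methods"})
    report["session"] = session
    return report


def run_study(config: "StudyConfig | None" = None) -> StudyResult:
    """Execute the configured analysis grid end to end."""
    config = config or StudyConfig()
    root = np.random.SeedSequence(config.seed)

    study = None
    if config.input_mode == "synthetic":
        study = generate_study(config.synth)
        raw_recordings = study.recordings
    elif config.input_mode == "files":
        if not config.input_dir:
            raise ValueError("input_dir required for input_mode='files'")
        raw_recordings = _load_recordings(config.input_dir)
    else:
        raise ValueError(f"unknown input_mode {config.input_mode!r}")

    # Preprocess once at the full montage; subset afterwards.
    pre: list[Recording] = []
    broadband: list[Recording] = []
    for rec in raw_recordings:
        analysis, broad = preprocessing.standard_chain(
            rec, config.prep, return_broadband=True)
        pre.append(analysis)
        broadband.append(broad)

    band_powers = pd.concat(
        [preprocessing.band_power(rec, config.prep.bands) for rec in broadband],
        ignore_index=True)

    subjects = sorted({rec.subject_id for rec in pre})
    features_all: list[pd.DataFrame] = []
    mapsets_out: dict = {}
    tanova_rows: list[dict] = []
    manifest: dict = {
        "n_recordings": len(pre),
        "mean_duration_s": float(np.mean([r.duration_s for r in pre])),
        "montages": list(config.montages),
        "strategies": list(config.strategies),
        "algorithms": list(config.algorithms),
        "seed": config.seed,
        "gev_level1": {},
    }

    for montage in config.montages:
        peaksets = [find_gfp_peaks(
            preprocessing.subset_channels(rec, montage)) for rec in pre]

        level1: dict[str, list[MapSet]] = {}
        for ai, algorithm in enumerate(config.algorithms):
            level1[algorithm] = clustering.first_level_maps(
                peaksets, algorithm=algorithm, k=config.k,
                restarts=config.kmeans_restarts,
                seed=_stage_seed(root, montage, ai, 1))
            manifest["gev_level1"][f"{montage}ch_{algorithm}"] = [
                ms.gev_on_source for ms in level1[algorithm]]

        # Global TAAHC maps anchor all labels on this montage.
        ref_algorithm = "taahc" if "taahc" in config.algorithms \
            else config.algorithms[0]
        reference = clustering.derive_maps(
            peaksets, "global", ref_algorithm, k=config.k,
            restarts=config.kmeans_restarts,
            seed=_stage_seed(root, montage, 0, 2),
            level1=level1[ref_algorithm])["global"]

        for ai, algorithm in enumerate(config.algorithms):
            for si, strategy in enumerate(config.strategies):
                mapsets = clustering.derive_maps(
                    peaksets, strategy, algorithm, k=config.k,
                    restarts=config.kmeans_restarts,
                    seed=_stage_seed(root, montage, 10 * ai + si, 3),
                    reference=reference, level1=level1[algorithm])
                mapsets_out[(montage, strategy, algorithm)] = mapsets
                for ps in peaksets:
                    ms = _mapset_for_recording(mapsets, strategy, ps)
                    feats = segmentation.features_for_recording(
                        ps, replace(ms, algorithm=algorithm), montage=montage)
                    features_all.append(feats)

        if {"taahc", "kmeans"} <= set(config.algorithms):
            matched = {
                alg: {(ps.subject_id, ps.session_id):
                      clustering.match_labels(ms, reference)
                      for ps, ms in zip(peaksets, level1[alg])}
                for alg in ("taahc", "kmeans")}
            for label in reference.labels:
                g1 = _subject_class_maps(matched["taahc"], subjects, label)
                g2 = _subject_class_maps(matched["kmeans"], subjects, label)
                res = reliability.tanova(
                    g1, g2, permutations=config.tanova_permutations,
                    seed=_stage_seed(root, montage, ord(label[0]), 4))
                tanova_rows.append({
                    "montage": montage, "class": label,
                    "observed_gmd": res.observed_gmd, "p": res.p_value,
                    "n_permutations": res.n_permutations, "seed": res.seed})

    features = pd.concat(features_all, ignore_index=True)
    report = reliability.reliability_report(features)

    glb = features[features["strategy"] == "global"]
    cons_alg = (consistency_analysis(glb, "algorithm")
                if len(config.algorithms) > 1 else pd.DataFrame())
    cons_mont = (consistency_analysis(
        glb[glb["algorithm"] == ("taahc" if "taahc" in config.algorithms
                                 else config.algorithms[0])], "montage")
        if len(config.montages) > 1 else pd.DataFrame())

    corr_base = glb[(glb["montage"] == str(config.montages[0]))
                    & (glb["algorithm"] == config.algorithms[0])]
    correlations = reliability.feature_correlations(corr_base)

    model_rows = []
    for response in ("mean_lifespan_ms", "frequency_hz"):
        try:
            model = reliability.power_regression(corr_base, band_powers,
                                                 response=response)
        except ValueError as err:
            logger.warning("power_regression(%s) skipped: %s", response, err)
            continue
        for name in model["params"].index:
            model_rows.append({
                "response": response, "term": name,
                "coef": model["params"][name],
                "p_value": model["pvalues"][name],
                "r_squared": model["r_squared"],
                "collinear": model["collinear"], "n": model["n"]})
    power_models = pd.DataFrame(model_rows)

    return StudyResult(
        config=config, features=features, band_powers=band_powers,
        reliability=report, consistency_algorithms=cons_alg,
        consistency_montages=cons_mont, tanova=pd.DataFrame(tanova_rows),
        correlations=correlations, power_models=power_models,
        mapsets=mapsets_out, manifest=manifest, synthetic_study=study)
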
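"""Microstate template identification: TAAHC and polarity-invariant k-means.

Both algorithms cluster "original maps" (topographies at GFP peaks) into
K template maps using the absolute spatial correlation, so a map and its
negation always land in the same cluster.  Cluster means are computed
after sign-aligning members to the current mean — without this, the
polarity inversions of the oscillatory carrier would cancel the mean to
zero.

TAAHC (topographic atomize-and-agglomerate hierarchical clustering)
starts from singleton clusters and repeatedly dissolves the "worst"
cluster — the one with the lowest summed member-to-mean |correlation| —
redistributing its members one at a time (in input order) to the
remaining cluster each correlates with most strongly, until K clusters
remain.  It is deterministic given the input order.

The modified k-means draws K distinct maps as initial templates,
alternates polarity-invariant assignment with sign-aligned re-averaging
until the global explained variance (GEV) stops improving, and keeps the
best of many random restarts (300 by default).
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .topography import PeakSet, gfp, gfp_normalize

__all__ = [
    "MapSet",
    "ClusterAssignment",
    "taahc",
    "kmeans_microstates",
    "gev",
    "cv_criterion",
    "match_labels",
    "derive_maps",
]


@dataclass
class MapSet:
    """K labeled microstate template maps plus provenance."""

    maps: np.ndarray  # (K, n_channels), zero-mean, unit-GFP rows
    labels: tuple[str, ...]
    algorithm: str = ""
    strategy: str = ""
    channel_labels: tuple[str, ...] = ()
    gev_on_source: "float | None" = None
    seed: "int | None" = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[0] != len(self.labels):
            raise ValueError("maps must be (K, n_channels) matching labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    def map_for(self, label: str) -> np.ndarray:
        return self.maps[self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        cols = list(self.channel_labels) or [f"ch{i}" for i in
                                             range(self.maps.shape[1])]
        frame = pd.DataFrame(self.maps, columns=cols)
        frame.insert(0, "label", list(self.labels))
        return frame

    def save(self, path: "str | Path") -> None:
        """Delimited table plus a small JSON metadata sidecar."""
        import json

        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        meta = {"algorithm": self.algorithm, "strategy": self.strategy,
                "gev_on_source": self.gev_on_source, "seed": self.seed}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: "str | Path") -> "MapSet":
        import json

        path = Path(path)
        frame = pd.read_csv(path, sep="\t")
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(maps=frame.drop(columns="label").to_numpy(),
                   labels=tuple(frame["label"]),
                   algorithm=meta.get("algorithm", ""),
                   strategy=meta.get("strategy", ""),
                   channel_labels=tuple(frame.columns[1:]),
                   gev_on_source=meta.get("gev_on_source"),
                   seed=meta.get("seed"))


@dataclass
class ClusterAssignment:
    cluster_index: np.ndarray  # per input map
    means: np.ndarray  # (K, n_channels), unit-GFP


def _normalize_rows(maps: np.ndarray) -> np.ndarray:
    maps = np.asarray(maps, dtype=float)
    centered = maps - maps.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.mean(centered**2, axis=1, keepdims=True))
    if np.any(norms == 0):
        raise ValueError("cannot cluster constant (zero-GFP) maps")
    return centered / norms


def _aligned_mean(members: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Unit-GFP mean of *members* after sign-aligning each to *anchor*."""
    members = np.atleast_2d(members)
    signs = np.sign(members @ anchor)
    signs[signs == 0] = 1.0
    return gfp_normalize((signs[:, None] * members).mean(axis=0))


def taahc(maps: np.ndarray, k: int) -> tuple[MapSet, ClusterAssignment]:
    """Atomize-and-agglomerate hierarchical clustering down to *k* clusters.

    Deterministic given the input order; ties (equally bad clusters,
    equally good destinations) break toward the lowest cluster index.
    """
    X = _normalize_rows(maps)
    m, n_ch = X.shape
    if not (1 <= k <= m):
        raise ValueError(f"need 1 <= K <= number of maps ({m}), got K={k}")

    assignment = np.arange(m)
    members: list[list[int]] = [[i] for i in range(m)]
    means = X.copy()
    active = np.ones(m, dtype=bool)
    n_active = m

    while n_active > k:
        corr_own = np.abs(np.einsum("ij,ij->i", X, means[assignment])) / n_ch
        quality = np.bincount(assignment, weights=corr_own, minlength=m)
        quality[~active] = np.inf
        worst = int(np.argmin(quality))  # argmin takes the lowest index on ties
        orphans = members[worst]
        active[worst] = False
        members[worst] = []
        n_active -= 1
        act_ix = np.flatnonzero(active)
        for i in orphans:  # sequential, in input order
            corrs = np.abs(means[act_ix] @ X[i]) / n_ch
            dest = int(act_ix[int(np.argmax(corrs))])
            assignment[i] = dest
            members[dest].append(i)
            means[dest] = _aligned_mean(X[members[dest]], means[dest])

    act_ix = np.flatnonzero(active)
    # stable output order: by descending cluster size, then cluster index
    sizes = np.array([len(members[c]) for c in act_ix])
    order = act_ix[np.lexsort((act_ix, -sizes))]
    remap = {int(c): i for i, c in enumerate(order)}
    out_assign = np.array([remap[int(c)] for c in assignment])
    out_means = np.array([means[c] for c in order])
    labels = tuple(str(i + 1) for i in range(k))
    mapset = MapSet(maps=out_means, labels=labels, algorithm="taahc")
    return mapset, ClusterAssignment(cluster_index=out_assign, means=out_means)


def gev(maps: np.ndarray, templates: "MapSet | np.ndarray",
        assignment: "ClusterAssignment | np.ndarray") -> float:
    """Global explained variance of an assignment of maps to templates.

    GEV = Σ_u (GFP_u · C_u)² / Σ_u GFP_u², where C_u is the spatial
    correlation of original map u with its assigned template.  Squaring
    makes the measure polarity-invariant.
    """
    maps = np.asarray(maps, dtype=float)
    T = templates.maps if isinstance(templates, MapSet) else np.asarray(templates)
    a = (assignment.cluster_index if isinstance(assignment, ClusterAssignment)
         else np.asarray(assignment))
    X = _normalize_rows(maps)
    w = gfp(maps.T)  # per-map GFP
    Tn = _normalize_rows(T)
    corr = np.einsum("ij,ij->i", X, Tn[a]) / maps.shape[1]
    return float(np.sum((w * corr) ** 2) / np.sum(w**2))


def kmeans_microstates(maps: np.ndarray, k: int, restarts: int = 300,
                       seed: "int | np.random.SeedSequence | None" = None,
                       max_iter: int = 1000, tol: float = 1e-7,
                       ) -> tuple[MapSet, ClusterAssignment]:
    """Polarity-invariant k-means over topographies, best of *restarts*.

    Each restart initializes templates from K distinct input maps, then
    alternates |correlation| assignment with sign-aligned re-averaging
    until GEV improves by less than *tol*.  The restart with the highest
    GEV wins; the procedure is reproducible under *seed*.
    """
    maps = np.asarray(maps, dtype=float)
    X = _normalize_rows(maps)
    m, n_ch = X.shape
    if not (1 <= k <= m):
        raise ValueError(f"need 1 <= K <= number of maps ({m}), got K={k}")
    distinct = np.unique(np.round(X, 12), axis=0)
    if len(distinct) < k:
        raise ValueError(f"only {len(distinct)} distinct maps for K={k}")
    w = gfp(maps.T)
    w2 = np.sum(w**2)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(0 if seed is None else seed))
    rng = np.random.default_rng(ss)

    best_gev = -np.inf
    best: "tuple[np.ndarray, np.ndarray] | None" = None
    for _ in range(restarts):
        for _try in range(100):
            idx = rng.choice(m, size=k, replace=False)
            if len(np.unique(np.round(X[idx], 12), axis=0)) == k:
                break
        T = X[idx].copy()
        prev = -np.inf
        for _it in range(max_iter):
            corr = X @ T.T / n_ch
            assign = np.argmax(np.abs(corr), axis=1)
            picked = corr[np.arange(m), assign]
            cur = float(np.sum((w * picked) ** 2) / w2)
            if cur - prev < tol:
                break
            prev = cur
            for c in range(k):
                sel = assign == c
                if sel.any():  # empty clusters keep their template
                    T[c] = _aligned_mean(X[sel], T[c])
        if cur > best_gev:
            best_gev = cur
            best = (T.copy(), assign.copy())

    T, assign = best  # type: ignore[misc]
    order = np.lexsort((np.arange(k), -np.bincount(assign, minlength=k)))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    mapset = MapSet(maps=T[order], labels=tuple(str(i + 1) for i in range(k)),
                    algorithm="kmeans", gev_on_source=best_gev)
    return mapset, ClusterAssignment(cluster_index=remap[assign], means=T[order])


def cv_criterion(maps: np.ndarray, templates: "MapSet | np.ndarray",
                 assignment: "ClusterAssignment | np.ndarray") -> float:
    """Predictive-residual cross-validation criterion for the model order.

    CV = σ̂² · ((n−1)/(n−1−K))², with σ̂² the mean residual variance of
    the original maps about their assigned templates (the variance not
    explained by the best scaled template).  Lower is better; diverges as
    K approaches n−1, which is refused.
    """
    maps = np.asarray(maps, dtype=float)
    T = templates.maps if isinstance(templates, MapSet) else np.asarray(templates)
    a = (assignment.cluster_index if isinstance(assignment, ClusterAssignment)
         else np.asarray(assignment))
    m, n = maps.shape
    k = T.shape[0]
    if k >= n - 1:
        raise ValueError(f"CV criterion undefined for K={k} >= n_electrodes-1")
    centered = maps - maps.mean(axis=1, keepdims=True)
    Tn = _normalize_rows(T)  # unit-GFP rows, so ‖t‖₂² = n
    resid = np.sum(centered**2, axis=1) - (np.einsum("ij,ij->i", centered,
                                                     Tn[a]) ** 2) / n
    sigma2 = float(np.sum(resid) / (m * (n - 1)))
    return sigma2 * ((n - 1) / (n - 1 - k)) ** 2


def match_labels(mapset: MapSet, reference: MapSet) -> MapSet:
    """Relabel (and reorder) a map set against a reference map set.

    Finds the one-to-one assignment maximizing the total absolute spatial
    correlation (exhaustive over K! permutations; K is 4 here), breaking
    exact ties toward reference label order.  Matched maps are also
    sign-aligned to their reference map for display consistency.
    """
    if mapset.k != reference.k:
        raise ValueError("map sets must have the same K to be matched")
    n_ch = mapset.maps.shape[1]
    A = _normalize_rows(mapset.maps)
    R = _normalize_rows(reference.maps)
    corr = R @ A.T / n_ch  # (ref, candidate)
    best_perm, best_total = None, -np.inf
    for perm in itertools.permutations(range(mapset.k)):
        total = sum(abs(corr[i, perm[i]]) for i in range(mapset.k))
        if total > best_total + 1e-15:
            best_total, best_perm = total, perm
    new_maps = []
    for i, j in enumerate(best_perm):  # type: ignore[arg-type]
        sign = 1.0 if corr[i, j] >= 0 else -1.0
        new_maps.append(sign * A[j])
    return replace(mapset, maps=np.array(new_maps), labels=reference.labels)


def _cluster(maps: np.ndarray, k: int, algorithm: str, restarts: int,
             seed: "np.random.SeedSequence | int | None"):
    if algorithm == "taahc":
        return taahc(maps, k)
    if algorithm == "kmeans":
        return kmeans_microstates(maps, k, restarts=restarts, seed=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def first_level_maps(peaksets: "list[PeakSet]", algorithm: str = "taahc",
                     k: int = 4, restarts: int = 300,
                     seed: "int | None" = None) -> "list[MapSet]":
    """Cluster each recording's original maps into K maps (the shared
    first level of every derivation strategy).  Reusable across
    strategies via the ``level1`` argument of :func:`derive_maps`."""
    if not peaksets:
        raise ValueError("no peak sets supplied")
    for ps in peaksets:
        if ps.n_peaks == 0:
            raise ValueError(f"empty peak set for recording "
                             f"{ps.subject_id}/{ps.session_id}")
        if ps.n_peaks < k:
            raise ValueError(f"recording {ps.subject_id}/{ps.session_id} has "
                             f"fewer peaks ({ps.n_peaks}) than K={k}")
    root = np.random.SeedSequence([0 if seed is None else seed, 0x11])
    out: list[MapSet] = []
    for ps, child in zip(peaksets, root.spawn(len(peaksets))):
        ms, assign = _cluster(ps.maps, k, algorithm, restarts, child)
        out.append(replace(ms, channel_labels=ps.channel_labels,
                           gev_on_source=gev(ps.maps, ms, assign), seed=seed))
    return out


def derive_maps(peaksets: "list[PeakSet]", strategy: str = "global",
                algorithm: str = "taahc", k: int = 4, restarts: int = 300,
                seed: "int | None" = None,
                reference: "MapSet | None" = None,
                level1: "list[MapSet] | None" = None) -> dict:
    """Derive microstate maps under one of three strategies.

    Every strategy first clusters each recording's original maps into K
    maps.  ``global`` pools all first-level maps (K × n_recordings) into a
    second round of clustering, yielding one map set; ``by_session``
    pools within each session; ``by_recording`` stops at the first level.
    Outputs are label-matched to *reference* (normally the global TAAHC
    maps); without a reference, the global map set of this run — derived
    with the same algorithm — anchors the labels A–D in cluster-size
    order.

    Returns a dict keyed by ``"global"``, session id, or
    ``(subject, session)`` respectively.
    """
    if strategy not in ("global", "by_session", "by_recording"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if level1 is None:
        level1 = first_level_maps(peaksets, algorithm=algorithm, k=k,
                                  restarts=restarts, seed=seed)
    elif len(level1) != len(peaksets):
        raise ValueError("level1 must parallel peaksets")
    level1 = [replace(ms, strategy=strategy) for ms in level1]

    root = np.random.SeedSequence([0 if seed is None else seed, 0x22])
    level2_seeds = root.spawn(2)

    def second_level(subset: "list[MapSet]", child) -> MapSet:
        pooled = np.concatenate([ms.maps for ms in subset], axis=0)
        out, assign = _cluster(pooled, k, algorithm, restarts, child)
        return replace(out, strategy=strategy,
                       channel_labels=subset[0].channel_labels,
                       gev_on_source=gev(pooled, out, assign), seed=seed)

    if reference is None and strategy != "global":
        # anchor labels on this run's own global solution
        reference = second_level(level1, level2_seeds[1])
        reference = replace(reference,
                            labels=tuple(string.ascii_uppercase[i] for i in range(k)))

    if strategy == "global":
        out = second_level(level1, level2_seeds[0])
        if reference is not None:
            out = replace(match_labels(out, reference),
                          algorithm=algorithm, strategy=strategy,
                          gev_on_source=out.gev_on_source, seed=seed)
        else:
            out = replace(out, labels=tuple(string.ascii_uppercase[i] for i in range(k)))
        return {"global": out}

    if strategy == "by_session":
        sessions = sorted({ps.session_id for ps in peaksets})
        result = {}
        for ses, child in zip(sessions,
                              np.random.SeedSequence([0 if seed is None
                                                      else seed, 1]).spawn(
                                                          len(sessions))):
            subset = [ms for ms, ps in zip(level1, peaksets)
                      if ps.session_id == ses]
            ms = second_level(subset, child)
            result[ses] = replace(match_labels(ms, reference),
                                  algorithm=algorithm, strategy=strategy,
                                  gev_on_source=ms.gev_on_source, seed=seed)
        return result

    # by_recording
    result = {}
    for ms, ps in zip(level1, peaksets):
        matched = replace(match_labels(ms, reference),
                          algorithm=algorithm, strategy=strategy,
                          gev_on_source=ms.gev_on_source, seed=seed)
        result[(ps.subject_id, ps.session_id)] = matched
    return result
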
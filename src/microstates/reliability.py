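"""Test-retest reliability statistics and topographic permutation testing.

The unit of analysis is a subjects × K matrix of repeated measurements of
one feature (one class, one derivation strategy): K sessions for
test-retest reliability, or K analysis methods for cross-method
consistency.  From it we compute

* Cronbach's α — K/(K−1) · (1 − Σᵢ σ²ᵢ / σ²_Y), with σ²ᵢ the sample
  variance of measurement i over subjects and σ²_Y the variance of the
  per-subject sums.  α equals the ICC(3,k) intraclass correlation of the
  two-way (subject × measurement) ANOVA.
* SEM — the standard error of measurement, √MS_error of the same ANOVA;
  an absolute error in feature units.
* SDC₉₅ — the smallest detectable change, 1.96·√2·SEM: the smallest
  within-subject change distinguishable from measurement error with 95%
  confidence.

TANOVA compares mean topographies between two paired sets of maps with
the global map dissimilarity (GMD) as test statistic, building the null
distribution by randomly swapping each subject's pair of maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topography import gfp_normalize, gmd

__all__ = [
    "ReliabilityResult",
    "TanovaResult",
    "cronbach_alpha",
    "anova_mean_squares",
    "sem",
    "icc",
    "smallest_detectable_change",
    "tanova",
    "reliability_report",
    "feature_correlations",
    "power_regression",
]

logger = logging.getLogger(__name__)

SDC_FACTOR = 1.96 * np.sqrt(2.0)


def _as_matrix(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need a (subjects >= 2) × (measurements >= 2) matrix")
    if np.isnan(matrix).any():
        raise ValueError("matrix contains missing cells; apply listwise "
                         "deletion upstream")
    return matrix


def cronbach_alpha(matrix: np.ndarray) -> float:
    """Cronbach's α of a subjects × K measurement matrix.

    Returns NaN (with a log entry) when the between-subject variance of
    the summed scores is zero, where α is undefined.
    """
    matrix = _as_matrix(matrix)
    k = matrix.shape[1]
    item_var = matrix.var(axis=0, ddof=1)
    total_var = matrix.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        logger.warning("cronbach_alpha: zero variance of subject totals; "
                       "alpha undefined")
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def anova_mean_squares(matrix: np.ndarray) -> tuple[float, float, float]:
    """(MS_subjects, MS_measurements, MS_error) of the two-way
    subject × measurement decomposition without replication."""
    matrix = _as_matrix(matrix)
    n, k = matrix.shape
    grand = matrix.mean()
    row = matrix.mean(axis=1, keepdims=True)
    col = matrix.mean(axis=0, keepdims=True)
    ss_rows = k * float(((row - grand) ** 2).sum())
    ss_cols = n * float(((col - grand) ** 2).sum())
    ss_err = float(((matrix - row - col + grand) ** 2).sum())
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def sem(matrix: np.ndarray) -> float:
    """Standard error of measurement: √MS_error of the two-way ANOVA.

    Zero when all within-subject change is a shared session effect (a
    pure column shift), consistent with α treating such shifts as
    reliable.
    """
    _, _, ms_err = anova_mean_squares(matrix)
    return float(np.sqrt(ms_err))


def icc(matrix: np.ndarray, kind: str = "3k") -> float:
    """ICC(3,1) or ICC(3,k) from the ANOVA mean squares (fixed raters,
    consistency).  ICC(3,k) is numerically identical to Cronbach's α."""
    ms_r, _, ms_e = anova_mean_squares(matrix)
    k = np.asarray(matrix).shape[1]
    if kind == "3k":
        return float((ms_r - ms_e) / ms_r) if ms_r > 0 else float("nan")
    if kind == "31":
        denom = ms_r + (k - 1) * ms_e
        return float((ms_r - ms_e) / denom) if denom > 0 else float("nan")
    raise ValueError(f"unknown ICC kind {kind!r}")


def smallest_detectable_change(sem_value: float, z: float = 1.96) -> float:
    """Smallest detectable change: z·√2·SEM (95% two-sided by default)."""
    return float(z * np.sqrt(2.0) * sem_value)


@dataclass
class ReliabilityResult:
    mean: float
    sd: float
    cronbach_alpha: float
    sem: float
    sem_pct: float
    sdc95: float
    n_subjects: int
    k: int


def _reliability_from_matrix(matrix: np.ndarray) -> ReliabilityResult:
    matrix = _as_matrix(matrix)
    s = sem(matrix)
    mean = float(matrix.mean())
    return ReliabilityResult(
        mean=mean,
        sd=float(matrix.std(ddof=1)),
        cronbach_alpha=cronbach_alpha(matrix),
        sem=s,
        sem_pct=100.0 * s / abs(mean) if mean != 0 else float("nan"),
        sdc95=smallest_detectable_change(s),
        n_subjects=matrix.shape[0],
        k=matrix.shape[1],
    )


@dataclass
class TanovaResult:
    observed_gmd: float
    p_value: float
    n_permutations: int
    seed: "int | None" = None


def tanova(group1: np.ndarray, group2: np.ndarray,
           permutations: int = 5000,
           seed: "int | None" = None) -> TanovaResult:
    """Paired topographic randomization test between two sets of maps.

    *group1* and *group2* are (n_subjects, n_channels) arrays of paired
    per-subject maps.  All maps are GFP-normalized and sign-aligned to
    the dominant topography of the pooled data (the first principal
    component — the polarity-invariant grand mean) before averaging.  The
    test statistic is the GMD between the GFP-normalized group-average
    maps; the null distribution swaps each subject's pair at random.
    Permuted statistics at least as large as the observed one count
    toward p, so identical groups give p = 1.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 2:
        raise ValueError("groups must be equal-shape (n_subjects, n_channels)")
    if g1.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    n, n_ch = g1.shape
    g1 = np.array([gfp_normalize(m) for m in g1])
    g2 = np.array([gfp_normalize(m) for m in g2])

    pooled = np.concatenate([g1, g2], axis=0)
    _, _, vt = np.linalg.svd(pooled, full_matrices=False)
    anchor = vt[0]
    g1 *= np.where(g1 @ anchor < 0, -1.0, 1.0)[:, None]
    g2 *= np.where(g2 @ anchor < 0, -1.0, 1.0)[:, None]

    def stat(m1: np.ndarray, m2: np.ndarray) -> float:
        return gmd(gfp_normalize(m1), gfp_normalize(m2))

    observed = stat(g1.mean(axis=0), g2.mean(axis=0))

    rng = np.random.default_rng(seed)
    swap = rng.integers(0, 2, size=(permutations, n)).astype(bool)
    delta = (g2 - g1) / n  # moving subject i's pair across groups
    base1 = g1.mean(axis=0)
    base2 = g2.mean(axis=0)
    m1 = base1 + swap @ delta
    m2 = base2 - swap @ delta

    def norm_rows(mat: np.ndarray) -> np.ndarray:
        c = mat - mat.mean(axis=1, keepdims=True)
        g = np.sqrt(np.mean(c**2, axis=1, keepdims=True))
        g[g == 0] = 1.0
        return c / g

    diffs = norm_rows(m1) - norm_rows(m2)
    stats = np.sqrt(np.mean(diffs**2, axis=1))
    p = float(np.mean(stats >= observed - 1e-12))
    return TanovaResult(observed_gmd=observed, p_value=p,
                        n_permutations=permutations, seed=seed)


def reliability_report(features: pd.DataFrame,
                       value_columns: "tuple[str, ...]" = (
                           "mean_lifespan_ms", "frequency_hz", "coverage"),
                       measurement: str = "session") -> pd.DataFrame:
    """Tables-style reliability report from a long-format feature table.

    For every (montage, strategy, algorithm, feature, class) cell the
    subjects × *measurement* matrix is pivoted, rows with missing values
    are dropped (listwise, logged), and mean, SD, Cronbach's α, SEM
    (also as % of mean) and SDC₉₅ are reported.  The coverage "All" row
    is constant 1 and therefore skipped.
    """
    required = {"subject", measurement, "class"}
    if missing := required - set(features.columns):
        raise ValueError(f"feature table lacks column(s) {sorted(missing)}")
    group_cols = [c for c in ("montage", "strategy", "algorithm")
                  if c in features.columns and c != measurement]
    rows = []
    for keys, block in features.groupby(group_cols + ["class"], sort=True,
                                        dropna=False):
        keys = dict(zip(group_cols + ["class"], keys))
        for col in value_columns:
            if col == "coverage" and keys["class"] == "All":
                continue
            pivot = block.pivot_table(index="subject", columns=measurement,
                                      values=col, aggfunc="mean")
            complete = pivot.dropna()
            if (lost := len(pivot) - len(complete)):
                logger.info("reliability_report: %s/%s dropped %d incomplete "
                            "subject(s)", keys, col, lost)
            if len(complete) < 2 or complete.shape[1] < 2:
                continue
            res = _reliability_from_matrix(complete.to_numpy())
            rows.append({**keys, "feature": col, "mean": res.mean,
                         "sd": res.sd, "alpha": res.cronbach_alpha,
                         "sem": res.sem, "sem_pct": res.sem_pct,
                         "sdc95": res.sdc95, "n_subjects": res.n_subjects,
                         "k": res.k})
    return pd.DataFrame(rows)


def feature_correlations(features: pd.DataFrame,
                         classes: "tuple[str, ...]" = ("A", "B", "C", "D"),
                         ) -> pd.DataFrame:
    """Pearson correlations between paired feature columns over recordings.

    Reports, per class, lifespan vs frequency, and all between-class
    pairs of lifespans and of frequencies — mirroring the standard
    observation that dwell time and rate are mechanically inversely
    linked within a class.
    """
    wide_life = features.pivot_table(index=["subject", "session"],
                                     columns="class",
                                     values="mean_lifespan_ms")
    wide_freq = features.pivot_table(index=["subject", "session"],
                                     columns="class", values="frequency_hz")
    rows = []
    for c in classes:
        r = wide_life[c].corr(wide_freq[c])
        rows.append({"kind": "lifespan_vs_frequency", "pair": f"{c}", "r": r})
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            rows.append({"kind": "lifespan_vs_lifespan", "pair": f"{a}-{b}",
                         "r": wide_life[a].corr(wide_life[b])})
            rows.append({"kind": "frequency_vs_frequency", "pair": f"{a}-{b}",
                         "r": wide_freq[a].corr(wide_freq[b])})
    return pd.DataFrame(rows)


def power_regression(features: pd.DataFrame, band_powers: pd.DataFrame,
                     response: str = "mean_lifespan_ms") -> dict:
    """OLS of an overall ("All"-class) microstate feature on the four
    relative band powers, one observation per recording.

    Zero-variance regressors are dropped with a warning; near-perfect
    collinearity is flagged via the design-matrix condition number.
    Returns the fitted statsmodels results plus coefficient/p-value
    tables.
    """
    import statsmodels.api as sm

    y_tab = features[features["class"] == "All"][["subject", "session",
                                                  response]]
    x_tab = band_powers.pivot_table(index=["subject", "session"],
                                    columns="band",
                                    values="relative_power").reset_index()
    merged = y_tab.merge(x_tab, on=["subject", "session"]).dropna()
    bands = [c for c in ("delta", "theta", "alpha", "beta")
             if c in merged.columns]
    kept = []
    for b in bands:
        if merged[b].var() < 1e-15 * max(1.0, merged[b].mean() ** 2):
            logger.warning("power_regression: dropping zero-variance "
                           "regressor %r", b)
        else:
            kept.append(b)
    if not kept:
        raise ValueError("no usable band-power regressors")
    X = sm.add_constant(merged[kept])
    fit = sm.OLS(merged[response], X).fit()
    collinear = bool(np.linalg.cond(X.to_numpy()) > 1e10)
    if collinear:
        logger.warning("power_regression: design matrix is (near-)perfectly "
                       "collinear; coefficients are not identifiable")
    return {
        "response": response,
        "params": fit.params,
        "pvalues": fit.pvalues,
        "r_squared": float(fit.rsquared),
        "collinear": collinear,
        "n": int(fit.nobs),
        "fit": fit,
    }
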
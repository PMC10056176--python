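"""Cross-sample statistics on orientation-angle series.

A sample is summarized by its series of N orientation angles (degrees on
[0, 180)).  Samples are compared with:

* box/violin summaries (quartiles, 1.5-IQR whiskers and outliers, Gaussian
  KDE with Silverman bandwidth);
* Pearson and Spearman correlation of paired series;
* a chi-square goodness-of-fit statistic between the two series after
  rescaling the angles to [0, 180) — by default the paired comparison of the
  sorted (quantile-matched) values with the second series as expectation and
  N - 1 degrees of freedom; a binned-histogram variant with shared Sturges
  bins is available;
* PCA of the standardized angle matrix (correlation-matrix PCA: every
  variable is reduced to mean 0, SD 1 so it contributes equally) with a
  descriptive separation report of the sample centroids in the first two
  component scores.

Angles are treated as plain linear values by default, mirroring the common
practice of reading the recorded angle lists directly; a circular option
(statistics on the doubled angles) is available and is statistically the
sounder choice for orientations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .roiorient import AngleSeries
from .shapestats import sturges_bins

__all__ = [
    "DistributionSummary",
    "PairwiseStats",
    "PcaResult",
    "summarize_distribution",
    "pairwise_stats",
    "pca_angles",
    "separation_report",
]


@dataclass
class DistributionSummary:
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    kde_curve: tuple[np.ndarray, np.ndarray] | None
    degenerate: bool = False


@dataclass
class PairwiseStats:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    chi2_stat: float
    chi2_p: float
    chi2_df: int
    notes: list = field(default_factory=list)


@dataclass
class PcaResult:
    loadings: np.ndarray  # components x variables
    scores: np.ndarray  # observations x components
    explained_variance_ratio: np.ndarray
    dropped_columns: list = field(default_factory=list)


def _angles(series) -> np.ndarray:
    a = series.angles if isinstance(series, AngleSeries) else np.asarray(series, float)
    return np.asarray(a, dtype=float) % 180.0


def summarize_distribution(series) -> DistributionSummary:
    """Boxplot quantities plus the violin density curve.

    Quartiles use linear interpolation; outliers are the points beyond
    1.5*IQR from the box; whiskers reach the most extreme non-outliers.
    An all-identical series has IQR 0, no outliers and a flagged degenerate
    (skipped) KDE.
    """
    a = _angles(series)
    if len(a) < 4:
        raise ValueError("need at least 4 angles")
    q25, med, q75 = np.percentile(a, [25, 50, 75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = (a >= lo_fence) & (a <= hi_fence)
    outliers = a[~inside]
    whisk_lo = float(a[inside].min())
    whisk_hi = float(a[inside].max())
    degenerate = np.ptp(a) == 0
    kde_curve = None
    if not degenerate:
        kde = stats.gaussian_kde(a, bw_method="silverman")
        grid = np.linspace(a.min() - 3 * kde.factor * a.std(),
                           a.max() + 3 * kde.factor * a.std(), 256)
        kde_curve = (grid, kde(grid))
    return DistributionSummary(
        median=float(med), q25=float(q25), q75=float(q75),
        whisker_low=whisk_lo, whisker_high=whisk_hi,
        outliers=outliers, kde_curve=kde_curve, degenerate=bool(degenerate))


def pairwise_stats(a, b, chi2_mode: str = "paired",
                   eps: float = 1e-9) -> PairwiseStats:
    """Pearson, Spearman and chi-square comparison of two equal-length series.

    chi2_mode='paired': chi2 = sum_i (a_(i) - b_(i))^2 / b_(i) over the
    sorted values with b as the expectation, two-sided p at N-1 df.
    chi2_mode='binned': classical histogram goodness-of-fit on shared
    Sturges bins (b's scaled counts as expectation).
    """
    xa, xb = _angles(a), _angles(b)
    if len(xa) != len(xb):
        raise ValueError("series lengths differ")
    n = len(xa)
    notes: list[str] = []

    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        r, rp = math.nan, math.nan
        rho, sp = math.nan, math.nan
        notes.append("zero-variance series: correlations undefined")
    else:
        r, rp = stats.pearsonr(xa, xb)
        rho, sp = stats.spearmanr(xa, xb)

    if chi2_mode == "paired":
        sa, sb = np.sort(xa), np.sort(xb)
        expect = sb.copy()
        if (expect < eps).any():
            notes.append("chi2 expectation floored at eps for zero terms")
            expect = np.maximum(expect, eps)
        chi2 = float(((sa - sb) ** 2 / expect).sum())
        df = n - 1
    elif chi2_mode == "binned":
        k = sturges_bins(n)
        lo = min(xa.min(), xb.min())
        hi = max(xa.max(), xb.max())
        edges = np.linspace(lo, hi + 1e-9, k + 1)
        obs, _ = np.histogram(xa, bins=edges)
        exp, _ = np.histogram(xb, bins=edges)
        expf = np.maximum(exp.astype(float), eps)
        expf *= obs.sum() / expf.sum()
        chi2 = float(((obs - expf) ** 2 / expf).sum())
        df = k - 1
    else:
        raise ValueError("chi2_mode must be 'paired' or 'binned'")
    cdf = stats.chi2.cdf(chi2, df)
    chi2_p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))

    return PairwiseStats(pearson_r=float(r), pearson_p=float(rp),
                         spearman_rho=float(rho), spearman_p=float(sp),
                         chi2_stat=chi2, chi2_p=chi2_p, chi2_df=df,
                         notes=notes)


def pca_angles(matrix: np.ndarray, standardize: bool = True) -> PcaResult:
    """PCA of a samples x angle-variables matrix.

    With ``standardize`` each column is reduced to mean 0, SD 1 and the
    decomposition is of the correlation matrix, so every angle variable
    contributes equally.  Zero-variance columns are dropped with a warning.
    Sign convention: the largest-magnitude loading of each component is
    positive.  Explained-variance ratios sum to 1 and are non-increasing.
    """
    import warnings

    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 observations and >= 2 variables")
    if np.isnan(x).any():
        raise ValueError("matrix holds missing values")

    sd = x.std(axis=0)
    dropped = list(np.nonzero(sd == 0)[0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance column(s)")
        x = x[:, sd > 0]
        sd = sd[sd > 0]
        if x.shape[1] < 2:
            raise ValueError("fewer than 2 variables after dropping constants")
    z = x - x.mean(axis=0)
    if standardize:
        z = z / sd
    cov = z.T @ z / z.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    loadings = evecs[:, order].T  # components x variables
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
    scores = z @ loadings.T
    total = evals.sum()
    ratio = evals / total if total > 0 else evals
    return PcaResult(loadings=loadings, scores=scores,
                     explained_variance_ratio=ratio, dropped_columns=dropped)


def separation_report(series_by_sample: dict) -> dict:
    """Descriptive separation of samples in the first-two-component plane.

    ``series_by_sample`` maps sample id -> AngleSeries or list of replicate
    AngleSeries.  Each replicate becomes one observation whose variables are
    its sorted angles (sorting aligns the series as empirical quantiles).
    Reports pairwise Euclidean centroid distances in the 2-D score plane, the
    mean within-sample distance to the centroid, and a silhouette-style
    separation score; purely descriptive, no inference.
    """
    if len(series_by_sample) < 2:
        raise ValueError("need at least 2 samples")
    labels: list = []
    rows: list[np.ndarray] = []
    for sid, item in series_by_sample.items():
        reps = item if isinstance(item, (list, tuple)) else [item]
        for rep in reps:
            rows.append(np.sort(_angles(rep)))
            labels.append(sid)
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("all angle series must share the same length N")
    x = np.vstack(rows)

    sd = x.std(axis=0)
    if (sd > 0).sum() >= 2:
        pca = pca_angles(x, standardize=True)
        sc = pca.scores[:, :2]
        explained = float(pca.explained_variance_ratio[:2].sum())
    else:  # identical samples: no variance anywhere
        sc = np.zeros((len(rows), 2))
        explained = 0.0

    labels_arr = np.asarray(labels, dtype=object)
    ids = list(dict.fromkeys(labels))
    centroids = {s: sc[labels_arr == s].mean(axis=0) for s in ids}
    pair_dist = {
        (s1, s2): float(np.linalg.norm(centroids[s1] - centroids[s2]))
        for s1, s2 in combinations(ids, 2)
    }
    within = []
    for s in ids:
        pts = sc[labels_arr == s]
        if len(pts) > 1:
            within.extend(np.linalg.norm(pts - centroids[s], axis=1).tolist())
    mean_within = float(np.mean(within)) if within else 0.0

    silhouette = math.nan
    if len(ids) >= 2 and len(rows) > len(ids):
        try:
            from sklearn.metrics import silhouette_score
            silhouette = float(silhouette_score(sc, labels_arr.astype(str)))
        except ValueError:
            pass

    return {
        "samples": ids,
        "scores_2d": sc,
        "labels": labels,
        "centroid_distances": pair_dist,
        "mean_within_sample_distance": mean_within,
        "min_between_distance": min(pair_dist.values()),
        "silhouette": silhouette,
        "explained_first2": explained,
    }
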
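"""Population-average distance matrices and power-law statistics.

The central quantity is the mean pairwise spatial distance between probe
regions across many single-chromosome traces, summarized as an R x R
matrix, and its power-law fit

    d(g) = a * g**s

where ``g`` is genomic separation in Mb, ``a`` is the step size (mean
spatial distance at 1 Mb, in µm) and ``s`` the scaling exponent.  A random
walk has s = 0.5; a fractal globule ~0.3; C. elegans chromosomes sit near
0.2.  Group comparisons are made on the log scale with the linear model

    Y = b0 + b1*X + b2*G + b3*(X*G) + e

(Y = log mean distance, X = log genomic distance, G = group indicator), so
b2 tests a step-size difference and b3 an exponent difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .core import Trace
from .tracing import pairwise_distance_matrix

__all__ = [
    "MeanDistanceMatrix",
    "PowerLawFit",
    "GroupRegression",
    "mean_distance_matrix",
    "fit_power_law",
    "normalize_observed_expected",
    "compare_power_laws",
    "pairwise_difference_map",
    "replicate_correlation",
]


@dataclass
class MeanDistanceMatrix:
    """Region x region mean spatial distances with measurement counts.

    ``valid`` marks entries supported by more than the pair-count
    threshold; the diagonal is never valid.
    """

    mean: np.ndarray
    counts: np.ndarray
    valid: np.ndarray
    region_coords: np.ndarray  # Mb
    region_ids: np.ndarray
    min_regions: int = 7
    min_pair_count: int = 22

    @property
    def n_regions(self) -> int:
        return self.mean.shape[0]

    def pairs(self):
        """Yield (i, j, genomic separation Mb, mean distance µm) over the
        valid upper triangle."""
        iu, ju = np.triu_indices(self.n_regions, k=1)
        for i, j in zip(iu, ju):
            if self.valid[i, j]:
                g = abs(self.region_coords[j] - self.region_coords[i])
                yield i, j, g, self.mean[i, j]


@dataclass
class PowerLawFit:
    """Power-law parameters with 95% confidence intervals.

    ``a`` is in µm (distance at 1 Mb); ``s`` is dimensionless.  The log-log
    linear fit (slope, intercept) used for hypothesis testing is carried
    alongside the natural-scale nonlinear fit.
    """

    a: float
    s: float
    ci95_a: tuple
    ci95_s: tuple
    n_pairs: int
    loglog_slope: float
    loglog_intercept: float

    def expected(self, g):
        """Expected distance at genomic separation ``g`` Mb."""
        return self.a * np.asarray(g, dtype=float) ** self.s


@dataclass
class GroupRegression:
    """OLS coefficients of the log-log group-comparison model."""

    params: np.ndarray  # b0, b1, b2, b3
    bse: np.ndarray
    pvalues: np.ndarray
    resid_var: float

    @property
    def beta2(self) -> float:
        return float(self.params[2])

    @property
    def beta3(self) -> float:
        return float(self.params[3])


def mean_distance_matrix(
    traces: list[Trace],
    region_coords: np.ndarray,
    min_regions: int = 7,
    min_pair_count: int = 22,
) -> MeanDistanceMatrix:
    """Average per-trace pairwise distances across a trace population.

    Traces observing fewer than ``min_regions`` regions are dropped
    (hybridization-quality filter), and matrix entries supported by fewer
    than ``min_pair_count`` measurements are masked.  Excluded traces
    (``exclusion_reason != 'none'``) never contribute.
    """
    region_coords = np.asarray(region_coords, dtype=float)
    kept = [
        t for t in traces if not t.excluded and t.n_observed >= min_regions
    ]
    if kept:
        region_ids = kept[0].region_ids
        n = region_ids.size
    else:
        region_ids = np.arange(1, region_coords.size + 1)
        n = region_coords.size
    if region_coords.size != n:
        raise ValueError("region_coords length does not match region set")

    total = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for t in kept:
        d = pairwise_distance_matrix(t)
        obs = ~np.isnan(d)
        total[obs] += d[obs]
        counts[obs] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    valid = counts >= min_pair_count
    np.fill_diagonal(valid, False)
    mean[~valid] = np.nan
    return MeanDistanceMatrix(
        mean, counts, valid, region_coords, region_ids,
        min_regions=min_regions, min_pair_count=min_pair_count,
    )


def _valid_pairs(matrix: MeanDistanceMatrix):
    g = np.array([p[2] for p in matrix.pairs()])
    d = np.array([p[3] for p in matrix.pairs()])
    return g, d


def _nls_point_estimate(g, d):
    logg, logd = np.log(g), np.log(d)
    slope, intercept = np.polyfit(logg, logd, 1)
    p0 = (float(np.exp(intercept)), float(slope))
    popt, pcov = optimize.curve_fit(
        lambda x, a, s: a * x**s, g, d, p0=p0, maxfev=10000
    )
    return popt, pcov, slope, intercept


def _jackknife_se(traces, matrix, n_groups):
    """Delete-group jackknife standard errors of (a, s) over traces.

    The matrix entries all derive from the same traces and are strongly
    correlated, so the curve-fit covariance understates the sampling
    variance of the estimates; resampling whole traces captures it.
    """
    dms = [pairwise_distance_matrix(t) for t in traces]
    n = matrix.mean.shape[0]
    groups = [[] for _ in range(min(n_groups, len(dms)))]
    for i, dm in enumerate(dms):
        groups[i % len(groups)].append(dm)
    g_sum = np.zeros((len(groups), n, n))
    g_cnt = np.zeros((len(groups), n, n))
    for k, grp in enumerate(groups):
        for dm in grp:
            obs = ~np.isnan(dm)
            g_sum[k][obs] += dm[obs]
            g_cnt[k][obs] += 1
    tot_sum, tot_cnt = g_sum.sum(axis=0), g_cnt.sum(axis=0)
    gsep = np.abs(matrix.region_coords[None, :] - matrix.region_coords[:, None])
    iu = np.triu_indices(n, k=1)
    estimates = []
    for k in range(len(groups)):
        cnt = (tot_cnt - g_cnt[k])[iu]
        ok = cnt > 0
        mean = (tot_sum - g_sum[k])[iu][ok] / cnt[ok]
        try:
            popt, *_ = _nls_point_estimate(gsep[iu][ok], mean)
        except RuntimeError:
            continue
        estimates.append(popt)
    est = np.asarray(estimates)
    if est.shape[0] < 3:
        return None
    G = est.shape[0]
    return np.sqrt((G - 1) / G * ((est - est.mean(axis=0)) ** 2).sum(axis=0))


def fit_power_law(
    matrix: MeanDistanceMatrix,
    traces: list[Trace] | None = None,
    n_jackknife_groups: int = 50,
) -> PowerLawFit:
    """Fit ``d = a * g**s`` to the valid entries of a mean-distance matrix.

    The point estimate is nonlinear least squares on the natural scale,
    initialized from the log-log OLS line.  95% CIs come from the
    curve-fit parameter covariance by default; when the underlying trace
    population is supplied the CIs are computed instead by a delete-group
    jackknife over traces, which accounts for the correlation between
    matrix entries sharing traces (the covariance-based intervals are
    anti-conservative in that setting).  The log-log line is reported
    alongside for regression-based comparisons.
    """
    g, d = _valid_pairs(matrix)
    if g.size < 3 or np.unique(g).size < 3:
        raise ValueError("need >= 3 valid pairs at distinct genomic separations")
    popt, pcov, slope, intercept = _nls_point_estimate(g, d)
    a_hat, s_hat = float(popt[0]), float(popt[1])
    se = np.sqrt(np.diag(pcov))
    if traces is not None:
        kept = [
            t for t in traces
            if not t.excluded and t.n_observed >= matrix.min_regions
        ]
        jk = _jackknife_se(kept, matrix, n_jackknife_groups)
        if jk is not None:
            se = jk
    z = stats.norm.ppf(0.975)
    return PowerLawFit(
        a=a_hat,
        s=s_hat,
        ci95_a=(a_hat - z * se[0], a_hat + z * se[0]),
        ci95_s=(s_hat - z * se[1], s_hat + z * se[1]),
        n_pairs=int(g.size),
        loglog_slope=float(slope),
        loglog_intercept=float(intercept),
    )


def normalize_observed_expected(
    matrix: MeanDistanceMatrix, fit: PowerLawFit
) -> np.ndarray:
    """Observed / expected ratio matrix under the power-law fit.

    Ratios below 1 mark region pairs closer together than the polymer
    baseline predicts (folding); above 1, further apart.  Masked entries
    propagate as NaN.
    """
    g = np.abs(matrix.region_coords[None, :] - matrix.region_coords[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = fit.a * g**fit.s
        ratio = matrix.mean / expected
    ratio[~matrix.valid] = np.nan
    return ratio


def compare_power_laws(
    matrix_a: MeanDistanceMatrix, matrix_b: MeanDistanceMatrix
) -> GroupRegression:
    """Test step-size and exponent differences between two populations.

    OLS of log mean distance on log genomic distance, a group indicator
    (0 = A, 1 = B) and their interaction.  ``beta2`` is the log step-size
    ratio, ``beta3`` the exponent difference s_B - s_A.
    """
    ga, da = _valid_pairs(matrix_a)
    gb, db = _valid_pairs(matrix_b)
    y = np.log(np.concatenate([da, db]))
    x = np.log(np.concatenate([ga, gb]))
    grp = np.concatenate([np.zeros(ga.size), np.ones(gb.size)])
    design = sm.add_constant(np.column_stack([x, grp, x * grp]))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(y, design).fit()
    return GroupRegression(
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        pvalues=np.asarray(res.pvalues),
        resid_var=float(res.mse_resid),
    )


def pairwise_difference_map(
    traces_a: list[Trace],
    traces_b: list[Trace],
    region_coords: np.ndarray,
    min_pair_count: int = 22,
    normalized: bool = False,
    test: str = "ranksum",
    alpha: float = 0.05,
):
    """Per-pair group differences with multiplicity-adjusted significance.

    For each region pair the difference of group means is computed (raw
    distances, or observed/expected ratios when ``normalized``) together
    with a two-sided test p-value (Wilcoxon rank-sum by default, Welch
    t-test with ``test='ttest'``), adjusted across pairs by
    Benjamini-Hochberg.  Pairs below ``min_pair_count`` in either group are
    masked (NaN).

    Returns ``(delta, qvalues)`` as R x R arrays.
    """
    region_coords = np.asarray(region_coords, dtype=float)
    n = region_coords.size

    def collect(traces):
        per_pair = [[[] for _ in range(n)] for _ in range(n)]
        for t in traces:
            if t.excluded:
                continue
            d = pairwise_distance_matrix(t)
            for i in range(n):
                for j in range(i + 1, n):
                    if not np.isnan(d[i, j]):
                        per_pair[i][j].append(d[i, j])
        return per_pair

    pa, pb = collect(traces_a), collect(traces_b)
    if normalized:
        fa = fit_power_law(mean_distance_matrix(traces_a, region_coords,
                                                min_pair_count=min_pair_count))
        fb = fit_power_law(mean_distance_matrix(traces_b, region_coords,
                                                min_pair_count=min_pair_count))

    delta = np.full((n, n), np.nan)
    pvals = np.full((n, n), np.nan)
    flat_p, flat_ij = [], []
    for i in range(n):
        for j in range(i + 1, n):
            xa = np.asarray(pa[i][j])
            xb = np.asarray(pb[i][j])
            if xa.size < min_pair_count or xb.size < min_pair_count:
                continue
            g = abs(region_coords[j] - region_coords[i])
            if normalized:
                xa = xa / fa.expected(g)
                xb = xb / fb.expected(g)
            delta[i, j] = delta[j, i] = xb.mean() - xa.mean()
            if test == "ranksum":
                p = stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
            elif test == "ttest":
                p = stats.ttest_ind(xa, xb, equal_var=False).pvalue
            else:
                raise ValueError(f"unknown test {test!r}")
            pvals[i, j] = pvals[j, i] = p
            flat_p.append(p)
            flat_ij.append((i, j))

    qvalues = np.full((n, n), np.nan)
    if flat_p:
        _, q, _, _ = multipletests(flat_p, alpha=alpha, method="fdr_bh")
        for (i, j), qi in zip(flat_ij, q):
            qvalues[i, j] = qvalues[j, i] = qi
    return delta, qvalues


def replicate_correlation(
    matrix_a: MeanDistanceMatrix, matrix_b: MeanDistanceMatrix
) -> float:
    """Pearson r between two mean-distance matrices over jointly valid
    upper-triangle entries (replicate agreement)."""
    if matrix_a.n_regions != matrix_b.n_regions:
        raise ValueError("matrices must share the region set")
    iu, ju = np.triu_indices(matrix_a.n_regions, k=1)
    joint = matrix_a.valid[iu, ju] & matrix_b.valid[iu, ju]
    if joint.sum() < 3:
        raise ValueError("need >= 3 jointly valid entries")
    r, _ = stats.pearsonr(
        matrix_a.mean[iu, ju][joint], matrix_b.mean[iu, ju][joint]
    )
    return float(r)
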
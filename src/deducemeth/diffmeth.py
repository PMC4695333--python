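"""Differential methylation between two sample groups.

Site-level testing uses an empirical-Bayes moderated t-statistic: per-site
two-group fits give a residual variance s^2 with d degrees of freedom; a
scaled inverse-chi-square prior (d0, s0^2) is estimated across sites by
moment matching on log variances, and the posterior variance
s~^2 = (d0 s0^2 + d s^2) / (d0 + d) replaces s^2 in the t-statistic, which
is referred to a t-distribution with d0 + d degrees of freedom.  P-values
are FDR-adjusted (Benjamini-Hochberg); adjusted site p-values inside a
fragment are combined with a coverage-weighted extension of Fisher's
method, and fragments are priority-ranked by the worst of their p-value,
log-fold-change and absolute-difference ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ModerationParams:
    """Empirical-Bayes shrinkage hyperparameters.

    ``prior_df`` and ``prior_variance`` are normally estimated from the data
    (method of moments on log variances); setting ``prior_df=0`` recovers
    the ordinary pooled-variance two-sample t-test.  ``epsilon`` guards the
    log-fold-change of proportions against log(0).
    """

    prior_df: float | None = None  # None = estimate from data
    prior_variance: float | None = None
    epsilon: float = 0.01


@dataclass
class SiteTestResult:
    site: tuple
    group_means: tuple[float, float]
    diff: float
    log_fold_change: float
    t_statistic: float
    p_value: float
    adjusted_p: float = float("nan")


@dataclass
class FragmentTestResult:
    fragment_id: str
    combined_p: float
    mean_diff: float
    log_fold_change: float
    mean_coverage: float = float("nan")
    rank_p: int = 0
    rank_lfc: int = 0
    rank_diff: int = 0

    @property
    def combined_rank(self) -> int:
        return max(self.rank_p, self.rank_lfc, self.rank_diff)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-10:
            break
    return x


def estimate_prior(
    variances: np.ndarray, dfs: np.ndarray
) -> tuple[float, float]:
    """Moment-match the scaled-F distribution of residual variances.

    Returns (d0, s0^2); d0 may be ``inf`` when the observed log variances
    are no more dispersed than sampling noise alone predicts.
    """
    ok = (variances > 0) & (dfs > 0)
    v = variances[ok]
    d = dfs[ok]
    if v.size < 2:
        return 0.0, float(np.median(variances)) if variances.size else 1.0
    z = np.log(v)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, d / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        # no excess dispersion beyond sampling noise: all sites share one
        # variance, whose pooled estimate is the arithmetic mean
        d0 = math.inf
        s0_sq = float(np.mean(v))
    return d0, s0_sq


def moderated_t_test(
    matrix: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    params: ModerationParams | None = None,
) -> list[SiteTestResult]:
    """Moderated two-group t-test per site (row) of a levels matrix.

    ``groups`` maps the two group labels to their sample (column) lists, in
    the order defining the sign of the difference (group1 - group2).  Sites
    with fewer than two observations in either group are skipped.
    """
    params = params or ModerationParams()
    labels = list(groups)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    g1 = matrix[list(groups[labels[0]])].to_numpy(dtype=float)
    g2 = matrix[list(groups[labels[1]])].to_numpy(dtype=float)

    n1 = np.sum(~np.isnan(g1), axis=1)
    n2 = np.sum(~np.isnan(g2), axis=1)
    usable = (n1 >= 2) & (n2 >= 2)
    if not usable.any():
        raise ValueError("insufficient replication: no site has >=2 observations per group")

    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(np.where(np.isnan(g1), np.nan, g1), axis=1)
        m2 = np.nanmean(np.where(np.isnan(g2), np.nan, g2), axis=1)
        v1 = np.nanvar(g1, axis=1, ddof=1)
        v2 = np.nanvar(g2, axis=1, ddof=1)
    dfs = n1 + n2 - 2
    pooled = ((n1 - 1) * np.nan_to_num(v1) + (n2 - 1) * np.nan_to_num(v2)) / np.where(
        dfs > 0, dfs, 1
    )

    if params.prior_df is None:
        d0, s0_sq = estimate_prior(pooled[usable], dfs[usable].astype(float))
    else:
        d0 = params.prior_df
        s0_sq = params.prior_variance if params.prior_variance is not None else 1.0

    results = []
    eps = params.epsilon
    # the moderated t cannot be better informed than pooling every residual
    df_pooled = float(np.sum(dfs[usable]))
    for i in np.nonzero(usable)[0]:
        d = float(dfs[i])
        s_sq = float(pooled[i])
        if math.isinf(d0):
            s_tilde_sq = s0_sq
            df_total = df_pooled
        else:
            s_tilde_sq = (d0 * s0_sq + d * s_sq) / (d0 + d)
            df_total = min(d0 + d, df_pooled)
        diff = float(m1[i] - m2[i])
        se = math.sqrt(s_tilde_sq * (1.0 / n1[i] + 1.0 / n2[i]))
        if se == 0:
            t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        else:
            t = diff / se
        if math.isinf(df_total):
            p = 2.0 * stats.norm.sf(abs(t))
        else:
            p = 2.0 * stats.t.sf(abs(t), df_total)
        num, den = m1[i] + eps, m2[i] + eps
        lfc = math.log2(num / den) if num > 0 and den > 0 else float("nan")
        results.append(
            SiteTestResult(
                site=matrix.index[i],
                group_means=(float(m1[i]), float(m2[i])),
                diff=diff,
                log_fold_change=lfc,
                t_statistic=float(t),
                p_value=min(1.0, float(p)),
            )
        )
    pvals = [r.p_value for r in results]
    adjusted = adjust_fdr(pvals)
    for r, a in zip(results, adjusted):
        r.adjusted_p = a
    return results


def adjust_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment (stable w.r.t. input order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def combine_fragment_pvalues(
    site_p: Sequence[float],
    weights: Sequence[float] | None = None,
    method: str = "weighted",
) -> float:
    """Combine per-site p-values into one fragment p-value.

    ``fisher``: X = -2 sum(ln p) ~ chi2 with 2k df.  ``weighted`` (default):
    the Makambi-style statistic K = sum(w_i * -2 ln p_i) with normalized
    weights, whose null is approximated by a scaled chi-square matching the
    mean (2) and variance (4 sum w_i^2); with equal weights it reduces
    exactly to Fisher.  Zero p-values are clamped to the smallest positive
    float.
    """
    p = np.asarray(site_p, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    tiny = np.finfo(float).tiny
    p = np.clip(p, tiny, 1.0)
    if method == "fisher":
        x = -2.0 * np.sum(np.log(p))
        return float(stats.chi2.sf(x, 2 * p.size))
    if method != "weighted":
        raise ValueError(f"unknown method {method!r}")
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        w = w / w.sum()
    k_stat = float(np.sum(w * (-2.0 * np.log(p))))
    sum_w_sq = float(np.sum(w**2))
    scale = sum_w_sq  # variance / (2 * mean) = 4*sum(w^2) / 4
    df = 2.0 / sum_w_sq  # 2 * mean^2 / variance
    return float(stats.chi2.sf(k_stat / scale, df))


def evaluate_fragments(
    site_results: Sequence[SiteTestResult],
    site_coverage: Mapping[tuple, float] | None = None,
    method: str = "weighted",
    epsilon: float = 0.01,
) -> list[FragmentTestResult]:
    """Fragment-level statistics from site results.

    Sites are grouped by the fragment_id component of their site key;
    combination weights are site coverages when provided.  mean_diff and the
    log-fold-change derive from the fragment's mean group levels.
    """
    by_frag: dict[str, list[SiteTestResult]] = {}
    for r in site_results:
        frag_id = r.site[0] if isinstance(r.site, tuple) else str(r.site)
        by_frag.setdefault(frag_id, []).append(r)
    out = []
    for frag_id in sorted(by_frag):
        members = by_frag[frag_id]
        ps = [m.adjusted_p for m in members]
        if site_coverage is not None:
            ws = [float(site_coverage.get(m.site, 1.0)) for m in members]
        else:
            ws = None
        combined = combine_fragment_pvalues(ps, ws, method=method)
        m1 = float(np.mean([m.group_means[0] for m in members]))
        m2 = float(np.mean([m.group_means[1] for m in members]))
        cov = float(np.mean(ws)) if ws else float("nan")
        out.append(
            FragmentTestResult(
                fragment_id=frag_id,
                combined_p=combined,
                mean_diff=m1 - m2,
                log_fold_change=math.log2((m1 + epsilon) / (m2 + epsilon)),
                mean_coverage=cov,
            )
        )
    return out


def rank_fragments(results: Sequence[FragmentTestResult]) -> list[FragmentTestResult]:
    """Worst-of-three priority ranking.

    Competition ranks (ties share the minimum rank) are assigned for
    combined_p ascending, |log fold change| descending and |mean difference|
    descending; the representative rank is the worst of the three.  The
    returned list is ordered by combined_rank, then combined_p, then
    fragment_id.
    """
    if not results:
        return []
    p = np.array([r.combined_p for r in results])
    lfc = np.array([abs(r.log_fold_change) for r in results])
    diff = np.array([abs(r.mean_diff) for r in results])
    rank_p = stats.rankdata(p, method="min")
    rank_lfc = stats.rankdata(-lfc, method="min")
    rank_diff = stats.rankdata(-diff, method="min")
    for r, rp, rl, rd in zip(results, rank_p, rank_lfc, rank_diff):
        r.rank_p = int(rp)
        r.rank_lfc = int(rl)
        r.rank_diff = int(rd)
    return sorted(results, key=lambda r: (r.combined_rank, r.combined_p, r.fragment_id))


def select_top_fragments(
    ranked: Sequence[FragmentTestResult],
    sequences: Mapping[str, str],
    n: int = 500,
    min_mean_coverage: float = 2.0,
    max_adjusted_p: float = 0.05,
) -> dict[str, list[tuple[str, str]]]:
    """Top differentially methylated fragments per direction, for export.

    Gates: mean coverage strictly greater than ``min_mean_coverage`` and
    combined p strictly below ``max_adjusted_p``; then the top ``n`` by
    combined rank are split by the sign of the mean difference (``hyper_group1``
    vs ``hyper_group2``).  Returns direction -> [(fragment_id, sequence)].
    """
    import warnings

    eligible = [
        r
        for r in ranked
        if r.mean_coverage > min_mean_coverage and r.combined_p < max_adjusted_p
    ]
    top = eligible[:n]
    if not top:
        warnings.warn("no fragments pass the coverage/significance gates")
    out: dict[str, list[tuple[str, str]]] = {"hyper_group1": [], "hyper_group2": []}
    for r in top:
        direction = "hyper_group1" if r.mean_diff > 0 else "hyper_group2"
        out[direction].append((r.fragment_id, sequences[r.fragment_id]))
    return out


def site_results_table(results: Sequence[SiteTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fragment_id": r.site[0] if isinstance(r.site, tuple) else r.site,
                "position": r.site[1] if isinstance(r.site, tuple) and len(r.site) > 1 else -1,
                "mean_group1": r.group_means[0],
                "mean_group2": r.group_means[1],
                "diff": r.diff,
                "log_fold_change": r.log_fold_change,
                "t_statistic": r.t_statistic,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
            }
            for r in results
        ]
    )


def fragment_results_table(results: Sequence[FragmentTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fragment_id": r.fragment_id,
                "combined_p": r.combined_p,
                "mean_diff": r.mean_diff,
                "log_fold_change": r.log_fold_change,
                "mean_coverage": r.mean_coverage,
                "rank_p": r.rank_p,
                "rank_lfc": r.rank_lfc,
                "rank_diff": r.rank_diff,
                "combined_rank": r.combined_rank,
            }
            for r in results
        ]
    )
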
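"""Transitions in mean-FRI category between adjacent exams.

For each tooth group and adjacent age pair, units (participants or
teeth) are cross-tabulated by their baseline and follow-up mean-FRI
categories on the pairwise-aligned zone set. Cell uncertainty is a 95%
Wilson score interval at the person level (cells with at least 10
participants) and a cluster-robust interval from an intercept-only
logistic model with a sandwich variance at the tooth level, where
teeth of one participant are correlated.

Whether severity declines is tested per baseline category with
one-sided Wilcoxon signed-rank tests on the *actual* mean-FRI
differences (follow-up minus baseline), not the category changes; a
cluster-adjusted variant — ranks computed across all observations, the
statistic's variance estimated from cluster-level sums of signed ranks
— handles the tooth level. A bleaching sensitivity analysis compares
the differences between participants who did and did not report
bleaching/whitening product use, with (clustered) rank-sum tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit
from statsmodels.stats.proportion import proportion_confint

from .fri_data import CohortDataset, ToothGroupName
from .severity import (
    AlignedZoneSet,
    MeanFriCategory,
    align_zones,
    categorize_mean_fri_array,
    person_means,
    tooth_means,
)

__all__ = [
    "SignedRankResult",
    "RankSumResult",
    "TransitionTable",
    "DegenerateProportionError",
    "wilson_ci",
    "cluster_robust_proportion_ci",
    "signed_rank_decline",
    "clustered_signed_rank_decline",
    "rank_sum",
    "clustered_rank_sum",
    "transition_table",
    "pairwise_unit_changes",
    "bleaching_sensitivity",
]

MIN_CELL_FOR_CI = 10  # person-level Wilson CIs only for cells this large


# ---------------------------------------------------------------------------
# binomial proportion intervals


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """95% (by default) Wilson score interval for a binomial proportion.

    The interval inverts the binomial score test; its lower bound is
    exactly 0 when ``successes`` is 0 and its upper bound exactly 1
    when ``successes == n``.
    """
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: successes={successes}, n={n}")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    # the score interval hits the boundary exactly at 0/n successes;
    # clamp the floating-point evaluation to the algebraic value
    if successes == 0:
        lo = 0.0
    if successes == n:
        hi = 1.0
    return float(lo), float(hi)


class DegenerateProportionError(ValueError):
    """Pooled proportion is 0 or 1; the logit-scale interval is undefined."""


def cluster_robust_proportion_ci(
    outcomes: Sequence[int] | np.ndarray,
    cluster_ids: Sequence,
    level: float = 0.95,
) -> tuple[float, float]:
    """Cluster-robust CI for a proportion from an intercept-only logit model.

    Fits ``logit(p) = b0`` to binary outcomes and estimates ``var(b0)``
    with the cluster-sandwich estimator ``A^-1 B A^-1`` where
    ``A = n p(1-p)`` (the information) and ``B = sum_g S_g^2`` with
    ``S_g`` the cluster sums of score residuals ``y - p``. The Wald
    interval on the logit scale is back-transformed. With all clusters
    of size 1 this is the ordinary Wald-on-logit interval with variance
    ``1 / (n p (1-p))``.
    """
    y = np.asarray(outcomes, dtype=float)
    g = np.asarray(cluster_ids)
    if y.size < 1 or y.size != g.size:
        raise ValueError("outcomes and cluster_ids must be equal-length, non-empty")
    p = float(y.mean())
    if p <= 0.0 or p >= 1.0:
        raise DegenerateProportionError(
            f"pooled proportion {p} admits no logit-scale interval"
        )
    resid = y - p
    cluster_sums = pd.Series(resid).groupby(g).sum().to_numpy()
    a = y.size * p * (1 - p)
    b = float((cluster_sums**2).sum())
    se_logit = np.sqrt(b) / a
    zcrit = stats.norm.ppf(0.5 + level / 2)
    lo, hi = expit(logit(p) - zcrit * se_logit), expit(logit(p) + zcrit * se_logit)
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# signed-rank tests for decline

EXACT_SIGNED_RANK_MAX_N = 25


@dataclass(frozen=True)
class SignedRankResult:
    """One-sided Wilcoxon signed-rank test for declining scores.

    ``statistic`` is the sum of signed ranks T = W+ − W−; negative
    values indicate more / larger decreases than increases. ``p`` is
    one-sided for the alternative "differences tend negative": exact
    (``P(W+ <= w)`` over all sign assignments) for small samples,
    normal with midrank tie correction otherwise. ``z`` is always the
    normal-approximation statistic T / sqrt(sum r_i^2).
    """

    statistic: float
    z: float
    p_one_sided: float
    n_nonzero: int
    method: str  # "exact" | "normal" | "none"
    clustered: bool = False

    @property
    def valid(self) -> bool:
        return self.method != "none"


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks of |d| and signs for nonzero differences (zeros dropped)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    return ranks, np.sign(d)


def _exact_wplus_cdf(ranks: np.ndarray, wplus: float) -> float:
    """P(W+ <= wplus) under random signs, by convolution over 2*ranks."""
    doubled = np.rint(2 * ranks).astype(int)  # midranks -> integers
    dist = np.zeros(doubled.sum() + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = 0.5 * dist + 0.5 * shifted
    cutoff = int(np.floor(2 * wplus + 1e-9))
    return float(dist[: cutoff + 1].sum())


def signed_rank_decline(
    diffs: Sequence[float] | np.ndarray,
    exact_max_n: int = EXACT_SIGNED_RANK_MAX_N,
) -> SignedRankResult:
    """One-sided Wilcoxon signed-rank test that differences tend negative.

    Zero differences are dropped before ranking; ties are midranked.
    With at most ``exact_max_n`` nonzero differences the p-value comes
    from exact enumeration of the 2^n equiprobable sign assignments
    (``P(W+ <= observed)``); above that, from the normal approximation
    ``z = T / sqrt(sum r_i^2)``, which equals the classical
    tie-corrected variance formula. All-zero input yields a flagged
    no-test result.
    """
    ranks, signs = _signed_ranks(diffs)
    n = ranks.size
    if n == 0:
        return SignedRankResult(
            statistic=0.0, z=0.0, p_one_sided=float("nan"), n_nonzero=0, method="none"
        )
    t_stat = float((signs * ranks).sum())
    z = t_stat / np.sqrt(float((ranks**2).sum()))
    if n <= exact_max_n:
        wplus = float(ranks[signs > 0].sum())
        p = _exact_wplus_cdf(ranks, wplus)
        method = "exact"
    else:
        p = float(stats.norm.cdf(z))
        method = "normal"
    return SignedRankResult(
        statistic=t_stat, z=float(z), p_one_sided=p, n_nonzero=n, method=method
    )


def clustered_signed_rank_decline(
    diffs: Sequence[float] | np.ndarray,
    cluster_ids: Sequence,
) -> SignedRankResult:
    """Cluster-adjusted one-sided signed-rank test for decline.

    Signed midranks are computed across *all* nonzero differences; the
    statistic is their total T and its null variance is estimated from
    the cluster-level sums ``S_g`` as ``sum_g S_g^2``, which is valid
    under intra-cluster correlation because the cluster sums are
    independent with zero mean under the null of symmetric differences.
    With every cluster of size 1 the test reduces exactly to the
    unclustered normal approximation.
    """
    d = np.asarray(diffs, dtype=float)
    g = np.asarray(cluster_ids)
    if d.size != g.size:
        raise ValueError("diffs and cluster_ids must be equal length")
    keep = d != 0
    d, g = d[keep], g[keep]
    if d.size == 0:
        return SignedRankResult(
            statistic=0.0, z=0.0, p_one_sided=float("nan"), n_nonzero=0,
            method="none", clustered=True,
        )
    if np.unique(g).size < 2:
        raise ValueError("clustered signed-rank needs >= 2 clusters with nonzero diffs")
    ranks = stats.rankdata(np.abs(d))
    signed = np.sign(d) * ranks
    cluster_sums = pd.Series(signed).groupby(g).sum().to_numpy()
    t_stat = float(cluster_sums.sum())
    var = float((cluster_sums**2).sum())
    z = t_stat / np.sqrt(var)
    return SignedRankResult(
        statistic=t_stat,
        z=float(z),
        p_one_sided=float(stats.norm.cdf(z)),
        n_nonzero=int(d.size),
        method="normal",
        clustered=True,
    )


# ---------------------------------------------------------------------------
# rank-sum tests (bleaching sensitivity)


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided (clustered) Wilcoxon rank-sum comparison of two groups."""

    statistic: float
    z: float
    p_two_sided: float
    n1: int
    n0: int
    clustered: bool = False


def rank_sum(values1, values0) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test via centered midranks.

    ``z = S / sqrt(n1 n0 sum c_i^2 / (N (N-1)))`` where ``S`` sums the
    centered ranks of group 1; this equals the classical tie-corrected
    normal approximation (no continuity correction).
    """
    v1 = np.asarray(values1, dtype=float)
    v0 = np.asarray(values0, dtype=float)
    if v1.size == 0 or v0.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([v1, v0])
    labels = np.concatenate([np.ones(v1.size, dtype=int), np.zeros(v0.size, dtype=int)])
    return _rank_sum_from_clusters(pooled, labels, np.arange(pooled.size))


def clustered_rank_sum(values, group_labels, cluster_ids) -> RankSumResult:
    """Cluster-adjusted two-sided rank-sum test.

    The group label must be constant within each cluster (e.g. a
    participant-level exposure with teeth as observations). Centered
    midranks are summed per cluster; the group-1 total is compared to
    its permutation variance over cluster-label reassignments,
    ``m1 m0 sum_g C_g^2 / (m (m-1))``. With all clusters of size 1 this
    reduces exactly to :func:`rank_sum`.
    """
    v = np.asarray(values, dtype=float)
    x = np.asarray(group_labels, dtype=int)
    g = np.asarray(cluster_ids)
    if not (v.size == x.size == g.size):
        raise ValueError("values, group_labels and cluster_ids must be equal length")
    per_cluster_groups = pd.Series(x).groupby(g).nunique()
    if (per_cluster_groups > 1).any():
        raise ValueError("group label must be constant within each cluster")
    res = _rank_sum_from_clusters(v, x, g)
    return RankSumResult(
        statistic=res.statistic, z=res.z, p_two_sided=res.p_two_sided,
        n1=res.n1, n0=res.n0, clustered=True,
    )


def _rank_sum_from_clusters(values, group_labels, cluster_ids) -> RankSumResult:
    centered = stats.rankdata(values) - (values.size + 1) / 2.0
    frame = pd.DataFrame({"c": centered, "x": group_labels, "g": cluster_ids})
    by_cluster = frame.groupby("g").agg(csum=("c", "sum"), x=("x", "first"))
    m = len(by_cluster)
    m1 = int((by_cluster["x"] == 1).sum())
    m0 = m - m1
    if m1 == 0 or m0 == 0:
        raise ValueError("both groups must contain at least one cluster")
    if m < 2:
        raise ValueError("variance inestimable with a single cluster")
    s = float(by_cluster.loc[by_cluster["x"] == 1, "csum"].sum())
    var = m1 * m0 * float((by_cluster["csum"] ** 2).sum()) / (m * (m - 1))
    if var == 0:
        z, p = 0.0, 1.0
    else:
        z = s / np.sqrt(var)
        p = 2.0 * float(stats.norm.sf(abs(z)))
    n1 = int((np.asarray(group_labels) == 1).sum())
    return RankSumResult(
        statistic=s, z=float(z), p_two_sided=p, n1=n1,
        n0=int(np.asarray(values).size - n1),
    )


# ---------------------------------------------------------------------------
# transition tables


@dataclass
class TransitionTable:
    """Baseline × follow-up mean-FRI category counts for one age pair.

    ``counts`` is a 4×4 frame (baseline rows, follow-up columns);
    ``cell_cis`` maps (baseline, follow-up) category pairs to 95%
    intervals for the within-stratum transition proportion where the
    eligibility rule holds, else None; ``signed_rank`` maps each
    baseline category with data to its decline test.
    """

    group: ToothGroupName
    level: Literal["person", "tooth"]
    age_pair: tuple[int, int]
    counts: pd.DataFrame
    proportions: pd.DataFrame
    cell_cis: dict = field(default_factory=dict)
    signed_rank: dict = field(default_factory=dict)
    n_units: int = 0

    def to_tidy(self) -> pd.DataFrame:
        """One row per cell: counts, row-wise proportions and CI bounds."""
        rows = []
        for b in self.counts.index:
            for f in self.counts.columns:
                ci = self.cell_cis.get((b, f))
                rows.append(
                    {
                        "group": self.group.value,
                        "level": self.level,
                        "baseline_age": self.age_pair[0],
                        "followup_age": self.age_pair[1],
                        "baseline_cat": int(b),
                        "followup_cat": int(f),
                        "count": int(self.counts.loc[b, f]),
                        "proportion": float(self.proportions.loc[b, f]),
                        "ci_lo": np.nan if ci is None else float(ci[0]),
                        "ci_hi": np.nan if ci is None else float(ci[1]),
                    }
                )
        return pd.DataFrame(rows)


def pairwise_unit_changes(
    aligned: AlignedZoneSet,
    level: Literal["person", "tooth"],
) -> pd.DataFrame:
    """Per-unit mean FRI at both ages of a pairwise alignment.

    Returns one row per unit with columns ``cluster_id`` (participant),
    ``baseline``, ``followup``, ``diff`` (follow-up − baseline, on the
    actual score scale), ``baseline_cat`` and ``followup_cat``.
    """
    if aligned.mode != "pairwise" or len(aligned.ages) != 2:
        raise ValueError("transition analysis requires a pairwise alignment")
    base_age, follow_age = aligned.ages
    means = person_means(aligned) if level == "person" else tooth_means(aligned)
    if means.empty:
        raise ValueError("empty aligned set: no units to tabulate")
    out = pd.DataFrame(
        {
            "baseline": means[base_age].to_numpy(),
            "followup": means[follow_age].to_numpy(),
        }
    )
    if level == "person":
        out["cluster_id"] = means.index.to_numpy()
        out["unit_id"] = means.index.to_numpy()
    else:
        out["cluster_id"] = means.index.get_level_values("participant_id").to_numpy()
        out["unit_id"] = [f"{p}:{t}" for p, t in means.index]
    out["diff"] = out["followup"] - out["baseline"]
    out["baseline_cat"] = categorize_mean_fri_array(out["baseline"])
    out["followup_cat"] = categorize_mean_fri_array(out["followup"])
    return out


def transition_table(
    data: CohortDataset,
    group: ToothGroupName | str,
    level: Literal["person", "tooth"],
    age_pair: tuple[int, int],
    ci_level: float = 0.95,
) -> TransitionTable:
    """Cross-tabulate baseline vs follow-up mean-FRI categories.

    Units are pairwise-aligned participants (person level) or teeth
    (tooth level). Person-level cells with at least 10 participants get
    Wilson score CIs for the within-stratum transition proportion;
    tooth-level cells get cluster-robust logit intervals (teeth
    clustered by participant) where the pooled proportion is
    non-degenerate. Each baseline stratum with data gets a one-sided
    signed-rank decline test — cluster-adjusted at the tooth level.
    """
    group = ToothGroupName(group)
    aligned = align_zones(data, group, ages=tuple(age_pair), mode="pairwise")
    units = pairwise_unit_changes(aligned, level)
    cat_levels = [int(c) for c in MeanFriCategory]
    counts = (
        pd.crosstab(units["baseline_cat"], units["followup_cat"])
        .reindex(index=cat_levels, columns=cat_levels, fill_value=0)
    )
    row_totals = counts.sum(axis=1)
    proportions = counts.div(row_totals.replace(0, np.nan), axis=0)

    cell_cis: dict = {}
    signed_rank: dict = {}
    for b in cat_levels:
        stratum = units[units["baseline_cat"] == b]
        n_row = int(row_totals[b])
        if n_row == 0:
            continue
        for f in cat_levels:
            k = int(counts.loc[b, f])
            if level == "person":
                if k >= MIN_CELL_FOR_CI:
                    cell_cis[(b, f)] = wilson_ci(k, n_row, level=ci_level)
                else:
                    cell_cis[(b, f)] = None
            else:
                try:
                    cell_cis[(b, f)] = cluster_robust_proportion_ci(
                        (stratum["followup_cat"] == f).astype(int).to_numpy(),
                        stratum["cluster_id"].to_numpy(),
                        level=ci_level,
                    )
                except (DegenerateProportionError, ValueError):
                    cell_cis[(b, f)] = None
        diffs = stratum["diff"].to_numpy()
        if level == "tooth" and stratum["cluster_id"].nunique() >= 2:
            signed_rank[b] = clustered_signed_rank_decline(
                diffs, stratum["cluster_id"].to_numpy()
            )
        else:
            signed_rank[b] = signed_rank_decline(diffs)

    return TransitionTable(
        group=group,
        level=level,
        age_pair=tuple(age_pair),
        counts=counts,
        proportions=proportions,
        cell_cis=cell_cis,
        signed_rank=signed_rank,
        n_units=len(units),
    )


# ---------------------------------------------------------------------------
# bleaching / whitening sensitivity analysis


def bleaching_sensitivity(
    changes: pd.DataFrame,
    level: Literal["person", "tooth"],
) -> pd.DataFrame:
    """Compare mean-FRI changes between bleaching users and non-users.

    ``changes`` has one row per unit with columns ``unit_id``,
    ``cluster_id``, ``baseline_cat``, ``diff`` and boolean
    ``bleach_group``; strata are the baseline categories. Person-level
    strata use a plain two-sided rank-sum test, tooth-level strata the
    cluster-adjusted variant. Strata with an empty group are reported
    as skipped with a reason. The ``n_tests_in_family`` column carries
    the family size for the multiple-comparisons caveat (no formal
    correction is applied).
    """
    required = {"unit_id", "cluster_id", "baseline_cat", "diff", "bleach_group"}
    missing = required - set(changes.columns)
    if missing:
        raise ValueError(f"changes is missing columns {sorted(missing)}")
    strata = sorted(changes["baseline_cat"].unique())
    results = []
    for b in strata:
        sub = changes[changes["baseline_cat"] == b]
        users = sub[sub["bleach_group"].astype(bool)]
        nonusers = sub[~sub["bleach_group"].astype(bool)]
        row = {
            "level": level,
            "baseline_cat": int(b),
            "n_bleach": len(users),
            "n_none": len(nonusers),
            "mean_diff_bleach": users["diff"].mean() if len(users) else np.nan,
            "mean_diff_none": nonusers["diff"].mean() if len(nonusers) else np.nan,
        }
        if len(users) == 0 or len(nonusers) == 0:
            row.update(z=np.nan, p_two_sided=np.nan, skipped="empty group in stratum")
        else:
            try:
                if level == "tooth":
                    res = clustered_rank_sum(
                        sub["diff"].to_numpy(),
                        sub["bleach_group"].astype(int).to_numpy(),
                        sub["cluster_id"].to_numpy(),
                    )
                else:
                    res = rank_sum(users["diff"].to_numpy(), nonusers["diff"].to_numpy())
                row.update(z=res.z, p_two_sided=res.p_two_sided, skipped=None)
            except ValueError as exc:
                row.update(z=np.nan, p_two_sided=np.nan, skipped=str(exc))
        results.append(row)
    out = pd.DataFrame(results)
    out["n_tests_in_family"] = int(out["skipped"].isna().sum())
    return out
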
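"""Ordinal association and inter-examiner agreement statistics.

The trend of severity with exam age is measured with Goodman and
Kruskal's gamma on an ordered age × ordered severity-category count
table:

    gamma = (C - D) / (C + D)

where C and D count concordant and discordant observation pairs; tied
pairs contribute to neither. Person-level inference uses the standard
asymptotic variance of gamma; tooth-level inference uses a
within-participant permutation scheme, since teeth of one mouth are
correlated and the asymptotic variance would be too small.

Inter-examiner reliability on the duplicate-exam subset is summarized
by unweighted Cohen's kappa for each examiner pair and the mean over
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "GammaResult",
    "KappaResult",
    "gk_gamma",
    "gamma_asymptotic",
    "gamma_asymptotic_se",
    "gamma_cluster_permutation",
    "pairwise_kappa",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Ordered row-level × ordered column-level count matrix.

    Rows are exam ages (increasing) and columns severity categories
    (increasing severity) in this package's use, but any two ordinal
    axes work.
    """

    counts: np.ndarray
    row_levels: tuple
    col_levels: tuple

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.shape != (len(self.row_levels), len(self.col_levels)):
            raise ValueError("level lists do not match the count matrix shape")

    @classmethod
    def from_counts(cls, counts, row_levels=None, col_levels=None) -> "ContingencyTable":
        counts = np.asarray(counts)
        if row_levels is None:
            row_levels = tuple(range(counts.shape[0]))
        if col_levels is None:
            col_levels = tuple(range(counts.shape[1]))
        return cls(counts=counts, row_levels=tuple(row_levels), col_levels=tuple(col_levels))

    @classmethod
    def from_observations(cls, rows, cols, row_levels=None, col_levels=None) -> "ContingencyTable":
        """Cross-tabulate paired ordinal observations."""
        tab = pd.crosstab(pd.Series(rows), pd.Series(cols))
        if row_levels is not None:
            tab = tab.reindex(index=list(row_levels), fill_value=0)
        if col_levels is not None:
            tab = tab.reindex(columns=list(col_levels), fill_value=0)
        return cls(
            counts=tab.to_numpy(),
            row_levels=tuple(tab.index),
            col_levels=tuple(tab.columns),
        )

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_levels), columns=list(self.col_levels))

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis(index="age").to_csv(str(path))

    @classmethod
    def read_csv(cls, path) -> "ContingencyTable":
        df = pd.read_csv(str(path), index_col=0)
        return cls(
            counts=df.to_numpy(dtype=int),
            row_levels=tuple(df.index),
            col_levels=tuple(df.columns),
        )


@dataclass(frozen=True)
class GammaResult:
    """Goodman–Kruskal gamma with optional standard error and normal test."""

    gamma: float
    concordant: float
    discordant: float
    se: float | None = None
    method: str | None = None  # "asymptotic" or "cluster_permutation"
    z: float | None = None
    p_two_sided: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


def _concordance_partners(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell counts of concordant (A) and discordant (B) partners.

    A[i, j] sums the counts in cells strictly below-right plus strictly
    above-left of (i, j); B[i, j] those below-left plus above-right.
    """
    c = np.asarray(counts, dtype=float)
    R, Cn = c.shape
    A = np.zeros_like(c)
    B = np.zeros_like(c)
    for i in range(R):
        for j in range(Cn):
            A[i, j] = c[:i, :j].sum() + c[i + 1:, j + 1:].sum()
            B[i, j] = c[:i, j + 1:].sum() + c[i + 1:, :j].sum()
    return A, B


def _gamma_cd(counts: np.ndarray) -> tuple[float, float]:
    A, B = _concordance_partners(counts)
    c = np.asarray(counts, dtype=float)
    # each pair counted twice in sum(n_ij * A_ij)
    return float((c * A).sum() / 2.0), float((c * B).sum() / 2.0)


def gk_gamma(table: ContingencyTable) -> GammaResult:
    """Goodman–Kruskal gamma point estimate with pair counts.

    Raises if every pair is tied (C + D = 0), e.g. when all counts sit
    in a single row or column.
    """
    C, D = _gamma_cd(table.counts)
    if C + D == 0:
        raise ValueError("gamma undefined: no untied pairs (C + D = 0)")
    return GammaResult(gamma=(C - D) / (C + D), concordant=C, discordant=D)


def gamma_asymptotic(table: ContingencyTable) -> GammaResult:
    """Gamma with its asymptotic standard error and two-sided normal p.

    Uses the Goodman–Kruskal variance
    ``var = 16 / (P+Q)^4 * sum_ij n_ij (Q*A_ij - P*B_ij)^2`` where
    ``P = sum_ij n_ij A_ij`` and ``Q = sum_ij n_ij B_ij`` are twice the
    concordant/discordant pair counts, and treats gamma / se as
    standard normal.
    """
    point = gk_gamma(table)
    C, D = point.concordant, point.discordant
    A, B = _concordance_partners(table.counts)
    c = np.asarray(table.counts, dtype=float)
    P, Q = 2.0 * C, 2.0 * D
    var = 16.0 / (P + Q) ** 4 * float((c * (Q * A - P * B) ** 2).sum())
    se = float(np.sqrt(var))
    if se == 0:
        z, p = (0.0, 1.0) if point.gamma == 0 else (np.inf * np.sign(point.gamma), 0.0)
    else:
        z = point.gamma / se
        p = 2.0 * float(stats.norm.sf(abs(z)))
    return GammaResult(
        gamma=point.gamma,
        concordant=C,
        discordant=D,
        se=se,
        method="asymptotic",
        z=float(z),
        p_two_sided=p,
    )


def gamma_asymptotic_se(table: ContingencyTable) -> float:
    """Asymptotic standard error of gamma (see :func:`gamma_asymptotic`)."""
    return gamma_asymptotic(table).se


def _pooled_gamma_from_codes(age_idx, cat_idx, n_ages, n_cats) -> float:
    counts = np.bincount(age_idx * n_cats + cat_idx, minlength=n_ages * n_cats)
    counts = counts.reshape(n_ages, n_cats)
    C, D = _gamma_cd(counts)
    if C + D == 0:
        return np.nan
    return (C - D) / (C + D)


def gamma_cluster_permutation(
    long_data: pd.DataFrame,
    n_perm: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GammaResult:
    """Gamma with a cluster-permutation standard error.

    ``long_data`` has one row per observation (e.g. one tooth at one
    wave) with columns ``cluster_id`` (participant), ``age`` and
    ``category``. The observed gamma comes from the pooled age ×
    category table. Null replicates permute the age labels *jointly
    within each cluster*: one random permutation of the wave labels per
    cluster per replicate, applied to all the cluster's observations,
    which preserves the within-cluster correlation structure while
    breaking any age–severity association. The replicate standard
    deviation is the standard error; gamma / se is treated as standard
    normal for the two-sided p.
    """
    if n_perm < 200:
        raise ValueError(f"n_perm must be at least 200, got {n_perm}")
    if rng is None:
        rng = np.random.default_rng(seed)

    df = pd.DataFrame(long_data)[["cluster_id", "age", "category"]]
    ages = np.sort(df["age"].unique())
    cats = np.sort(df["category"].unique())
    if len(ages) < 2 or len(cats) < 2:
        raise ValueError("need at least 2 ages and 2 categories")
    age_idx = np.searchsorted(ages, df["age"].to_numpy())
    cat_idx = np.searchsorted(cats, df["category"].to_numpy())
    cluster_codes, cluster_idx = np.unique(df["cluster_id"].to_numpy(), return_inverse=True)
    n_clusters, n_ages, n_cats = len(cluster_codes), len(ages), len(cats)

    observed = _pooled_gamma_from_codes(age_idx, cat_idx, n_ages, n_cats)
    if np.isnan(observed):
        raise ValueError("gamma undefined on the pooled table (C + D = 0)")

    reps = np.empty(n_perm)
    for b in range(n_perm):
        # one wave-label permutation per cluster, applied to all its rows
        perms = np.argsort(rng.random((n_clusters, n_ages)), axis=1)
        perm_age = perms[cluster_idx, age_idx]
        reps[b] = _pooled_gamma_from_codes(perm_age, cat_idx, n_ages, n_cats)

    se = float(np.std(reps[~np.isnan(reps)], ddof=1))
    if se == 0:
        z, p = (0.0, 1.0) if observed == 0 else (np.inf * np.sign(observed), 0.0)
    else:
        z = observed / se
        p = 2.0 * float(stats.norm.sf(abs(z)))
    C, D = _gamma_cd(
        np.bincount(age_idx * n_cats + cat_idx, minlength=n_ages * n_cats).reshape(
            n_ages, n_cats
        )
    )
    return GammaResult(
        gamma=float(observed),
        concordant=C,
        discordant=D,
        se=se,
        method="cluster_permutation",
        z=float(z),
        p_two_sided=p,
        n_permutations=n_perm,
        seed=seed,
    )


@dataclass(frozen=True)
class KappaResult:
    """Pairwise Cohen's kappas and their mean over examiner pairs."""

    pairwise_kappas: dict
    mean_kappa: float
    n_units: dict


def _cohen_kappa(a: Sequence, b: Sequence, categories: Sequence) -> float:
    """Unweighted Cohen's kappa for two raters over a fixed category set."""
    tab = pd.crosstab(
        pd.Categorical(a, categories=categories),
        pd.Categorical(b, categories=categories),
        dropna=False,
    ).to_numpy(dtype=float)
    n = tab.sum()
    po = np.trace(tab) / n
    pe = float(tab.sum(axis=1) @ tab.sum(axis=0)) / n**2
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1 - pe))


def pairwise_kappa(dup_exams: pd.DataFrame, categories: Sequence | None = None) -> KappaResult:
    """Mean pairwise Cohen's kappa over examiners on co-rated units.

    ``dup_exams`` has columns ``unit_id``, ``examiner_id``,
    ``category``; a unit is whatever was co-rated (a participant's
    person-level category, a tooth, a zone). Each examiner pair
    contributes an unweighted kappa over the units both rated; the
    result averages pairs with at least one co-rated unit.
    """
    df = pd.DataFrame(dup_exams)[["unit_id", "examiner_id", "category"]]
    if categories is None:
        categories = sorted(df["category"].unique())
    wide = df.pivot_table(
        index="unit_id", columns="examiner_id", values="category", aggfunc="first"
    )
    examiners = sorted(wide.columns)
    kappas: dict[tuple, float] = {}
    n_units: dict[tuple, int] = {}
    for i, e1 in enumerate(examiners):
        for e2 in examiners[i + 1:]:
            both = wide[[e1, e2]].dropna()
            if len(both) == 0:
                continue
            kappas[(e1, e2)] = _cohen_kappa(both[e1], both[e2], categories)
            n_units[(e1, e2)] = len(both)
    if not kappas:
        raise ValueError("no examiner pair shares a co-rated unit")
    return KappaResult(
        pairwise_kappas=kappas,
        mean_kappa=float(np.mean(list(kappas.values()))),
        n_units=n_units,
    )
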
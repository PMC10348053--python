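"""Transition tables, proportion CIs, and (clustered) rank tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fritrend.fri_data import Zone
from fritrend.transitions import (
    DegenerateProportionError,
    bleaching_sensitivity,
    cluster_robust_proportion_ci,
    clustered_rank_sum,
    clustered_signed_rank_decline,
    rank_sum,
    signed_rank_decline,
    transition_table,
    wilson_ci,
)
from fritrend.severity import summarize_severity
from fritrend.synthcohort import generate_cohort

from .conftest import manual_cohort, noiseless_params

Z4 = [Zone.incisal_third, Zone.middle_third, Zone.cervical_third, Zone.occlusal_incisal]


def exact_signed_rank_p(diffs):
    """Oracle: P(W+ <= observed) by enumerating all sign assignments."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = ranks[np.array(signs, dtype=bool)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            count += 1
    return count / total


class TestWilsonCi:
    def test_zero_successes_lower_bound_is_zero(self):
        lo, hi = wilson_ci(0, 10)
        assert lo == 0.0 and 0 < hi < 0.35

    def test_all_successes_upper_bound_is_one(self):
        lo, hi = wilson_ci(10, 10)
        assert hi == 1.0 and 0.65 < lo < 1

    def test_matches_closed_form_score_interval(self):
        z = stats.norm.ppf(0.975)
        p_hat, n = 0.5, 10
        center = (p_hat + z**2 / (2 * n)) / (1 + z**2 / n)
        half = (
            z
            * np.sqrt(p_hat * (1 - p_hat) / n + z**2 / (4 * n**2))
            / (1 + z**2 / n)
        )
        lo, hi = wilson_ci(5, 10)
        assert lo == pytest.approx(center - half, abs=1e-12)
        assert hi == pytest.approx(center + half, abs=1e-12)

    def test_contains_point_estimate_within_unit_interval(self):
        for k, n in [(1, 7), (3, 11), (12, 13)]:
            lo, hi = wilson_ci(k, n)
            assert 0 <= lo <= k / n <= hi <= 1

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            wilson_ci(5, 4)


class TestClusterRobustCi:
    def test_size_one_clusters_equal_wald_on_logit(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=80)
        lo, hi = cluster_robust_proportion_ci(y, np.arange(80))
        p = y.mean()
        se = np.sqrt(1 / (80 * p * (1 - p)))
        z = stats.norm.ppf(0.975)
        from scipy.special import expit, logit

        assert lo == pytest.approx(expit(logit(p) - z * se), abs=1e-12)
        assert hi == pytest.approx(expit(logit(p) + z * se), abs=1e-12)

    def test_matches_statsmodels_gee_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        clusters = np.repeat(np.arange(30), 4)
        theta = rng.normal(0, 1, 30)[clusters]
        y = (rng.random(120) < stats.norm.cdf(theta)).astype(int)
        lo, hi = cluster_robust_proportion_ci(y, clusters)
        gee = sm.GEE(
            y,
            np.ones((120, 1)),
            groups=clusters,
            family=sm.families.Binomial(),
        ).fit()
        g_lo, g_hi = gee.conf_int()[0]
        from scipy.special import expit

        assert lo == pytest.approx(expit(g_lo), rel=1e-6)
        assert hi == pytest.approx(expit(g_hi), rel=1e-6)

    def test_se_shrinks_with_sqrt_duplication(self):
        from scipy.special import logit

        y = np.array([1, 1, 0, 1, 0, 0, 0, 1])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])

        def logit_halfwidth(yv, gv):
            lo, hi = cluster_robust_proportion_ci(yv, gv)
            return (logit(hi) - logit(lo)) / 2

        w1 = logit_halfwidth(y, g)
        k = 4
        yk = np.tile(y, k)
        gk = np.concatenate([g + 2 * i for i in range(k)])
        assert logit_halfwidth(yk, gk) == pytest.approx(w1 / np.sqrt(k), rel=1e-9)

    def test_perfect_within_cluster_correlation_widens_interval(self):
        y_shared = np.repeat([1, 0, 1, 0, 1, 0, 0, 0], 5)  # clusters share outcomes
        g = np.repeat(np.arange(8), 5)
        lo_c, hi_c = cluster_robust_proportion_ci(y_shared, g)
        lo_i, hi_i = cluster_robust_proportion_ci(y_shared, np.arange(40))
        assert (hi_c - lo_c) > (hi_i - lo_i)

    def test_degenerate_proportion_raises(self):
        with pytest.raises(DegenerateProportionError):
            cluster_robust_proportion_ci(np.ones(10), np.arange(10))


class TestSignedRankDecline:
    def test_all_negative_five(self):
        res = signed_rank_decline([-1, -1, -1, -1, -1])
        assert res.p_one_sided == pytest.approx(1 / 32)
        assert res.statistic < 0 and res.method == "exact"

    def test_symmetric_diffs_center_the_statistic(self):
        res = signed_rank_decline([-1, 1, -2, 2])
        assert res.statistic == 0
        # the observed W+ sits at the distribution's center: CDF > 1/2 there
        assert res.p_one_sided == pytest.approx(exact_signed_rank_p([-1, 1, -2, 2]))

    def test_mirror_complement_identity(self):
        """p(d) + p(-d) = 1 + P(W+ = w) under exact enumeration."""
        diffs = [-0.3, 0.8, -1.1, 0.4, -0.6, 0.2, -0.2]
        p_neg = signed_rank_decline(diffs).p_one_sided
        p_pos = signed_rank_decline([-d for d in diffs]).p_one_sided
        # atom at the observed statistic, from the oracle distribution:
        # P(W+ <= w) - P(W+ <= w - smallest half-integer step)
        d = np.asarray(diffs)
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        atom = exact_signed_rank_p(diffs) - _cdf_below(diffs, w_obs - 0.5)
        assert p_neg + p_pos == pytest.approx(1 + atom)

    @pytest.mark.parametrize("n", [3, 6, 9, 12])
    def test_exact_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            diffs = np.round(rng.normal(-0.2, 1, size=n), 1)
            res = signed_rank_decline(diffs)
            if res.method == "none":
                continue
            assert res.p_one_sided == pytest.approx(exact_signed_rank_p(diffs))

    def test_large_sample_uses_tie_corrected_normal(self):
        rng = np.random.default_rng(0)
        diffs = np.round(rng.normal(-0.3, 1, size=80), 1)
        res = signed_rank_decline(diffs)
        assert res.method == "normal"
        d = diffs[diffs != 0]
        ranks = stats.rankdata(np.abs(d))
        t = (np.sign(d) * ranks).sum()
        assert res.z == pytest.approx(t / np.sqrt((ranks**2).sum()))

    def test_all_zero_diffs_flagged(self):
        res = signed_rank_decline([0.0, 0.0])
        assert res.method == "none" and np.isnan(res.p_one_sided)


def _cdf_below(diffs, w):
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = stats.rankdata(np.abs(d))
    count = total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        total += 1
        if ranks[np.array(signs, dtype=bool)].sum() <= w + 1e-9:
            count += 1
    return count / total


class TestClusteredSignedRank:
    def test_size_one_clusters_reduce_to_unclustered(self):
        rng = np.random.default_rng(7)
        diffs = rng.normal(-0.2, 1, size=40)
        plain = signed_rank_decline(diffs)
        clustered = clustered_signed_rank_decline(diffs, np.arange(40))
        assert abs(clustered.z - plain.z) < 1e-6

    def test_strong_decline_highly_significant(self):
        rng = np.random.default_rng(1)
        clusters = np.repeat(np.arange(20), 4)
        diffs = -np.abs(rng.normal(1, 0.2, size=80))
        res = clustered_signed_rank_decline(diffs, clusters)
        assert res.p_one_sided < 0.001 and res.statistic < 0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="cluster"):
            clustered_signed_rank_decline([-1, -2, 1], ["a", "a", "a"])

    def test_type_one_error_near_nominal(self):
        """One-sided rejection rate ~0.05 under a symmetric null."""
        rng = np.random.default_rng(2024)
        n_sims, alpha = 300, 0.05
        rejections = 0
        clusters = np.repeat(np.arange(25), 4)
        for _ in range(n_sims):
            shared = rng.normal(0, 1, 25)[clusters]
            diffs = shared * 0.7 + rng.normal(0, 1, 100)
            res = clustered_signed_rank_decline(diffs, clusters)
            rejections += res.p_one_sided < alpha
        rate = rejections / n_sims
        se = np.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rate - alpha) < 3 * se


class TestRankSum:
    def test_matches_scipy_mannwhitney_no_ties(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        res = rank_sum(a, b)
        u_p = stats.mannwhitneyu(a, b, alternative="two-sided", use_continuity=False).pvalue
        assert res.p_two_sided == pytest.approx(u_p, rel=1e-9)

    def test_clustered_size_one_reduces_to_plain(self):
        rng = np.random.default_rng(4)
        v = rng.normal(0, 1, 50)
        x = (rng.random(50) < 0.5).astype(int)
        if x.sum() in (0, 50):
            x[0] = 1 - x[0]
        plain = rank_sum(v[x == 1], v[x == 0])
        clust = clustered_rank_sum(v, x, np.arange(50))
        assert abs(clust.z - plain.z) < 1e-6

    def test_group_varying_within_cluster_rejected(self):
        with pytest.raises(ValueError, match="constant within"):
            clustered_rank_sum([1.0, 2.0], [0, 1], ["a", "a"])

    def test_power_against_location_shift(self):
        """Shift of 1 SD with n=50/50 is detected in >90% of simulations."""
        rng = np.random.default_rng(5)
        hits = 0
        n_sims = 200
        for _ in range(n_sims):
            a = rng.normal(1.0, 1, 50)
            b = rng.normal(0.0, 1, 50)
            hits += rank_sum(a, b).p_two_sided < 0.05
        assert hits / n_sims > 0.9

    def test_type_one_error_near_nominal_with_clusters(self):
        rng = np.random.default_rng(6)
        n_sims, alpha = 300, 0.05
        rejections = 0
        m = 30
        clusters = np.repeat(np.arange(m), 3)
        for _ in range(n_sims):
            shared = rng.normal(0, 1, m)[clusters]
            v = shared + rng.normal(0, 1, 3 * m)
            x_cluster = (rng.random(m) < 0.5).astype(int)
            if x_cluster.sum() in (0, m):
                x_cluster[0] = 1 - x_cluster[0]
            x = x_cluster[clusters]
            rejections += clustered_rank_sum(v, x, clusters).p_two_sided < alpha
        rate = rejections / n_sims
        se = np.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rate - alpha) < 3 * se


def _two_wave_cohort(fri_by_wave):
    """One tooth per participant; fri_by_wave: list of (fri9, fri13)."""
    rows = []
    for i, (f9, f13) in enumerate(fri_by_wave):
        pid = f"P{i}"
        for z in Z4:
            rows.append((pid, 9, "E1", 11, z, f9))
            rows.append((pid, 13, "E1", 11, z, f13))
    return manual_cohort(rows)


class TestTransitionTable:
    def test_unchanged_units_form_diagonal(self):
        data = _two_wave_cohort([(0, 0), (1, 1), (2, 2), (3, 3)] * 3)
        tab = transition_table(data, "maxillary_incisors", "person", (9, 13))
        off_diag = tab.counts.to_numpy() - np.diag(np.diag(tab.counts.to_numpy()))
        assert off_diag.sum() == 0 and tab.counts.to_numpy().sum() == 12

    def test_uniform_decline_fills_single_cell(self):
        # all participants move from mean FRI 0.25 (C1) to 0 (C0)
        rows = []
        for i in range(15):
            pid = f"P{i}"
            for z, f in zip(Z4, (1, 0, 0, 0)):
                rows.append((pid, 9, "E1", 11, z, f))
            for z in Z4:
                rows.append((pid, 13, "E1", 11, z, 0))
        tab = transition_table(manual_cohort(rows), "maxillary_incisors", "person", (9, 13))
        assert tab.counts.loc[1, 0] == 15
        assert tab.counts.to_numpy().sum() == 15

    def test_row_sums_match_pairwise_baseline_categories(self, small_cohort):
        tab = transition_table(small_cohort, "early_erupting", "person", (9, 13))
        assert tab.counts.to_numpy().sum() == tab.n_units
        # consistency with an all-ages summary restricted to the same pair
        summary = summarize_severity(small_cohort, "early_erupting", "person", ages=(9, 13))
        base_counts = summary[summary["age"] == 9].set_index("category")["count"]
        assert (tab.counts.sum(axis=1).to_numpy() == base_counts.to_numpy()).all()

    def test_person_level_ci_rule_is_ten_per_cell(self, small_cohort):
        tab = transition_table(small_cohort, "early_erupting", "person", (9, 13))
        for (b, f), ci in tab.cell_cis.items():
            if tab.counts.loc[b, f] >= 10:
                assert ci is not None and 0 <= ci[0] <= ci[1] <= 1
            else:
                assert ci is None

    def test_tooth_level_cis_respect_clustering(self, small_cohort):
        tab = transition_table(small_cohort, "early_erupting", "tooth", (9, 13))
        assert any(ci is not None for ci in tab.cell_cis.values())
        for res in tab.signed_rank.values():
            assert res.clustered

    def test_signed_rank_statistics_negative_in_declining_cohort(self):
        data = generate_cohort(noiseless_params(n_participants=50))
        for level in ("person", "tooth"):
            tab = transition_table(data, "early_erupting", level, (9, 13))
            for res in tab.signed_rank.values():
                if res.valid and res.n_nonzero >= 5:
                    assert res.statistic < 0

    def test_empty_alignment_raises(self):
        data = _two_wave_cohort([(0, 0)])
        with pytest.raises(ValueError):
            transition_table(data, "late_erupting", "person", (9, 13))


class TestBleachingSensitivity:
    def _changes(self, rng, n=120, shift=0.0):
        clusters = np.arange(n)
        return pd.DataFrame(
            {
                "unit_id": clusters,
                "cluster_id": clusters,
                "baseline_cat": rng.integers(1, 3, size=n),
                "diff": rng.normal(0, 0.4, size=n)
                - shift * (rng.random(n) < 0.5).astype(float),
                "bleach_group": rng.random(n) < 0.4,
            }
        )

    def test_reports_each_stratum(self):
        rng = np.random.default_rng(0)
        out = bleaching_sensitivity(self._changes(rng), "person")
        assert set(out["baseline_cat"]) == {1, 2}
        assert out["p_two_sided"].notna().all()
        assert (out["n_tests_in_family"] == len(out)).all()

    def test_empty_group_skipped_with_reason(self):
        rng = np.random.default_rng(1)
        changes = self._changes(rng)
        changes["bleach_group"] = False
        out = bleaching_sensitivity(changes, "person")
        assert out["skipped"].notna().all()
        assert out["p_two_sided"].isna().all()

    def test_label_permutation_preserves_type_one_error(self):
        rng = np.random.default_rng(2)
        n_sims, alpha = 300, 0.05
        rej = total = 0
        for _ in range(n_sims):
            changes = self._changes(rng, n=80)
            out = bleaching_sensitivity(changes, "person")
            valid = out[out["skipped"].isna()]
            rej += (valid["p_two_sided"] < alpha).sum()
            total += len(valid)
        rate = rej / total
        se = np.sqrt(alpha * (1 - alpha) / total)
        assert abs(rate - alpha) < 3 * se
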
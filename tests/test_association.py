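"""Case-control statistics: odds ratios, exact tests, logistic regression,
burden and indel-enrichment machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mitocohort import simulate
from mitocohort.association import (
    ContingencyTable,
    SeparationWarning,
    burden_by_region,
    chi_square,
    fisher_exact,
    haplogroup_association,
    indel_enrichment,
    logistic_fit,
    mann_whitney,
    odds_ratio,
    snp_association,
)
from mitocohort.calls import CohortVariantSummary, SampleCall
from mitocohort.genome import GenomeMap, Variant


def fisher_oracle(a, b, c, d):
    """Independent two-sided Fisher p: enumerate the hypergeometric
    distribution with math.comb and sum point probabilities <= observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    probs = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[k] = math.comb(r1, k) * math.comb(r2, c1 - k) / denom
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestOddsRatio:
    def test_table1_d4_row(self):
        res = odds_ratio(ContingencyTable(14, 132, 23, 97))
        assert res.odds_ratio == pytest.approx(0.447, abs=5e-4)
        assert res.ci_low == pytest.approx(0.219, abs=5e-4)
        assert res.ci_high == pytest.approx(0.914, abs=5e-4)
        assert not res.correction_applied

    def test_symmetric_table_is_null(self):
        res = odds_ratio(ContingencyTable(10, 10, 10, 10))
        assert res.odds_ratio == 1.0

    def test_haldane_correction_on_zero_cell(self):
        res = odds_ratio(ContingencyTable(0, 10, 5, 5))
        assert res.correction_applied
        assert res.odds_ratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_degenerate_all_zero_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(ContingencyTable(0, 0, 0, 0))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)

    @given(st.tuples(*[st.integers(min_value=0, max_value=60)] * 4))
    def test_woolf_ci_contains_or(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        res = odds_ratio(ContingencyTable(a, b, c, d))
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    @pytest.mark.parametrize("factor", [2, 5, 10])
    def test_ci_width_shrinks_with_sample_size(self, factor):
        base = ContingencyTable(8, 12, 14, 6)
        r1 = odds_ratio(base)
        r2 = odds_ratio(ContingencyTable(8 * factor, 12 * factor,
                                         14 * factor, 6 * factor))
        w1 = math.log(r1.ci_high) - math.log(r1.ci_low)
        w2 = math.log(r2.ci_high) - math.log(r2.ci_low)
        assert w2 < w1
        assert r2.odds_ratio == pytest.approx(r1.odds_ratio)


class TestFisher:
    def test_diagonal_two_by_two(self):
        # enumeration over k in {0,1,2}: probabilities {1/6, 4/6, 1/6}
        assert fisher_exact(ContingencyTable(2, 0, 0, 2)) == pytest.approx(1 / 3)

    def test_most_probable_table_gives_one(self):
        assert fisher_exact(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_zero_margin_is_degenerate(self):
        assert fisher_exact(ContingencyTable(0, 0, 3, 7)) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b + c + d == 0:
                continue
            p = fisher_exact(ContingencyTable(int(a), int(b), int(c), int(d)))
            assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)


class TestChiSquare:
    def test_independent_table(self):
        res = chi_square(ContingencyTable(10, 10, 10, 10))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_expected_count_oracle(self):
        # Pearson statistic recomputed from expected counts E_ij = row*col/n
        t = ContingencyTable(14, 132, 23, 97)
        obs = np.array([[14, 132], [23, 97]], dtype=float)
        n = obs.sum()
        expected = np.outer(obs.sum(1), obs.sum(0)) / n
        stat = ((obs - expected) ** 2 / expected).sum()
        res = chi_square(t)
        assert res.statistic == pytest.approx(stat)

    def test_rxc_generalization_nonnegative(self):
        table = [[5, 1, 0], [2, 8, 3], [1, 1, 9]]
        res = chi_square(table)
        assert res.valid and res.statistic >= 0

    def test_zero_margin_flagged(self):
        res = chi_square(ContingencyTable(0, 0, 5, 5))
        assert not res.valid and math.isnan(res.p)

    def test_yates_reduces_statistic(self):
        t = ContingencyTable(12, 5, 4, 13)
        assert chi_square(t, yates=True).statistic < chi_square(t).statistic


class TestLogistic:
    @staticmethod
    def _vectors(t: ContingencyTable):
        x = np.concatenate([np.ones(t.a), np.zeros(t.b),
                            np.ones(t.c), np.zeros(t.d)])
        y = np.concatenate([np.ones(t.a + t.b), np.zeros(t.c + t.d)])
        return x, y

    def test_binary_covariate_equals_contingency_or(self):
        t = ContingencyTable(14, 132, 23, 97)
        x, y = self._vectors(t)
        res = logistic_fit(x, y)
        assert res.converged
        assert res.odds_ratio == pytest.approx(0.447, abs=5e-4)
        assert res.odds_ratio == pytest.approx(
            odds_ratio(t).odds_ratio, abs=1e-9)

    def test_independent_exposure_gives_null_or(self):
        t = ContingencyTable(10, 10, 10, 10)
        x, y = self._vectors(t)
        res = logistic_fit(x, y)
        assert res.beta == pytest.approx(0.0, abs=1e-8)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-8)

    def test_separation_falls_back_with_warning(self):
        t = ContingencyTable(0, 10, 5, 5)
        x, y = self._vectors(t)
        with pytest.warns(SeparationWarning):
            res = logistic_fit(x, y)
        assert res.fallback
        assert res.odds_ratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_matches_statsmodels_on_continuous_exposure(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(8)
        x = rng.normal(size=300)
        eta = -0.3 + 0.8 * x
        y = rng.random(300) < 1 / (1 + np.exp(-eta))
        ours = logistic_fit(x, y.astype(int))
        ref = sm.Logit(y.astype(float),
                       sm.add_constant(x)).fit(disp=0)
        assert ours.beta == pytest.approx(ref.params[1], abs=1e-7)
        assert ours.se == pytest.approx(ref.bse[1], abs=1e-6)

    def test_constant_exposure_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(np.ones(10), np.array([0, 1] * 5))


class TestMannWhitney:
    def test_complete_separation_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / 20)  # 2 of C(6,3)=20 assignments

    def test_identical_samples_are_null(self):
        u, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)  # n_x*n_y/2
        assert p == pytest.approx(1.0)

    def test_constant_data_guard(self):
        u, p = mann_whitney([2, 2], [2, 2, 2])
        assert u == 3.0 and p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_exact_matches_enumeration_oracle(self):
        """Exact p equals full rank-assignment enumeration (tie-free)."""
        from itertools import combinations
        rng = np.random.default_rng(4)
        for nx in (3, 5):
            x = rng.permutation(100)[: nx + 4].astype(float)
            xs, ys = x[:nx], x[nx:]
            u_obs, p_obs = mann_whitney(xs, ys)
            pooled = np.concatenate([xs, ys])
            ranks = pooled.argsort().argsort() + 1
            nx_, ny_ = len(xs), len(ys)
            u_all = []
            for combo in combinations(range(nx_ + ny_), nx_):
                r = ranks[list(combo)].sum()
                u_all.append(r - nx_ * (nx_ + 1) / 2)
            u_all = np.array(u_all)
            mu = nx_ * ny_ / 2
            p_exp = np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - 1e-12)
            assert p_obs == pytest.approx(p_exp, rel=1e-9)

    def test_null_rejection_rate_calibrated(self):
        """Monte-Carlo type-I error at alpha=0.05 for the cohort-scale
        asymptotic path (n=146 vs 120, count-like data)."""
        rng = np.random.default_rng(31)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x = rng.poisson(5, size=146)
            y = rng.poisson(5, size=120)
            _, p = mann_whitney(x, y)
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) <= 0.01


class TestSnpAssociation:
    def _matrix(self, af_cases, af_controls, n_cases=100, n_controls=100):
        carriers = {}
        idx = [f"c{i}" for i in range(n_cases)] + [f"h{i}" for i in range(n_controls)]
        col = np.zeros(n_cases + n_controls, dtype=bool)
        col[: int(af_cases * n_cases)] = True
        col[n_cases: n_cases + int(af_controls * n_controls)] = True
        carriers["snp1"] = col
        df = pd.DataFrame(carriers, index=idx)
        is_case = pd.Series([True] * n_cases + [False] * n_controls, index=idx)
        return df, is_case

    def test_low_maf_in_both_cohorts_excluded(self):
        df, is_case = self._matrix(0.04, 0.04)
        assert snp_association(df, is_case).empty

    def test_low_maf_in_one_cohort_retained(self):
        df, is_case = self._matrix(0.04, 0.06)
        out = snp_association(df, is_case)
        assert list(out["exposure"]) == ["snp1"]

    def test_maf_exactly_at_floor_retained(self):
        df, is_case = self._matrix(0.05, 0.05)
        assert len(snp_association(df, is_case)) == 1

    def test_high_major_frequency_counts_as_minor(self):
        # carrier frequency 0.97 in both cohorts: MAF 0.03 < floor
        df, is_case = self._matrix(0.97, 0.97)
        assert snp_association(df, is_case).empty

    def test_report_has_raw_and_bh_adjusted_p(self):
        df, is_case = self._matrix(0.30, 0.10)
        out = snp_association(df, is_case)
        assert {"p_wald", "p_bh", "OR", "ci_low", "ci_high",
                "p_fisher", "p_chi2"} <= set(out.columns)
        assert (out["p_bh"] >= out["p_wald"] - 1e-12).all()


class TestBurden:
    def _toy_gm(self):
        from mitocohort.genome import Feature
        return GenomeMap([
            Feature("geneA", 1, 9, "H", "protein"),
            Feature("geneB", 10, 19, "H", "tRNA"),
        ], genome_length=30)

    def _call(self, sid, pos, hf=1.0):
        return SampleCall(sid, Variant(pos, "A", "G"), int(hf * 100), 100)

    def test_single_sample_counts(self):
        gm = self._toy_gm()
        calls = [self._call("s1", 2), self._call("s1", 3), self._call("s1", 5)]
        res = burden_by_region(calls, {"s1": "case", "s2": "control"}, gm)
        assert res.counts.loc["s1", "geneA"] == 3
        assert res.counts.loc["s1", "geneB"] == 0
        assert res.counts.loc["s1", "coding"] == 3
        assert res.counts.loc["s2", "total"] == 0

    def test_identical_groups_give_null_p(self):
        gm = self._toy_gm()
        calls = ([self._call(f"c{i}", 2) for i in range(3)]
                 + [self._call(f"h{i}", 2) for i in range(3)])
        groups = {f"c{i}": "case" for i in range(3)}
        groups.update({f"h{i}": "control" for i in range(3)})
        res = burden_by_region(calls, groups, gm)
        assert res.group_stats.loc["geneA", "p"] == pytest.approx(1.0)

    def test_heteroplasmic_only_restriction(self):
        gm = self._toy_gm()
        calls = [self._call("s1", 2, hf=1.0), self._call("s1", 3, hf=0.5)]
        groups = {"s1": "case", "s2": "control"}
        res = burden_by_region(calls, groups, gm, heteroplasmic_only=True)
        assert res.counts.loc["s1", "geneA"] == 1

    def test_unknown_sample_rejected(self):
        gm = self._toy_gm()
        with pytest.raises(ValueError, match="missing from group map"):
            burden_by_region([self._call("sX", 2)], {"s1": "case"}, gm)

    def test_shifted_region_flagged(self):
        """A +2 mean count shift in one region for cases is detected."""
        gm = self._toy_gm()
        rng = np.random.default_rng(6)
        calls, groups = [], {}
        for i in range(100):
            sid = f"c{i}"
            groups[sid] = "case"
            for _ in range(rng.poisson(5)):  # shifted region
                calls.append(self._call(sid, 2))
            for _ in range(rng.poisson(3)):
                calls.append(self._call(sid, 12))
        for i in range(100):
            sid = f"h{i}"
            groups[sid] = "control"
            for _ in range(rng.poisson(3)):
                calls.append(self._call(sid, 2))
            for _ in range(rng.poisson(3)):
                calls.append(self._call(sid, 12))
        res = burden_by_region(calls, groups, gm)
        assert res.group_stats.loc["geneA", "p"] < 0.05
        assert res.group_stats.loc["geneA", "mean_cases"] > \
            res.group_stats.loc["geneA", "mean_controls"]

    def test_power_at_stated_effect_size(self):
        """Mann-Whitney power >= 0.8 over 200 replicates for a +2 Poisson
        mean shift at n=100 per group."""
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(200):
            x = rng.poisson(5, size=100)
            y = rng.poisson(3, size=100)
            _, p = mann_whitney(x, y)
            hits += p < 0.05
        assert hits / 200 >= 0.8


class TestIndelEnrichment:
    def _summary(self, variant, profile):
        return CohortVariantSummary(variant, 1, 0, profile, 0.0, False, "rare")

    def test_all_snv_degenerate_flagged(self, gm):
        summaries = [self._summary(Variant(100, "A", "G"), "heteroplasmic_only"),
                     self._summary(Variant(200, "C", "T"), "homoplasmic_only")]
        res = indel_enrichment(summaries, gm)
        assert not res.state_chi2.valid
        assert res.state_fisher is None

    def test_indels_only_in_heteroplasmic_detected(self, gm):
        summaries = []
        for i in range(12):
            summaries.append(self._summary(
                Variant(100 + i, "A", "AC"), "heteroplasmic_only"))
            summaries.append(self._summary(
                Variant(300 + i, "A", "G"), "homoplasmic_only"))
        for i in range(12):
            summaries.append(self._summary(
                Variant(500 + i, "C", "T"), "heteroplasmic_only"))
        res = indel_enrichment(summaries, gm)
        assert res.state_fisher < 0.05
        assert res.state_table.loc["homoplasmic_only", "indel"] == 0

    def test_tables_conserve_totals(self, gm):
        summaries = [
            self._summary(Variant(100, "A", "AC"), "heteroplasmic_only"),
            self._summary(Variant(3010, "G", "A"), "both"),
            self._summary(Variant(5000, "T", "C"), "homoplasmic_only"),
        ]
        res = indel_enrichment(summaries, gm)
        # "both" informs only the region table
        assert res.state_table.to_numpy().sum() == 2
        assert res.region_table.to_numpy().sum() == 3


class TestHaplogroupAssociation:
    def test_full_report_from_pooled_counts(self):
        counts = pd.DataFrame(
            {"case": [14, 132], "control": [23, 97]},
            index=["D4", "Others"])
        rep = haplogroup_association(counts)
        assert rep.loc["D4", "OR"] == pytest.approx(0.447, abs=5e-4)
        assert rep.loc["D4", "cases"] == 14
        # the complementary row is the inverse association
        assert rep.loc["Others", "OR"] == pytest.approx(1 / 0.4473, rel=1e-3)
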
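import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import twinefi as te

from conftest import make_cohort, make_matrix


def oracle_levene_p(a, b, center="median"):
    """Brute-force deviation-ANOVA: absolute deviations from the group
    center, one-way F on 1 and n1+n2-2 df. Pure-Python arithmetic."""
    groups = [list(map(float, a)), list(map(float, b))]
    cfun = (lambda g: sorted(g)[len(g) // 2] if len(g) % 2
            else (sorted(g)[len(g) // 2 - 1] + sorted(g)[len(g) // 2]) / 2) \
        if center == "median" else (lambda g: sum(g) / len(g))
    z = [[abs(x - cfun(g)) for x in g] for g in groups]
    ns = [len(g) for g in z]
    n = sum(ns)
    zbar = sum(x for g in z for x in g) / n
    zbars = [sum(g) / len(g) for g in z]
    ssb = sum(ni * (zi - zbar) ** 2 for ni, zi in zip(ns, zbars))
    ssw = sum((x - zi) ** 2 for g, zi in zip(z, zbars) for x in g)
    if ssw == 0:
        return 1.0 if ssb == 0 else 0.0
    w = ssb * (n - 2) / ssw
    return float(stats.f.sf(w, 1, n - 2))


def oracle_bh(pvalues):
    """Independently coded Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adj[order[i]] = running
    return adj


class TestLevene:
    def test_identical_groups_p_one(self):
        assert te.levene_p([-1, 0, 1], [-1, 0, 1]) == 1.0

    def test_strong_spread_difference_detected(self):
        a = [-1.0, 0.0, 1.0] * 10
        b = [-5.0, 0.0, 5.0] * 10
        p = te.levene_p(a, b)
        assert p < 0.01
        assert p == pytest.approx(oracle_levene_p(a, b), abs=1e-12)

    def test_degenerate_all_zero_deviations(self):
        assert te.levene_p([0.2, 0.2, 0.2], [0.7, 0.7, 0.7]) == 1.0

    def test_too_few_values_rejected(self):
        with pytest.raises(te.ValidationError):
            te.levene_p([0.1], [0.2, 0.3])

    @pytest.mark.parametrize("center", ["median", "mean"])
    def test_matches_scipy(self, center):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.normal(0, 1, rng.integers(3, 25))
            b = rng.normal(0, rng.uniform(0.3, 3), rng.integers(3, 25))
            ours = te.levene_p(a, b, center=center)
            ref = stats.levene(a, b, center=center).pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_matrix_form_matches_scalar_with_missing(self):
        rng = np.random.default_rng(9)
        dy = rng.normal(0, 0.02, (20, 15))
        de = rng.normal(0, 0.04, (20, 18))
        dy[rng.random(dy.shape) < 0.1] = np.nan
        de[rng.random(de.shape) < 0.1] = np.nan
        pmat = te.levene_p_matrix(dy, de)
        for i in range(20):
            a = dy[i][~np.isnan(dy[i])]
            b = de[i][~np.isnan(de[i])]
            assert pmat[i] == pytest.approx(te.levene_p(a, b), abs=1e-12)


class TestStoreyQvalues:
    def test_all_p_one(self):
        model = te.storey_qvalues(np.ones(20))
        assert model.pi0 == 1.0
        np.testing.assert_allclose(model.qvalues, 1.0)

    def test_pi0_one_equals_bh(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 2000)
        q = te.storey_qvalues(p, pi0=1.0).qvalues
        np.testing.assert_allclose(q, oracle_bh(p), rtol=1e-12)

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(4)
        p = np.sort(rng.uniform(0, 1, 500))
        q = te.storey_qvalues(p).qvalues
        assert np.all(np.diff(q) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(te.ValidationError):
            te.storey_qvalues([0.5, np.nan])
        with pytest.raises(te.ValidationError):
            te.storey_qvalues([0.5, 1.5])

    def test_pi0_near_one_under_pure_null(self):
        rng = np.random.default_rng(12)
        pi0 = te.estimate_pi0(rng.uniform(0, 1, 10_000))
        assert 0.8 <= pi0 <= 1.0

    def test_pi0_below_one_with_signal(self):
        rng = np.random.default_rng(13)
        p = np.concatenate([rng.uniform(0, 1, 8000), rng.beta(0.1, 10, 2000)])
        assert te.estimate_pi0(p) < 0.95

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=200))
    def test_q_bounded_and_aligned(self, pvals):
        model = te.storey_qvalues(pvals)
        assert model.qvalues.shape == (len(pvals),)
        assert np.all((model.qvalues >= 0) & (model.qvalues <= 1))
        # q respects the p-value ordering
        order = np.argsort(pvals)
        assert np.all(np.diff(model.qvalues[order]) >= -1e-15)


class TestClassification:
    @pytest.mark.parametrize(
        "efi,q,expected",
        [
            (2.0, 0.001, "elderly-significant"),
            (0.5, 0.001, "young-significant"),
            (2.0, 0.02, "not-significant"),
            (np.nan, 0.001, "excluded"),
            (1.0, 0.001, "not-significant"),  # EFI exactly 1 is neither class
        ],
    )
    def test_rules(self, efi, q, expected):
        assert te.classify_sites(np.array([efi]), np.array([q]), alpha=0.01)[0] == expected

    def test_length_mismatch(self):
        with pytest.raises(te.ValidationError, match="differ in length"):
            te.classify_sites(np.array([1.0, 2.0]), np.array([0.5]))


class TestAnalyzeCohort:
    def test_excluded_sites_not_in_fdr_family(self):
        # one constant-difference site (undefined EFI) among normal sites
        rng = np.random.default_rng(8)
        n_pairs = 30
        ages = np.r_[np.full(15, 30.0), np.full(15, 70.0)]
        cohort = make_cohort(ages)
        base = rng.uniform(0.3, 0.7, (40, 1))
        d = rng.normal(0, 0.02, (40, n_pairs))
        d[0] = 0.0  # zero spread in both groups at site 0
        beta = np.empty((40, 2 * n_pairs))
        beta[:, 0::2] = base + d / 2
        beta[:, 1::2] = base - d / 2
        matrix = make_matrix(beta, subject_ids=cohort.subject_ids)
        res = te.analyze_cohort(matrix, cohort)
        assert res.results.loc[0, "class"] == "excluded"
        assert np.isnan(res.results.loc[0, "q_storey"])
        tested = res.results["q_storey"].notna().sum()
        assert tested == 39  # m excludes the undefined site

    def test_summary_counts_match_table(self, small_analysis):
        summary = small_analysis.summary()
        counts = small_analysis.results["class"].value_counts()
        for cls, n in summary["counts_per_class"].items():
            assert n == counts.get(cls, 0)
        assert summary["n_sites"] == len(small_analysis.results)


class TestAgeCorrelation:
    def test_perfect_linear_relation(self):
        cohort = make_cohort([30, 40, 50, 60])
        ages = np.repeat(cohort.ages, 2)
        beta = (ages / 100.0)[None, :]
        matrix = make_matrix(beta, subject_ids=cohort.subject_ids)
        r = te.age_correlation(matrix, cohort)
        assert r.iloc[0] == pytest.approx(1.0)

    def test_constant_beta_flagged(self):
        cohort = make_cohort([30, 40, 50, 60])
        matrix = make_matrix(np.full((1, 8), 0.5), subject_ids=cohort.subject_ids)
        assert np.isnan(te.age_correlation(matrix, cohort).iloc[0])

    def test_null_sites_centered_near_zero(self, small_sim):
        r = te.age_correlation(small_sim.matrix, small_sim.cohort).dropna()
        null_probes = set(small_sim.truth.loc[~small_sim.truth["affected"], "probe"])
        r_null = r[r.index.isin(null_probes)]
        assert abs(r_null.median()) < 0.1
        # unimodal in the loose sense: the bulk lies in one central band
        assert (r_null.abs() < 0.35).mean() > 0.9


class TestCutoffSensitivity:
    def test_identical_cutoffs_r_one(self, small_sim):
        ages = small_sim.cohort.ages
        med = float(np.median(ages))
        table = te.cutoff_sensitivity(small_sim.matrix, small_sim.cohort, [med, med])
        assert table.iloc[0, 1] == pytest.approx(1.0)

    def test_nearby_cutoffs_agree_more_than_distant(self, small_sim):
        ages = small_sim.cohort.ages
        med = float(np.median(ages))
        near, far = med + 3, float(np.quantile(ages, 0.85))
        table = te.cutoff_sensitivity(small_sim.matrix, small_sim.cohort, [near, far])
        assert table.loc["median", str(near)] > table.loc["median", str(far)]

    def test_degenerate_cutoff_named(self, small_sim):
        with pytest.raises(te.ValidationError, match="200"):
            te.cutoff_sensitivity(small_sim.matrix, small_sim.cohort, [200.0])


class TestSubsetSummary:
    def test_identity_subset_reproduces_global(self, small_analysis):
        res = small_analysis.results
        s = te.subset_summary(res, list(res["probe"]))
        defined = res["efi"].dropna()
        assert s["n_sites"] == len(res)
        assert s["mean_efi"] == pytest.approx(defined.mean())
        assert s["sd_efi"] == pytest.approx(defined.std(ddof=1))

    def test_partition_recovers_global_mean(self, small_analysis):
        res = small_analysis.results.dropna(subset=["efi"])
        probes = list(res["probe"])
        half = len(probes) // 2
        s1 = te.subset_summary(small_analysis.results, probes[:half])
        s2 = te.subset_summary(small_analysis.results, probes[half:])
        pooled = (s1["mean_efi"] * s1["n_sites"] + s2["mean_efi"] * s2["n_sites"]) / (
            s1["n_sites"] + s2["n_sites"]
        )
        assert pooled == pytest.approx(res["efi"].mean())

    def test_empty_and_unmatched(self, small_analysis):
        with pytest.raises(te.ValidationError):
            te.subset_summary(small_analysis.results, [])
        with pytest.raises(te.ValidationError):
            te.subset_summary(small_analysis.results, ["cgNOPE"])
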
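"""Genotype QC: HWE exact test, call-rate/MAF filters, heterozygosity,
inbreeding F, sex check, IBD relatedness, PCA outliers and LD pruning."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from bcellprs import qc
from bcellprs.scoring import RiskVariant, WeightTable
from tests.conftest import make_matrix


def hwe_oracle(n_aa, n_ab, n_bb):
    """Independent enumeration oracle: log-space conditional probabilities
    of every heterozygote count with the observed allele totals."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    hs = np.arange(rare % 2, rare + 1, 2)
    aa = (n_a - hs) // 2
    bb = (n_b - hs) // 2
    logp = (
        hs * math.log(2.0)
        + gammaln(n + 1)
        - gammaln(aa + 1)
        - gammaln(hs + 1)
        - gammaln(bb + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[list(hs).index(n_ab)]
    return float(p[p <= obs * (1 + 1e-12)].sum())


class TestHWEExactTest:
    def test_monomorphic_is_one(self):
        assert qc.hwe_exact_test(50, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [(0, 100, 0), (25, 50, 25), (90, 9, 1), (1, 1, 1), (0, 1, 0), (3, 0, 3)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert qc.hwe_exact_test(*counts) == pytest.approx(
            hwe_oracle(*counts), abs=1e-12
        )

    @settings(max_examples=300, deadline=None)
    @given(
        st.integers(0, 80), st.integers(0, 80), st.integers(0, 80)
    )
    def test_oracle_agreement_random_tables(self, aa, ab, bb):
        if aa + ab + bb == 0:
            return
        p = qc.hwe_exact_test(aa, ab, bb)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(hwe_oracle(aa, ab, bb), abs=1e-12)

    def test_rejects_all_zero(self):
        with pytest.raises(ValueError):
            qc.hwe_exact_test(0, 0, 0)

    def test_excess_heterozygosity_detected(self):
        # all-het table is maximally discordant with HWE for large n
        assert qc.hwe_exact_test(0, 100, 0) < 1e-20


class TestSampleCallRate:
    def test_boundary_is_kept(self):
        d = np.zeros((2, 100))
        d[0, :6] = np.nan  # 94% call rate
        d[1, :5] = np.nan  # 95%: not "below"
        rep = qc.sample_call_rate_filter(make_matrix(d))
        assert rep.loc["S1", "excluded"] and rep.loc["S1", "reasons"] == ["low_call_rate"]
        assert not rep.loc["S2", "excluded"]

    def test_fully_missing_sample(self):
        d = np.full((1, 10), np.nan)
        rep = qc.sample_call_rate_filter(make_matrix(d))
        assert rep["call_rate"].iloc[0] == 0.0 and rep["excluded"].iloc[0]


class TestVariantFilters:
    def test_maf_computed_on_calls(self):
        # counts AA=90, AB=9, BB=1 -> maf = 11/200 = 0.055
        d = np.array([0] * 90 + [1] * 9 + [2] * 1, dtype=float).reshape(-1, 1)
        rep = qc.variant_filters(make_matrix(d))
        assert rep["maf"].iloc[0] == pytest.approx(0.055)
        assert "low_maf" not in rep["reasons"].iloc[0]

    def test_monomorphic_excluded(self):
        d = np.zeros((100, 1))
        rep = qc.variant_filters(make_matrix(d))
        assert rep["maf"].iloc[0] == 0.0 and "low_maf" in rep["reasons"].iloc[0]

    def test_low_call_rate_excluded(self):
        d = np.ones((100, 1))
        d[:3, 0] = np.nan  # 97%
        rep = qc.variant_filters(make_matrix(d))
        assert "low_call_rate" in rep["reasons"].iloc[0]

    def test_all_missing_is_undefined_safe(self):
        d = np.full((10, 1), np.nan)
        rep = qc.variant_filters(make_matrix(d))
        assert rep["excluded"].iloc[0]
        assert rep["reasons"].iloc[0] == ["low_call_rate"]

    def test_hwe_failure_flagged(self):
        d = np.ones((200, 1))  # every sample heterozygous
        rep = qc.variant_filters(make_matrix(d))
        assert "hwe_fail" in rep["reasons"].iloc[0]


class TestHeterozygosity:
    def test_identical_rates_none_excluded(self):
        d = np.tile([0.0, 1.0, 2.0, 1.0], (5, 1))
        rep = qc.heterozygosity_filter(make_matrix(d))
        assert not rep["excluded"].any()

    def test_gross_outlier_excluded(self, rng):
        n, m = 400, 200
        d = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        d[0] = 1.0  # fully heterozygous sample
        rep = qc.heterozygosity_filter(make_matrix(d))
        assert rep["excluded"].iloc[0]
        assert rep["excluded"].sum() == 1

    def test_below_threshold_kept(self, rng):
        rates = np.full(1000, 0.30) + rng.normal(0, 0.01, 1000)
        # craft per-sample het rates directly via 1000-marker rows
        m = 1000
        d = np.zeros((1000, m))
        for i, r in enumerate(rates):
            k = int(round(r * m))
            d[i, :k] = 1.0
        g = make_matrix(d)
        rep = qc.heterozygosity_filter(g)
        mean, sd = rep["het_rate"].mean(), rep["het_rate"].std(ddof=1)
        inlier = (rep["het_rate"] - mean).abs() <= 4.9 * sd
        assert not rep.loc[inlier, "excluded"].any()


class TestInbreedingF:
    def test_fully_homozygous_is_one(self, rng):
        d = rng.choice([0.0, 2.0], size=(50, 200))
        d[1] = rng.binomial(2, 0.5, 200).astype(float)  # keep loci polymorphic
        g = make_matrix(d)
        assert qc.inbreeding_f(g, "S1") == pytest.approx(1.0)

    def test_fully_heterozygous_near_minus_one(self):
        # many samples at p=0.5; focal sample heterozygous everywhere
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.5, size=(500, 400)).astype(float)
        d[0] = 1.0
        g = make_matrix(d)
        f = qc.inbreeding_f(g, "S1")
        assert f < -0.8

    def test_hwe_sample_near_zero(self, rng):
        fs = []
        for _ in range(30):
            d = rng.binomial(2, 0.3, size=(300, 500)).astype(float)
            g = make_matrix(d)
            fs.append(qc.inbreeding_f(g, "S1"))
        fs = np.asarray(fs)
        assert abs(fs.mean()) < 3 * fs.std(ddof=1) / math.sqrt(len(fs)) + 0.01

    def test_no_polymorphic_markers_rejected(self):
        g = make_matrix(np.zeros((3, 5)))
        with pytest.raises(ValueError, match="polymorphic"):
            qc.inbreeding_f(g, "S1")


class TestSexCheck:
    @pytest.mark.parametrize(
        "sex,f,expect",
        [
            ("male", 0.5, True),
            ("male", 0.9, False),
            ("female", 0.1, False),
            ("female", 0.25, True),
            ("unknown", 0.99, False),
            ("unknown", 0.0, False),
        ],
    )
    def test_rule(self, sex, f, expect):
        rep = qc.sex_check_filter(pd.Series({"S1": f}), {"S1": sex})
        assert rep.loc["S1", "excluded"] == expect


def _hwe_matrix(rng, n, m, p=0.3):
    return rng.binomial(2, p, size=(n, m)).astype(float)


class TestIBD:
    def test_duplicate_pair_near_one(self, rng):
        d = _hwe_matrix(rng, 100, 1000)
        d[1] = d[0]
        g = make_matrix(d)
        est = qc.ibd_estimate(g, ("S1", "S2"))
        assert est.pi_hat >= 0.95
        assert est.ibs_counts[0] == 0

    def test_unrelated_mean_near_zero(self, rng):
        vals = []
        for _ in range(100):
            d = _hwe_matrix(rng, 60, 1000)
            g = make_matrix(d)
            vals.append(qc.ibd_estimate(g, ("S1", "S2")).pi_hat)
        assert np.mean(vals) < 0.05

    def test_full_sibs_near_half(self, rng):
        """Gene-dropping oracle: sibs share each parental allele with
        probability 1/2, so expected pi_hat is 0.5."""
        vals = []
        m = 1000
        for _ in range(100):
            p = rng.uniform(0.2, 0.8, m)
            mother = rng.random((2, m)) < p
            father = rng.random((2, m)) < p
            def child():
                mi = rng.integers(0, 2, m)
                fi = rng.integers(0, 2, m)
                return (
                    mother[mi, np.arange(m)].astype(float)
                    + father[fi, np.arange(m)].astype(float)
                )
            background = rng.binomial(2, p, size=(58, m)).astype(float)
            d = np.vstack([child(), child(), background])
            g = make_matrix(d)
            vals.append(qc.ibd_estimate(g, ("S1", "S2")).pi_hat)
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_self_beats_unrelated(self, rng):
        d = _hwe_matrix(rng, 50, 1000)
        d = np.vstack([d, d[0]])
        g = make_matrix(d, sample_ids=[f"S{i}" for i in range(51)])
        self_hat = qc.ibd_estimate(g, ("S0", "S50")).pi_hat
        other = qc.ibd_estimate(g, ("S0", "S1")).pi_hat
        assert self_hat >= other

    def test_insufficient_overlap_rejected(self, rng):
        d = _hwe_matrix(rng, 3, 40)
        g = make_matrix(d)
        with pytest.raises(ValueError, match="insufficient markers"):
            qc.ibd_estimate(g, ("S1", "S2"))


class TestRelatednessFilter:
    def cr(self, ids, rates=None):
        return pd.Series(rates or {i: 1.0 for i in ids})

    def test_no_pairs_empty(self):
        df = pd.DataFrame({"sample_1": ["A"], "sample_2": ["B"], "pi_hat": [0.1]})
        assert qc.relatedness_filter(df, self.cr(["A", "B"])) == set()

    def test_duplicate_pair_drops_lower_call_rate(self):
        df = pd.DataFrame({"sample_1": ["A"], "sample_2": ["B"], "pi_hat": [0.9]})
        out = qc.relatedness_filter(df, pd.Series({"A": 0.99, "B": 0.97}))
        assert out == {"B"}

    def test_tie_drops_later_id(self):
        df = pd.DataFrame({"sample_1": ["A"], "sample_2": ["B"], "pi_hat": [0.9]})
        assert qc.relatedness_filter(df, self.cr(["A", "B"])) == {"B"}

    def test_triangle_removes_two(self):
        df = pd.DataFrame(
            {
                "sample_1": ["A", "A", "B"],
                "sample_2": ["B", "C", "C"],
                "pi_hat": [0.5, 0.4, 0.45],
            }
        )
        out = qc.relatedness_filter(df, self.cr(["A", "B", "C"]))
        assert len(out) == 2
        # remaining sample participates in no pair above threshold
        left = {"A", "B", "C"} - out
        assert len(left) == 1


class TestPCAOutliers:
    def test_homogeneous_population_unflagged(self, rng):
        d = _hwe_matrix(rng, 300, 300)
        rep = qc.pca_outlier_filter(make_matrix(d), n_components=5)
        assert rep["excluded"].sum() <= 1

    def test_diverged_subgroup_flagged(self, rng):
        m = 400
        p_a = rng.uniform(0.2, 0.8, m)
        p_b = np.clip(p_a + rng.choice([-0.35, 0.35], m), 0.02, 0.98)
        d = np.vstack(
            [
                rng.binomial(2, p_a, size=(990, m)),
                rng.binomial(2, p_b, size=(10, m)),
            ]
        ).astype(float)
        rep = qc.pca_outlier_filter(make_matrix(d), n_components=5)
        flagged = set(np.where(rep["excluded"])[0])
        assert flagged == set(range(990, 1000))

    def test_infinite_threshold_flags_none(self, rng):
        d = _hwe_matrix(rng, 100, 50)
        rep = qc.pca_outlier_filter(make_matrix(d), sd_threshold=np.inf)
        assert not rep["excluded"].any()

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant|PCA"):
            qc.pca_outlier_filter(make_matrix(np.ones((30, 20))))


def _prune_table(specs):
    return WeightTable(
        [
            RiskVariant(
                snp_id=s, risk_allele="G", other_allele="A", raf=raf, or_sle=orr,
                gene="g", in_bcell_prs=True, in_bcell_activation_prs=False,
            )
            for s, orr, raf in specs
        ]
    )


class TestLDPrune:
    def test_correlated_pair_keeps_higher_or(self, rng):
        base = rng.binomial(2, 0.4, size=1000).astype(float)
        d = np.column_stack([base, base])
        g = make_matrix(d, snp_ids=["rsA", "rsB"])
        table = _prune_table([("rsA", 1.5, 0.4), ("rsB", 1.2, 0.4)])
        res = qc.ld_prune(g, table)
        assert res.kept == ["rsA"]
        assert res.removed[0][0] == "rsB" and res.removed[0][2] > 0.99

    def test_independent_snps_all_kept(self, rng):
        d = rng.binomial(2, 0.4, size=(2000, 6)).astype(float)
        g = make_matrix(d, snp_ids=[f"rs{i}" for i in range(6)])
        table = _prune_table([(f"rs{i}", 1.2 + 0.01 * i, 0.4) for i in range(6)])
        res = qc.ld_prune(g, table)
        assert sorted(res.kept) == sorted(f"rs{i}" for i in range(6))

    def test_chained_correlation_hand_trace(self, rng):
        """A~B and B~C strongly correlated, A~C weakly: greedy keeps A, C."""
        n = 5000
        a = rng.binomial(2, 0.5, n).astype(float)
        noise = rng.binomial(2, 0.5, n).astype(float)
        # B highly correlated with both A and (through A) with C
        b = np.where(rng.random(n) < 0.95, a, noise)
        c_ind = rng.binomial(2, 0.5, n).astype(float)
        # make C correlate with B but only weakly with A: mix of b and fresh
        c = np.where(rng.random(n) < 0.6, b, c_ind)
        g = make_matrix(np.column_stack([a, b, c]), snp_ids=["rsA", "rsB", "rsC"])
        r2 = qc._pairwise_r2(g, ["rsA", "rsB", "rsC"])
        table = _prune_table([("rsA", 1.5, 0.5), ("rsB", 1.4, 0.5), ("rsC", 1.3, 0.5)])
        res = qc.ld_prune(g, table)
        # independent greedy trace on the computed r2 matrix
        kept = {"rsA", "rsB", "rsC"}
        order = {"rsA": 1.5, "rsB": 1.4, "rsC": 1.3}
        while True:
            pairs = [
                (x, y, r2.loc[x, y])
                for x, y in itertools.combinations(sorted(kept), 2)
                if r2.loc[x, y] > 0.2
            ]
            if not pairs:
                break
            x, y, _ = max(pairs, key=lambda t: t[2])
            kept.discard(x if order[x] < order[y] else y)
        assert set(res.kept) == kept
        for x, y in itertools.combinations(res.kept, 2):
            assert r2.loc[x, y] <= 0.2

    def test_missing_table_snp_rejected(self, rng):
        g = make_matrix(rng.binomial(2, 0.4, size=(100, 1)).astype(float),
                        snp_ids=["rsA"])
        table = _prune_table([("rsA", 1.5, 0.4), ("rsZ", 1.2, 0.4)])
        with pytest.raises(KeyError, match="rsZ"):
            qc.ld_prune(g, table)


class TestRunQC:
    def test_clean_input_no_exclusions(self, rng):
        # enough markers that no unrelated pair drifts past the IBD
        # threshold by sampling noise alone
        d = _hwe_matrix(rng, 40, 2000)
        res = qc.run_qc(make_matrix(d), run_pca=False)
        assert not res.samples["excluded"].any()
        assert res.filtered.n_samples == 40

    def test_planted_defects_each_caught(self, rng):
        n, m = 60, 2000
        d = _hwe_matrix(rng, n, m)
        d[0, : int(0.06 * m)] = np.nan        # 94% call rate
        d[2] = d[1]                            # duplicate pair
        # heterozygosity outlier: heavily inbred sample (het rate ~40% of
        # the cohort's); unlike an all-het sample this cannot mimic IBD
        inbred = rng.random(m) < 0.6
        d[3] = np.where(inbred, 2.0 * rng.binomial(1, 0.3, m), d[3])
        sample_ids = [f"S{i:03d}" for i in range(n)]
        g = make_matrix(d, sample_ids=sample_ids)
        res = qc.run_qc(g, run_pca=False)
        rep = res.samples
        assert rep.loc["S000", "excluded"] and "low_call_rate" in rep.loc["S000", "reasons"]
        dup = {"S001", "S002"}
        flagged_rel = {s for s in dup if "related" in rep.loc[s, "reasons"]}
        assert len(flagged_rel) == 1
        assert "het_outlier" in rep.loc["S003", "reasons"]
        excluded = set(rep.index[rep["excluded"]])
        assert excluded == {"S000", "S003"} | flagged_rel

    def test_sex_discordance_caught(self, rng):
        n, m = 60, 400
        auto = _hwe_matrix(rng, n, m)
        # X markers: females HWE (F~0), one annotated male also F~0 -> flagged
        x = rng.binomial(2, 0.4, size=(n, 500)).astype(float)
        d = np.hstack([auto, x])
        is_x = [False] * m + [True] * 500
        sample_ids = [f"S{i:02d}" for i in range(n)]
        sex = {s: "female" for s in sample_ids}
        sex["S05"] = "male"
        g = make_matrix(d, is_x=is_x, sample_ids=sample_ids, annotated_sex=sex)
        res = qc.run_qc(g, run_pca=False, run_ibd=False)
        assert "sex_discordant" in res.samples.loc["S05", "reasons"]
        others = res.samples.drop("S05")
        assert not others["excluded"].any()

    def test_stage_counts_reconcile(self, rng):
        d = _hwe_matrix(rng, 50, 300)
        d[0, :30] = np.nan
        res = qc.run_qc(make_matrix(d), run_pca=False)
        assert res.stages["input"] == 50
        assert res.stages["call_rate"] == 50 - 1
        assert res.stages["heterozygosity"] == res.filtered.n_samples
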
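"""DMR stage: candidate rule, sub-window enumeration, GLS region
statistic against a dense-matrix oracle, cross-cohort meta."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from twinewas.datatypes import DataError
from twinewas.dmr import (
    DmrRecord,
    RegionCandidate,
    cpg_correlations,
    dmr_meta_analysis,
    enumerate_tested_regions,
    find_candidate_regions,
    region_statistic,
    _regularize,
)


def _summary(pos, p, beta, chrom="1"):
    beta = np.asarray(beta, dtype=float)
    p = np.asarray(p, dtype=float)
    se = np.abs(beta) / np.abs(norm.isf(p / 2))  # consistent z
    se[se == 0] = 1.0
    z = beta / se
    return pd.DataFrame(
        {
            "cpg": [f"cg{i:03d}" for i in range(len(pos))],
            "chr": chrom,
            "pos": np.asarray(pos, dtype=int),
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
            "n": 100,
            "cohort": "c",
            "model": "adjusted",
        }
    )


class TestCandidates:
    def test_no_qualifying_cpgs(self):
        s = _summary([100, 200, 300], [0.5, 0.9, 0.06], [0.1, 0.1, 0.1])
        assert find_candidate_regions(s) == []

    def test_hand_enumeration_of_rule(self):
        """Third CpG is sign-discordant and 800 bp away; fourth fails the
        p threshold: exactly one candidate {100, 400}."""
        s = _summary([100, 400, 1200, 1600], [0.01, 0.02, 0.03, 0.20],
                     [0.1, 0.2, -0.1, 0.1])
        cands = find_candidate_regions(s, p_enter=0.05, max_gap=500)
        assert len(cands) == 1
        assert cands[0].start == 100 and cands[0].end == 400
        assert cands[0].cpgs == ("cg000", "cg001")

    def test_sign_constraint_can_be_disabled(self):
        s = _summary([100, 400], [0.01, 0.02], [0.1, -0.2])
        assert find_candidate_regions(s) == []
        cands = find_candidate_regions(s, require_same_sign=False)
        assert len(cands) == 1

    def test_three_cpg_run_has_three_subwindows(self):
        s = _summary([100, 300, 500], [0.01, 0.01, 0.01], [0.1, 0.1, 0.1])
        cands = find_candidate_regions(s)
        assert len(cands) == 1 and cands[0].n_cpgs == 3
        tested = enumerate_tested_regions(cands, s)
        members = {c.cpgs for c in tested}
        assert members == {("cg000", "cg001"), ("cg001", "cg002"),
                           ("cg000", "cg001", "cg002")}

    def test_subwindow_count_is_k_choose_2(self):
        pos = np.arange(5) * 100 + 1
        s = _summary(pos, [0.01] * 5, [0.1] * 5)
        cands = find_candidate_regions(s)
        assert len(enumerate_tested_regions(cands, s)) == 5 * 4 // 2

    def test_span_mode_bounds_total_length(self):
        pos = [100, 500, 900]  # consecutive gaps 400 but total span 800
        s = _summary(pos, [0.01] * 3, [0.1] * 3)
        by_gap = find_candidate_regions(s, max_gap=500, span_mode="gap")
        assert by_gap[0].n_cpgs == 3
        by_span = find_candidate_regions(s, max_gap=500, span_mode="span")
        assert max(c.n_cpgs for c in by_span) == 2

    def test_chromosomes_not_merged(self):
        a = _summary([100, 200], [0.01, 0.01], [0.1, 0.1], chrom="1")
        b = _summary([150, 250], [0.01, 0.01], [0.1, 0.1], chrom="2")
        b["cpg"] = ["cg100", "cg101"]
        cands = find_candidate_regions(pd.concat([a, b], ignore_index=True))
        assert len(cands) == 2
        assert {c.chrom for c in cands} == {"1", "2"}


class TestCorrelations:
    def test_independent_cpgs_near_zero(self):
        rng = np.random.default_rng(0)
        resid = pd.DataFrame(rng.standard_normal((4, 5000)),
                             index=["cg000", "cg001", "cg002", "cg003"])
        cand = RegionCandidate("1", 100, 400, ("cg000", "cg001", "cg002", "cg003"))
        R = cpg_correlations(resid, cand)
        np.testing.assert_allclose(np.diag(R), 1.0)
        off = R[np.triu_indices(4, 1)]
        assert np.abs(off).max() < 0.05

    def test_identical_cpgs_give_unit_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        resid = pd.DataFrame(np.vstack([x, x]), index=["cg000", "cg001"])
        R = cpg_correlations(resid, RegionCandidate("1", 1, 2, ("cg000", "cg001")))
        assert R[0, 1] == pytest.approx(1.0)
        # downstream regularization caps it
        assert _regularize(R)[0, 1] <= 0.99 * 0.99 + 0.01

    def test_constant_cpg_named_in_error(self):
        resid = pd.DataFrame(
            np.vstack([np.ones(50), np.random.default_rng(0).standard_normal(50)]),
            index=["cgAAA", "cgBBB"])
        with pytest.raises(DataError, match="cgAAA"):
            cpg_correlations(resid, RegionCandidate("1", 1, 2, ("cgAAA", "cgBBB")))


class TestRegionStatistic:
    def test_independence_reduces_to_fixed_effects_meta(self):
        s = _summary([100, 200], [0.01, 0.01], [0.004, 0.004])
        cand = RegionCandidate("1", 100, 200, ("cg000", "cg001"))
        rec = region_statistic(cand, s, np.eye(2))
        se = s["se"].to_numpy()
        w = 1 / se**2
        assert rec.effect == pytest.approx((w * s["beta"]).sum() / w.sum(), rel=1e-12)
        assert rec.se == pytest.approx(w.sum() ** -0.5, rel=1e-12)

    def test_two_cpg_gls_closed_form(self):
        """b=(0.004,0.004), s=(0.001,0.001), r=0.5 (after ridge
        regularization eps=0.01 the working r is 0.495):
        se = s*sqrt((1+r)/2), effect unchanged."""
        s = _summary([100, 200], [0.01, 0.01], [0.004, 0.004])
        s["se"] = 0.001
        s["z"] = s["beta"] / s["se"]
        cand = RegionCandidate("1", 100, 200, ("cg000", "cg001"))
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        rec = region_statistic(cand, s, R)
        assert rec.effect == pytest.approx(0.004, rel=1e-10)
        r_work = 0.5 * 0.99  # ridge-blended correlation
        assert rec.se == pytest.approx(0.001 * np.sqrt((1 + r_work) / 2), rel=1e-10)
        assert rec.se == pytest.approx(8.6603e-4, rel=5e-3)

    def test_matches_dense_gls_oracle(self):
        """Random 2-10 CpG regions match a brute-force explicit-inverse
        GLS oracle to 1e-10."""
        rng = np.random.default_rng(99)
        worst = 0.0
        for _ in range(200):
            k = int(rng.integers(2, 11))
            b = rng.normal(0, 0.01, k)
            se = rng.uniform(0.001, 0.01, k)
            A = rng.standard_normal((k, k + 3))
            R = np.corrcoef(A)
            s = _summary(np.arange(k) * 50 + 1, np.full(k, 0.01), b)
            s["se"] = se
            s["z"] = b / se
            cand = RegionCandidate("1", 1, k * 50, tuple(s["cpg"]))
            rec = region_statistic(cand, s, R)
            Rreg = _regularize(R)
            V = np.diag(se) @ Rreg @ np.diag(se)
            Vinv = np.linalg.inv(V)
            one = np.ones(k)
            eff = one @ Vinv @ b / (one @ Vinv @ one)
            sse = (one @ Vinv @ one) ** -0.5
            worst = max(worst, abs(rec.effect - eff), abs(rec.se - sse))
        assert worst < 1e-10

    def test_se_bounds(self):
        """With R=I the GLS se is below the smallest member se; with r->1
        and equal inputs it approaches the single-CpG se."""
        s = _summary([100, 200], [0.01, 0.01], [0.004, 0.004])
        s["se"] = 0.001
        s["z"] = s["beta"] / s["se"]
        cand = RegionCandidate("1", 100, 200, ("cg000", "cg001"))
        indep = region_statistic(cand, s, np.eye(2))
        assert indep.se < 0.001
        redundant = region_statistic(cand, s, np.array([[1, 0.9999], [0.9999, 1]]))
        assert redundant.se == pytest.approx(0.001, rel=0.01)

    def test_mean_absolute_effect_definition(self):
        s = _summary([100, 200, 300], [0.01] * 3, [-0.004, -0.004, 0.002])
        cand = RegionCandidate("1", 100, 300, ("cg000", "cg001", "cg002"))
        rec = region_statistic(cand, s, np.eye(3))
        assert rec.mean_abs_effect == pytest.approx(0.00333, abs=5e-5)


class TestNullFamilyWiseControl:
    def test_no_excess_significant_regions_under_null(self):
        """Null two-cohort panels with correlated CpG blocks: the genome-
        wide potential-region Bonferroni keeps the family-wise rate of
        p_adjust < 0.05 regions controlled."""
        from twinewas.datatypes import ModelSpec
        from twinewas.ewas import residualize, run_ewas
        from twinewas.meta import meta_fixed_effects
        from twinewas.dmr import run_dmr_analysis
        from twinewas.simulate import SimConfig, generate_cohort

        covs = ["age", "sex", "smoking", "neut", "plate"]
        tech = ["neut", "lymph", "mono", "eos", "plate", "row"]
        hits = 0
        for seed in range(12):
            summaries, resids = [], []
            for k, (fs, est) in enumerate([
                    ({"mz_pairs": 0.4, "dz_pairs": 0.3, "singletons": 0.3},
                     "cluster-exchangeable"),
                    ({"mz_pairs": 0.0, "dz_pairs": 0.0, "singletons": 1.0},
                     "ols")]):
                c = generate_cohort(SimConfig(
                    n_samples=600, n_cpgs=1500, seed=40000 + 2 * seed + k,
                    manifest_seed=seed, family_structure=dict(fs),
                    block_rho=0.5))
                summaries.append(run_ewas(
                    c.dataset, ModelSpec(covariates=covs, estimator=est)))
                resids.append(residualize(c.dataset, tech))
            meta = meta_fixed_effects(summaries)
            res = run_dmr_analysis(meta, summaries, resids)
            hits += any(r.p_adjust < 0.05 for r in res.representatives)
        # 99.9% binomial upper bound at a true family-wise rate of 0.10
        assert hits <= 5


class TestDmrMeta:
    def _rec(self, effect, se, cohort):
        z = effect / se
        return DmrRecord("1", 100, 200, ("cg000", "cg001"), effect, se, z,
                         float(2 * norm.sf(abs(z))), abs(effect), cohort)

    def test_single_cohort_identity(self):
        rec = self._rec(0.01, 0.002, "a")
        out = dmr_meta_analysis([[rec]], n_regions_tested=5)
        assert out[0].effect == pytest.approx(0.01)
        assert out[0].se == pytest.approx(0.002)
        assert out[0].p_adjust == pytest.approx(min(1, rec.p * 5))

    def test_identical_cohorts_halve_variance(self):
        a, b = self._rec(0.01, 0.002, "a"), self._rec(0.01, 0.002, "b")
        out = dmr_meta_analysis([[a], [b]], n_regions_tested=1)
        assert out[0].se == pytest.approx(0.002 / np.sqrt(2), rel=1e-10)

    def test_missing_candidate_dropped(self, caplog):
        a1 = self._rec(0.01, 0.002, "a")
        a2 = DmrRecord("1", 500, 600, ("cg010", "cg011"), 0.02, 0.004, 5.0,
                       1e-6, 0.02, "a")
        b1 = self._rec(0.012, 0.002, "b")
        out = dmr_meta_analysis([[a1, a2], [b1]], n_regions_tested=2)
        assert len(out) == 1 and out[0].start == 100

    def test_bonferroni_uses_regions_tested(self):
        rec = self._rec(0.006, 0.002, "a")  # p ~ 0.0027
        out = dmr_meta_analysis([[rec]], n_regions_tested=100)
        assert out[0].p_adjust == pytest.approx(min(1.0, rec.p * 100))
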
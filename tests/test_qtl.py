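"""Association machinery: OLS, HWE, q-values, clusters, D', causal models."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from bindqtl.qtl import (
    bonferroni_threshold,
    cluster_variants,
    compare_causal_models,
    filter_variants,
    hwe_test,
    ld_dprime,
    linear_qtl,
    linear_qtl_many,
    resolve_distal,
    shape_phenotypes,
    storey_qvalue,
)
from bindqtl.synthio import GenotypeTable, SimConfig, simulate_fragments, simulate_genotypes


class TestHWE:
    def test_perfect_hwe_is_modal(self):
        assert hwe_test((25, 50, 25)) == pytest.approx(1.0)

    def test_total_het_deficit_rejected(self):
        assert hwe_test((50, 0, 50)) < 1e-4

    def test_matches_enumeration_oracle(self):
        # brute force: enumerate all genotype configurations with n=10
        # individuals and 10 copies of each allele
        n, na = 10, 10
        hets = range(na % 2, na + 1, 2)

        def prob(h):
            a = (na - h) // 2
            b = n - a - h
            return (2.0**h / (math.factorial(h) * math.factorial(a)
                              * math.factorial(b)))

        probs = {h: prob(h) for h in hets}
        z = sum(probs.values())
        obs = probs[4] / z
        expect = sum(p / z for p in probs.values() if p / z <= obs + 1e-12)
        assert hwe_test((3, 4, 3)) == pytest.approx(expect, abs=1e-12)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            hwe_test((0, 0, 0))


class TestFilterVariants:
    def _table(self, dosage_cols, positions):
        dosages = np.array(dosage_cols, dtype=np.int8).T
        n_var = dosages.shape[1]
        variants = pd.DataFrame({
            "chrom": "chr1", "pos": positions,
            "id": [f"v{i}" for i in range(n_var)],
            "ref": "A", "alt": "C", "ancestral": "A",
            "is_indel": False,
            "maf": np.minimum(dosages.mean(0) / 2, 1 - dosages.mean(0) / 2),
        })
        samples = [f"s{i}" for i in range(dosages.shape[0])]
        return GenotypeTable(samples=samples, variants=variants,
                             dosages=dosages)

    def test_exact_maf_boundary_excluded(self):
        # MAF exactly 0.05 fails the strict > filter
        col = [1] + [0] * 9  # 1 alt allele / 20 -> maf 0.05
        g = self._table([col], [1000])
        region = pd.Series({"chrom": "chr1", "start": 900, "end": 1100,
                            "center": 1000})
        idx, tally = filter_variants(g, region)
        assert len(idx) == 0 and tally["maf"] == 1

    def test_window_boundary(self):
        col = [0, 1, 2, 1, 0, 1, 2, 1, 0, 1]
        g = self._table([col, col], [50_000, 50_001])
        region = pd.Series({"chrom": "chr1", "start": -100, "end": 100,
                            "center": 0})
        idx, tally = filter_variants(g, region)
        assert list(idx) == [0] and tally["window"] == 1

    def test_monomorphic_excluded_as_maf(self):
        g = self._table([[0] * 10], [1000])
        region = pd.Series({"center": 1000, "chrom": "chr1",
                            "start": 900, "end": 1100})
        idx, tally = filter_variants(g, region)
        assert len(idx) == 0 and tally["maf"] == 1

    def test_hwe_failure_excluded(self):
        col = [0] * 50 + [2] * 50  # total heterozygote deficit
        g = self._table([col], [1000])
        region = pd.Series({"center": 1000, "chrom": "chr1",
                            "start": 900, "end": 1100})
        idx, tally = filter_variants(g, region)
        assert len(idx) == 0 and tally["hwe"] == 1


class TestLinearQTL:
    def test_exact_linear_fit(self):
        g = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = 0.5 * g
        beta, se, t, p = linear_qtl(y, g)
        assert beta == pytest.approx(0.5, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_phenotype(self):
        g = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = np.array([1, -1, 1, -1, 1, -1], dtype=float)
        beta, _, _, p = linear_qtl(y, g)
        assert beta == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations_on_fixture(self, rng):
        # independent oracle: solve the 2x2 normal equations directly
        g = rng.integers(0, 3, 12).astype(float)
        y = 0.3 * g + rng.normal(0, 1, 12)
        n = 12
        X = np.column_stack([np.ones(n), g])
        XtX = X.T @ X
        coef = np.linalg.solve(XtX, X.T @ y)
        resid = y - X @ coef
        s2 = resid @ resid / (n - 2)
        se_o = np.sqrt(s2 * np.linalg.inv(XtX)[1, 1])
        t_o = coef[1] / se_o
        p_o = 2 * stats.t.sf(abs(t_o), n - 2)
        beta, se, t, p = linear_qtl(y, g)
        assert beta == pytest.approx(coef[1], abs=1e-10)
        assert se == pytest.approx(se_o, abs=1e-10)
        assert t == pytest.approx(t_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            linear_qtl(np.arange(6, dtype=float), np.ones(6))

    def test_vectorized_agrees_with_scalar(self, rng):
        G = rng.integers(0, 3, (20, 5)).astype(float)
        G[:, :] += (G.var(axis=0) == 0)[None, :] * rng.integers(0, 2, (20, 5))
        G = np.where(G > 2, 2, G)
        y = rng.normal(0, 1, 20)
        beta, se, t, p = linear_qtl_many(y, G)
        for k in range(5):
            b1, s1, t1, p1 = linear_qtl(y, G[:, k])
            assert beta[k] == pytest.approx(b1, abs=1e-12)
            assert p[k] == pytest.approx(p1, abs=1e-12)


class TestStoreyQ:
    def test_pi0_one_reduces_to_bh(self, rng):
        p = rng.uniform(0, 1, 200)
        q, _ = storey_qvalue(p, pi0=1.0)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_uniform_pvalues_pi0_near_one(self):
        for seed in range(5):
            p = np.random.default_rng(seed).uniform(0, 1, 10_000)
            _, pi0 = storey_qvalue(p)
            assert 0.9 <= pi0 <= 1.0

    def test_small_example_bound(self):
        p = np.array([1e-8, 0.5, 0.9, 0.95])
        q, pi0 = storey_qvalue(p)
        assert q[0] <= 4 * 1e-8 * pi0 + 1e-18

    def test_monotone_in_p(self, rng):
        p = rng.uniform(0, 1, 500)
        q, _ = storey_qvalue(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_never_below_bh(self, rng):
        p = np.concatenate([rng.uniform(0, 1e-3, 50),
                            rng.uniform(0, 1, 450)])
        q, pi0 = storey_qvalue(p)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        assert (q >= pi0 * bh - 1e-12).all()

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            storey_qvalue(np.array([]))


class TestBonferroni:
    def test_study_scale_threshold(self):
        thr = bonferroni_threshold(0.05, 13_293_727)
        assert float(f"{thr:.1e}") == pytest.approx(3.8e-9)

    def test_single_test(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.01, 10) == pytest.approx(0.001)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestClusters:
    def test_order_of_magnitude_rule(self):
        df = pd.DataFrame({"p": [9e-13, 5e-12, 1e-12, 2e-11],
                           "pos": [10, 20, 30, 40]})
        out = cluster_variants(df)
        assert out["is_lead"].tolist() == [True, False, False, False]
        assert out["in_cluster"].tolist() == [True, True, True, False]

    def test_single_variant(self):
        out = cluster_variants(pd.DataFrame({"p": [0.5], "pos": [1]}))
        assert out["is_lead"].iloc[0] and out["in_cluster"].iloc[0]

    def test_tied_leads_leftmost_wins(self):
        df = pd.DataFrame({"p": [1e-9, 1e-9], "pos": [200, 100]})
        out = cluster_variants(df)
        assert out.loc[out["pos"] == 100, "is_lead"].iloc[0]
        assert not out.loc[out["pos"] == 200, "is_lead"].iloc[0]
        assert out["in_cluster"].all()


class TestDPrime:
    def test_perfect_ld(self, rng):
        g = rng.integers(0, 3, 100)
        g[0], g[1] = 0, 2
        assert ld_dprime(g, g) == pytest.approx(1.0, abs=1e-6)

    def test_independent_variants_near_zero(self):
        cfg = SimConfig(n_samples=10_000, n_regions=10, seed=8,
                        ld_block_size=1)
        g = simulate_genotypes(cfg, n_variants=6)
        vals = [ld_dprime(g.dosages[:, i], g.dosages[:, j])
                for i, j in itertools.combinations(range(6), 2)]
        assert np.median(vals) < 0.1

    def test_matches_phased_haplotype_oracle(self, rng):
        # haplotypes drawn from a known 4-type distribution; the oracle is
        # the direct D' computed from the *sampled phased* haplotypes
        hap_types = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        haps = hap_types[rng.choice(4, 2 * 5000,
                                    p=[3 / 8, 1 / 8, 1 / 8, 3 / 8])]
        pA, pB = haps[:, 0].mean(), haps[:, 1].mean()
        pAB = (haps[:, 0] & haps[:, 1]).mean()
        D = pAB - pA * pB
        dmax = min(pA * (1 - pB), (1 - pA) * pB) if D > 0 else \
            min(pA * pB, (1 - pA) * (1 - pB))
        oracle = abs(D) / dmax
        g1 = haps[0::2, 0] + haps[1::2, 0]
        g2 = haps[0::2, 1] + haps[1::2, 1]
        est = ld_dprime(g1, g2)
        assert est == pytest.approx(oracle, abs=0.02)

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError):
            ld_dprime(np.zeros(10, dtype=int), np.ones(10, dtype=int))


class TestResolveDistal:
    def test_duplicate_of_lead_returned(self, rng):
        cfg = SimConfig(n_regions=10, seed=4)
        g = simulate_genotypes(cfg, n_variants=50)
        lead = g.dosages[:, 0].astype(float)
        g.dosages[:, 1] = g.dosages[:, 0]
        y = 0.5 * lead + rng.normal(0, 0.5, len(lead))
        cands = pd.DataFrame({"variant_idx": [1]})
        out = resolve_distal(g.dosages[:, 0], 1e-8, cands, g, y)
        assert out is not None
        assert out["variant_idx"] == 1
        assert out["dprime"] == pytest.approx(1.0, abs=1e-6)

    def test_no_candidates(self, rng):
        cfg = SimConfig(n_regions=10, seed=4)
        g = simulate_genotypes(cfg, n_variants=10)
        out = resolve_distal(g.dosages[:, 0], 1e-8,
                             pd.DataFrame({"variant_idx": []}), g,
                             rng.normal(0, 1, 51))
        assert out is None

    def test_recovers_planted_proximal_cause(self):
        # distal variant tags a proximal causal variant through block LD:
        # the proximal cause should be picked in nearly all seeds
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n = 51
            causal_hap = (r.random((2 * n,)) < 0.3).astype(int)
            flip = r.random((2 * n,)) < 0.05
            tag_hap = causal_hap ^ flip
            causal = causal_hap[0::2] + causal_hap[1::2]
            tag = tag_hap[0::2] + tag_hap[1::2]
            other = r.integers(0, 3, n)
            if causal.var() == 0 or tag.var() == 0 or other.var() == 0:
                continue
            y = 0.8 * causal + r.normal(0, 0.8, n)
            dosages = np.column_stack([tag, causal, other]).astype(np.int8)
            variants = pd.DataFrame({
                "chrom": "chr1", "pos": [60_000, 500, 800],
                "id": ["tag", "cause", "bystander"],
                "ref": "A", "alt": "C", "ancestral": "A", "is_indel": False,
                "maf": 0.3})
            g = GenotypeTable(samples=[f"s{i}" for i in range(n)],
                              variants=variants, dosages=dosages)
            cands = pd.DataFrame({"variant_idx": [1, 2]})
            out = resolve_distal(tag.astype(float), 1e-6, cands, g, y)
            if out is not None and out["variant_idx"] == 1:
                hits += 1
        assert hits >= 0.9 * n_seeds


class TestShapePhenotypes:
    def test_point_mass_traits(self):
        fr = pd.DataFrame({"chrom": "chr1", "start": [990.0] * 5,
                           "end": [1010.0] * 5, "midpoint": [1000.0] * 5,
                           "sample": ["s1"] * 5})
        region = pd.Series({"chrom": "chr1", "start": 0, "end": 2000})
        out = shape_phenotypes(fr, region)
        assert out["extent"].iloc[0] == 0.0
        assert abs(out["summit"].iloc[0] - 1000) <= 10

    def test_uniform_extent_is_half_range(self, rng):
        mids = rng.uniform(0, 4000, 4000)
        fr = pd.DataFrame({"chrom": "chr1", "start": mids - 10,
                           "end": mids + 10, "midpoint": mids,
                           "sample": "s1"})
        region = pd.Series({"chrom": "chr1", "start": 0, "end": 4000})
        out = shape_phenotypes(fr, region)
        assert out["extent"].iloc[0] == pytest.approx(2000, rel=0.05)

    def test_under_two_fragments_missing(self):
        fr = pd.DataFrame({"chrom": "chr1", "start": [100.0], "end": [300.0],
                           "midpoint": [200.0], "sample": ["s1"]})
        region = pd.Series({"chrom": "chr1", "start": 0, "end": 1000})
        out = shape_phenotypes(fr, region)
        assert np.isnan(out["extent"].iloc[0])

    def test_summit_shift_detectable_as_qtl(self):
        # two sub-peaks whose relative weight tracks genotype: the summit
        # trait should associate with dosage far below genome-wide thresholds
        r = np.random.default_rng(0)
        n = 51
        g = r.integers(0, 3, n).astype(float)
        summits, samples = [], []
        frames = []
        for j in range(n):
            w = 0.2 + 0.6 * g[j] / 2  # weight on the right sub-peak
            n_frag = 300
            right = int(round(w * n_frag))
            mids = np.concatenate([
                r.normal(1000, 40, n_frag - right),
                r.normal(1500, 40, right)])
            frames.append(pd.DataFrame({
                "chrom": "chr1", "start": mids - 50, "end": mids + 50,
                "midpoint": mids, "sample": f"s{j:03d}"}))
        fr = pd.concat(frames)
        region = pd.Series({"chrom": "chr1", "start": 0, "end": 2500})
        traits = shape_phenotypes(fr, region)
        traits["g"] = g[[int(s[1:]) for s in traits["sample"]]]
        _, _, _, p = linear_qtl(traits["summit"].to_numpy(),
                                traits["g"].to_numpy())
        assert p < 3.8e-9


class TestCausalModels:
    def test_direct_effect_model_selected(self):
        # spurious-edge rate per one-extra-parameter alternative is about
        # P(chi2_1 > ln n), so n = 1000 keeps the expected win rate > 95%
        wins = 0
        n_seeds = 100
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            v = r.integers(0, 3, 1000).astype(float)
            br1 = 0.7 * v + r.normal(0, 1, 1000)
            br2 = r.normal(0, 1, 1000)
            best, _, warn = compare_causal_models(v, br1, br2)
            wins += best == 1
            assert not warn
        assert wins >= 95

    def test_correlated_regions_need_edge(self):
        r = np.random.default_rng(1)
        v = r.integers(0, 3, 500).astype(float)
        shared = r.normal(0, 1, 500)
        br1 = 0.5 * v + shared + r.normal(0, 0.1, 500)
        br2 = 0.5 * v + shared + r.normal(0, 0.1, 500)
        _, bics, _ = compare_causal_models(v, br1, br2)
        with_edge = min(bics[3], bics[5], bics[6])
        without_edge = min(bics[1], bics[2], bics[4], bics[7])
        assert with_edge < without_edge

    def test_constant_variant_errors(self):
        with pytest.raises(ValueError):
            compare_causal_models(np.ones(20), np.zeros(20), np.zeros(20))
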
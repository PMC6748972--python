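import numpy as np
import pandas as pd
import pytest
from scipy import stats

from invpopkit.core_io import InversionRecord, InvpopkitError, VariantPanel
from invpopkit.function_assoc import (
    benjamini_hochberg,
    cluster_gwas_loci,
    count_loci_in_region,
    gwas_enrichment,
    inversion_eqtl,
    joint_lead_eqtl,
    rank_normalize,
)
from invpopkit.synthdata import simulate_expression


class TestRankNormalize:
    def test_three_values_symmetric(self):
        out = rank_normalize([1.0, 2.0, 3.0])
        assert out[1] == pytest.approx(0.0, abs=1e-12)
        assert out[0] == pytest.approx(-out[2])
        assert out[2] > 0

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=50)
        assert np.allclose(rank_normalize(x), rank_normalize(np.exp(x)))

    def test_constant_vector_rejected(self):
        with pytest.raises(InvpopkitError):
            rank_normalize([2.0, 2.0, 2.0, 2.0])

    def test_moments_near_standard_normal(self, rng):
        out = rank_normalize(rng.exponential(size=500))
        assert abs(out.mean()) < 0.01
        assert abs(out.std() - 1) < 0.05

    def test_output_passes_normality(self, rng):
        passed = 0
        for _ in range(20):
            out = rank_normalize(rng.exponential(size=500))
            passed += stats.shapiro(out).pvalue > 0.05
        assert passed >= 18


class TestBenjaminiHochberg:
    @staticmethod
    def _step_up_oracle(p):
        """Direct implementation of the BH step-up adjusted p-values."""
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        return adj

    def test_matches_direct_step_up(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(3, 60))
            assert np.allclose(benjamini_hochberg(p), self._step_up_oracle(p))


class TestInversionEQTL:
    def test_planted_effect_detected(self, unique_sim):
        _, _, _, gt, _ = unique_sim
        expr, _ = simulate_expression(
            gt, effects=np.concatenate([[1.5], np.zeros(19)]),
            noise_sd=1.0, n_genes=20, seed=3)
        res = inversion_eqtl(gt, "inv0", expr, n_expression_pcs=0)
        assert res.table.iloc[0]["feature"] == "gene000"
        assert res.table.iloc[0]["significant"]

    def test_tss_window_rule(self, unique_sim):
        cfg, _, _, gt, _ = unique_sim
        expr, _ = simulate_expression(gt, effects=1.0, noise_sd=1.0,
                                      n_genes=2, seed=4)
        inv = InversionRecord("inv0", "chrS", cfg.span[0], cfg.span[0],
                              cfg.span[1], cfg.span[1])
        tss = {"gene000": ("chrS", cfg.span[0] - 10_000),
               "gene001": ("chrS", cfg.span[1] + 1_200_000)}
        res = inversion_eqtl(gt, "inv0", expr, tss=tss, inv_record=inv,
                             n_expression_pcs=0)
        assert set(res.table["feature"]) == {"gene000"}

    def test_permutation_negative_control(self, unique_sim):
        _, _, _, gt, _ = unique_sim
        expr, _ = simulate_expression(gt, effects=2.0, noise_sd=1.0,
                                      n_genes=30, seed=5)
        res = inversion_eqtl(gt, "inv0", expr, n_expression_pcs=0,
                             permute_seed=11)
        assert res.permuted
        assert res.table["significant"].sum() == 0

    def test_confounded_covariate_demonstration(self, rng):
        """A batch effect correlated with genotype inflates hits when
        ignored and is absorbed when supplied as a covariate."""
        from invpopkit.core_io import GenotypeTable, PopulationPanel

        n = 120
        samples = [f"s{i:03d}" for i in range(n)]
        panel = PopulationPanel(pd.DataFrame({
            "sample_id": samples, "sex": "female", "population": "CEU",
            "group": "EUR", "family_role": "unrelated"}))
        dosage = rng.integers(0, 3, n)
        calls = np.array(["O1/O1", "O1/O2", "O2/O2"])[dosage]
        gt = GenotypeTable(pd.DataFrame({"inv": calls},
                                        index=pd.Index(samples, name="sample_id")),
                           panel)
        batch = dosage * 0.5 + rng.normal(scale=0.5, size=n)
        expr = pd.DataFrame(
            batch[:, None] * 1.0 + rng.normal(size=(n, 25)),
            index=samples, columns=[f"g{i}" for i in range(25)])
        naive = inversion_eqtl(gt, "inv", expr, n_expression_pcs=0)
        adjusted = inversion_eqtl(gt, "inv", expr, n_expression_pcs=0,
                                  covariates=pd.DataFrame({"batch": batch},
                                                          index=samples))
        assert naive.table["significant"].sum() > \
            adjusted.table["significant"].sum()
        assert adjusted.table["significant"].sum() <= 2

    def test_too_few_samples_rejected(self, trio_panel):
        from conftest import make_gt

        gt = make_gt(trio_panel, {"inv": ["O1/O1"] * 10})
        expr = pd.DataFrame(np.ones((10, 2)),
                            index=trio_panel.sample_ids, columns=["a", "b"])
        with pytest.raises(InvpopkitError):
            inversion_eqtl(gt, "inv", expr)


class TestJointLead:
    INV = pd.DataFrame({"feature": ["g1", "g2"], "id": ["inv", "inv"],
                        "p": [1e-8, 0.2], "beta": [1.0, 0.1]})
    VAR = pd.DataFrame({
        "feature": ["g1", "g1", "g2", "g2"],
        "id": ["snp1", "snp2", "snp1", "snp2"],
        "p": [1e-4, 0.3, 1e-5, 0.5],
        "beta": [0.5, 0.2, 0.9, 0.1],
    })

    def test_inversion_lead_when_smallest_p(self):
        res = joint_lead_eqtl(self.INV, self.VAR).set_index("feature")
        assert res.loc["g1", "lead"]
        assert not res.loc["g2", "lead"]
        assert res.loc["g2", "lead_id"] == "snp1"

    def test_tie_break_deterministic_by_effect_then_id(self):
        inv = pd.DataFrame({"feature": ["g"], "id": ["inv"],
                            "p": [0.01], "beta": [0.5]})
        var = pd.DataFrame({"feature": ["g"], "id": ["snp"],
                            "p": [0.01], "beta": [0.8]})
        res = joint_lead_eqtl(inv, var)
        assert res.iloc[0]["lead_id"] == "snp"   # larger |beta| wins the tie
        var2 = var.assign(beta=[0.5])
        res2 = joint_lead_eqtl(inv, var2)
        assert res2.iloc[0]["lead_id"] == "inv"  # then lexicographic id

    def test_missing_feature_skipped(self):
        res = joint_lead_eqtl(self.INV, self.VAR[self.VAR["feature"] == "g1"])
        assert set(res["feature"]) == {"g1"}


class TestGwasLocusClustering:
    def test_nearby_same_phenotype_merged(self):
        df = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "pos": [100_000, 150_000],
            "pvalue": [1e-8, 1e-6], "phenotype": ["asthma", "asthma"]})
        loci = cluster_gwas_loci(df)
        assert len(loci) == 1
        assert loci.iloc[0]["pvalue"] == 1e-8

    def test_same_position_different_phenotypes_kept(self):
        df = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "pos": [100_000, 100_000],
            "pvalue": [1e-8, 1e-6], "phenotype": ["asthma", "height"]})
        assert len(cluster_gwas_loci(df)) == 2

    def test_transitive_chain_single_locus(self):
        # A-B within 90 kb, B-C within 90 kb, A-C 180 kb apart
        df = pd.DataFrame({
            "chrom": ["chr1"] * 3, "pos": [0, 90_000, 180_000],
            "pvalue": [1e-9, 1e-8, 1e-7], "phenotype": ["t"] * 3})
        loci = cluster_gwas_loci(df)
        assert len(loci) == 1
        assert loci.iloc[0]["n_signals"] == 3

    def test_ld_provider_merges_distant_signals(self):
        df = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "pos": [0, 500_000],
            "pvalue": [1e-9, 1e-8], "phenotype": ["t", "t"]})
        loci = cluster_gwas_loci(df, ld=lambda a, b: 0.95)
        assert len(loci) == 1


def _uniform_variants(rng, n=4000, length=1_000_000):
    pos = np.sort(rng.choice(length, size=n, replace=False))
    p = rng.uniform(0.02, 0.5, size=n)
    geno = rng.binomial(1, p[:, None, None], size=(n, 40, 2)).astype(np.int8)
    return VariantPanel(
        chromosome=np.array(["chr1"] * n),
        positions=pos,
        ref=np.array(["A"] * n),
        alt=np.array(["G"] * n),
        genotypes=geno,
        phased=np.zeros((n, 40), dtype=bool),
        samples=[f"s{i}" for i in range(40)],
    )


class TestGwasEnrichment:
    def test_p_conventions_and_matching(self, rng):
        vp = _uniform_variants(rng)
        loci = pd.DataFrame({
            "chrom": ["chr1"] * 30,
            "pos": rng.choice(1_000_000, 30, replace=False),
            "pvalue": 1e-8, "phenotype": "t"})
        inv = InversionRecord("inv", "chr1", 480_000, 480_000, 520_000, 520_000)
        res = gwas_enrichment(loci, inv, vp, n_null=200, seed=1,
                              freq_tol=0.05)
        assert res.n_null == 200
        assert 0 < res.p_value <= 1.0
        obs = count_loci_in_region(loci, "chr1", 460_000, 540_000)
        assert res.observed == obs

    def test_no_observed_loci_p_one(self, rng):
        vp = _uniform_variants(rng)
        loci = pd.DataFrame({"chrom": ["chr2"], "pos": [1], "pvalue": [1e-8],
                             "phenotype": ["t"]})
        inv = InversionRecord("inv", "chr1", 480_000, 480_000, 520_000, 520_000)
        res = gwas_enrichment(loci, inv, vp, n_null=150, seed=2, freq_tol=0.05)
        assert res.observed == 0
        assert res.p_value == 1.0

    def test_null_calibration_fold_near_one(self, rng):
        """Uniformly planted loci show no enrichment: across inversions the
        mean fold is ~1 and small p-values are not over-produced."""
        vp = _uniform_variants(rng)
        loci = pd.DataFrame({
            "chrom": ["chr1"] * 80,
            "pos": rng.choice(1_000_000, 80, replace=False),
            "pvalue": 1e-8, "phenotype": "t"})
        folds, ps = [], []
        for i in range(20):
            start = 100_000 + i * 40_000
            inv = InversionRecord(f"inv{i}", "chr1", start, start,
                                  start + 30_000, start + 30_000)
            res = gwas_enrichment(loci, inv, vp, n_null=120, seed=100 + i,
                                  freq_tol=0.05)
            if np.isfinite(res.fold):
                folds.append(res.fold)
            ps.append(res.p_value)
        assert abs(np.mean(folds) - 1.0) < 0.35
        assert np.mean(np.array(ps) < 0.05) <= 0.15
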
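import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from lipidratios.genotypes import GenotypeData, VARIANT_COLUMNS, read_vcf, write_vcf
from lipidratios.gwas import (
    GRMatrix, VariantQCParams, compute_grm, genomic_inflation, genomic_pcs,
    hwe_test, ld_prune, lmm_gwas, lmm_gwas_multi, loco_grms, prepare_phenotype,
    reml_fit, rint, sample_qc, snp_p_gain, variant_qc,
)
from lipidratios.simulate import GeneticConfig, SyntheticConfig, simulate_genotypes


def make_genotypes(dosages, chrom=None, ref=None, alt=None, r2=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": np.arange(1, m + 1) * 1000,
            "id": [f"v{j}" for j in range(m)],
            "ref": ref if ref is not None else ["A"] * m,
            "alt": alt if alt is not None else ["G"] * m,
            "call_rate": 1.0, "MAC": 0, "MAF": np.nan, "hwe_p": np.nan,
            "imputation_r2": r2 if r2 is not None else np.nan,
            "palindromic": False,
        },
        columns=VARIANT_COLUMNS,
    )
    gt = GenotypeData(
        sample_ids=pd.Index([f"i{i}" for i in range(n)]),
        variants=variants, dosages=dosages,
    )
    gt.refresh_metadata()
    return gt


class TestHWE:
    def test_strong_deviation(self):
        # (50, 0, 50): expected (25, 50, 25) -> chi2 = 25 + 50 + 25 = 100
        p = hwe_test(50, 0, 50)
        assert p == pytest.approx(st.chi2.sf(100, 1), rel=1e-12)
        assert p < 5e-4  # fails the QC filter

    def test_exact_proportions(self):
        assert hwe_test(25, 50, 25) == 1.0

    def test_monomorphic_convention(self):
        assert hwe_test(0, 0, 100) == 1.0
        assert hwe_test(100, 0, 0) == 1.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_test(-1, 0, 0)


class TestSampleQC:
    def test_clean_panel_keeps_everyone(self):
        rng = np.random.default_rng(0)
        gt = make_genotypes(rng.binomial(2, 0.3, (50, 100)))
        kept, report = sample_qc(gt)
        assert kept.n_samples == 50
        assert report.empty

    def test_high_missingness_removed(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, (40, 100)).astype(float)
        d[3, :10] = np.nan  # 10% missing
        kept, report = sample_qc(make_genotypes(d))
        assert "i3" in report["sample_id"].tolist()
        assert "missingness" in report.loc[report.sample_id == "i3", "reason"].iloc[0]
        assert kept.n_samples == 39

    def test_heterozygosity_outlier_removed(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.3, (500, 200)).astype(float)
        d[7] = 1.0  # all-heterozygous sample
        kept, report = sample_qc(make_genotypes(d))
        assert "i7" in report["sample_id"].tolist()
        assert "heterozygosity" in report.loc[report.sample_id == "i7", "reason"].iloc[0]


class TestVariantQC:
    def test_toy_panel_per_filter_counts(self):
        rng = np.random.default_rng(3)
        n = 400
        clean = rng.binomial(2, 0.3, n).astype(float)
        low_call = clean.copy(); low_call[: n // 10] = np.nan      # call rate 0.9
        rare = np.zeros(n); rare[:7] = 1.0                         # MAC 7
        very_rare = np.zeros(n); very_rare[:2] = 1.0               # MAC 2
        hwe_bad = np.r_[np.zeros(n // 2), 2 * np.ones(n // 2)]     # no hets
        pal = rng.binomial(2, 0.45, n).astype(float)               # A/T, MAF~0.45
        low_r2 = rng.binomial(2, 0.3, n).astype(float)
        d = np.column_stack([clean, low_call, rare, very_rare, hwe_bad, pal, low_r2])
        gt = make_genotypes(
            d,
            alt=["G", "G", "G", "G", "G", "T", "G"],
            r2=[0.99, 0.99, 0.99, 0.99, 0.99, 0.99, 0.1],
        )
        kept, report = variant_qc(gt)
        # hand recount: MAC filter catches both rare variants, post-MAC only
        # the very rare one; all other filters catch exactly one variant
        assert report["call_rate"] == 1
        assert report["mac"] == 2
        assert report["post_mac"] == 1
        assert report["hwe"] == 1
        assert report["palindromic"] == 1
        assert report["imputation_r2"] == 1
        assert report["n_kept"] == 1
        assert kept.variants["id"].tolist() == ["v0"]

    def test_all_filters_disabled_is_identity(self):
        rng = np.random.default_rng(4)
        gt = make_genotypes(rng.binomial(2, 0.05, (100, 5)).astype(float))
        params = VariantQCParams(None, None, None, None, None, None)
        kept, report = variant_qc(gt, params)
        assert kept.n_variants == 5
        assert report["n_removed"] == 0

    def test_palindromic_rule_depends_on_maf(self):
        rng = np.random.default_rng(5)
        d = np.column_stack([
            rng.binomial(2, 0.45, 500),  # A/T high MAF -> dropped
            rng.binomial(2, 0.30, 500),  # A/T low MAF -> kept
        ]).astype(float)
        gt = make_genotypes(d, alt=["T", "T"])
        params = VariantQCParams(None, None, None, 0.4, None, None)
        kept, report = variant_qc(gt, params)
        assert report["palindromic"] == 1
        assert kept.variants["id"].tolist() == ["v1"]


class TestGRM:
    def test_duplicated_sample_off_diagonal(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.3, (30, 500)).astype(float)
        d[1] = d[0]
        gt = make_genotypes(d)
        k = compute_grm(gt).matrix
        assert k[0, 1] == pytest.approx(k[0, 0], rel=1e-12)

    def test_unrelated_samples_near_zero(self):
        rng = np.random.default_rng(7)
        gt = make_genotypes(rng.binomial(2, 0.3, (100, 5000)).astype(float))
        k = compute_grm(gt).matrix
        off = k[np.triu_indices_from(k, k=1)]
        assert abs(off.mean()) < 3 / np.sqrt(5000)
        assert np.diag(k).mean() == pytest.approx(1.0, abs=0.1)

    def test_loco_pieces_recombine_to_full(self):
        rng = np.random.default_rng(8)
        gt = make_genotypes(
            rng.binomial(2, 0.3, (40, 200)).astype(float),
            chrom=["1"] * 120 + ["2"] * 80,
        )
        full = compute_grm(gt)
        locos = loco_grms(gt)
        m1 = locos["2"].m_variants   # variants on chrom 1
        m2 = locos["1"].m_variants   # variants on chrom 2
        recombined = (m1 * locos["2"].matrix + m2 * locos["1"].matrix) / (m1 + m2)
        np.testing.assert_allclose(recombined, full.matrix, atol=1e-10)

    def test_exclude_unknown_chromosome(self):
        rng = np.random.default_rng(9)
        gt = make_genotypes(rng.binomial(2, 0.3, (20, 50)).astype(float))
        with pytest.raises(ValueError):
            compute_grm(gt, exclude_chrom="1")  # all variants are on chrom 1


class TestPCs:
    def test_two_subpopulations_separated(self):
        rng = np.random.default_rng(10)
        p1, p2 = rng.uniform(0.1, 0.9, 300), None
        p2 = np.clip(p1 + rng.choice([-0.3, 0.3], 300), 0.05, 0.95)
        d = np.vstack([
            rng.binomial(2, p1, (100, 300)),
            rng.binomial(2, p2, (100, 300)),
        ]).astype(float)
        gt = make_genotypes(d)
        pcs = genomic_pcs(compute_grm(gt), k=2)
        from sklearn.metrics import silhouette_score
        labels = np.r_[np.zeros(100), np.ones(100)]
        assert silhouette_score(pcs[["PC1"]].to_numpy(), labels) > 0.5

    def test_identity_grm_degenerate(self):
        ids = pd.Index([f"i{i}" for i in range(12)])
        grm = GRMatrix(np.eye(12), ids, 1)
        pcs = genomic_pcs(grm, k=3)
        # eigenvalues all 1: columns are unit vectors with the sign convention
        for c in pcs.columns:
            col = pcs[c].to_numpy()
            assert np.linalg.norm(col) == pytest.approx(1.0)
            assert col[np.argmax(np.abs(col))] > 0

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(11)
        gt = make_genotypes(rng.binomial(2, 0.4, (25, 300)).astype(float))
        grm = compute_grm(gt)
        pcs = genomic_pcs(grm, k=25).to_numpy()
        np.testing.assert_allclose(pcs @ pcs.T, grm.matrix, atol=1e-8)

    def test_k_larger_than_n_rejected(self):
        grm = GRMatrix(np.eye(5), pd.Index(list("abcde")), 1)
        with pytest.raises(ValueError):
            genomic_pcs(grm, k=6)


class TestRint:
    def test_blom_offsets_n3(self):
        out = rint([3.0, 1.0, 2.0])
        expect = st.norm.ppf([(3 - 0.375) / 3.25, (1 - 0.375) / 3.25, (2 - 0.375) / 3.25])
        np.testing.assert_allclose(out, expect, atol=1e-10)
        assert out[0] == pytest.approx(0.8694, abs=2e-4)
        assert out[2] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(100)
        np.testing.assert_allclose(rint(x), rint(np.exp(x)), atol=1e-12)

    def test_mean_zero_for_tie_free(self):
        rng = np.random.default_rng(13)
        assert abs(rint(rng.standard_normal(101)).mean()) < 1e-12

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rint([1.0, 1.0, 1.0])


class TestPreparePhenotype:
    def _inputs(self, n=300, seed=14):
        from conftest import make_cohort
        rng = np.random.default_rng(seed)
        cohort = make_cohort(n, seed=seed)
        pcs = pd.DataFrame(
            rng.standard_normal((n, 3)), index=cohort.sample_ids,
            columns=["PC1", "PC2", "PC3"],
        )
        y = pd.Series(rng.standard_normal(n), index=cohort.sample_ids, name="r")
        return y, cohort, pcs

    def test_age_shift_invariance(self):
        y, cohort, pcs = self._inputs()
        out1 = prepare_phenotype(y, cohort, pcs)
        cohort.table["age"] = cohort.table["age"] + 100.0
        out2 = prepare_phenotype(y, cohort, pcs)
        np.testing.assert_allclose(out1.to_numpy(), out2.to_numpy(), atol=1e-6)

    def test_orthogonal_phenotype_is_rint_of_itself(self):
        y, cohort, pcs = self._inputs()
        # residualize y against the design first, so the second residual
        # pass changes nothing and only RINT acts
        design = pd.concat(
            [cohort.table[["age", "sex"]].astype(float), pcs], axis=1
        )
        age, sex = cohort.table["age"].astype(float), cohort.table["sex"].astype(float)
        full = np.column_stack([
            np.ones(len(y)), age, sex, age ** 2, age * sex, age ** 2 * sex,
            pcs.to_numpy(),
        ])
        beta, *_ = np.linalg.lstsq(full, y.to_numpy(), rcond=None)
        resid = pd.Series(y.to_numpy() - full @ beta, index=y.index, name="r")
        out = prepare_phenotype(resid, cohort, pcs)
        np.testing.assert_allclose(out.to_numpy(), rint(resid.to_numpy()), atol=1e-8)

    def test_output_is_normal(self):
        y, cohort, pcs = self._inputs(n=1000)
        out = prepare_phenotype(y, cohort, pcs)
        assert st.shapiro(out.to_numpy()).pvalue > 0.01


class TestLMM:
    def test_identity_grm_equals_ols(self):
        rng = np.random.default_rng(15)
        n, m = 150, 60
        gt = make_genotypes(rng.binomial(2, 0.3, (n, m)).astype(float))
        y = pd.Series(rng.standard_normal(n), index=gt.sample_ids, name="y")
        ident = {"1": GRMatrix(np.eye(n), gt.sample_ids, 1, "1")}
        res = lmm_gwas(y, gt, ident)
        X0 = np.ones((n, 1))
        for j in range(m):
            X = np.column_stack([X0, gt.dosages[:, j]])
            beta, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
            r = y.to_numpy() - X @ beta
            s2 = (r ** 2).sum() / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            assert res.loc[j, "beta"] == pytest.approx(beta[1], abs=1e-8)
            assert res.loc[j, "se"] == pytest.approx(se, abs=1e-8)

    def test_tiny_instance_matches_dense_gls_oracle(self):
        rng = np.random.default_rng(16)
        n, m = 20, 8
        gt = make_genotypes(rng.binomial(2, 0.4, (n, m)).astype(float))
        z = rng.standard_normal((n, 50))
        K = z @ z.T / 50
        grm = {"1": GRMatrix(K, gt.sample_ids, 50, "1")}
        y = pd.Series(rng.standard_normal(n), index=gt.sample_ids, name="y")
        res = lmm_gwas(y, gt, grm)
        # oracle: dense GLS at the fitted delta
        dvals, U = np.linalg.eigh(K)
        vc = reml_fit(np.clip(dvals, 0, None), U.T @ y.to_numpy(),
                      (U.T @ np.ones(n))[:, None])
        V = K + vc.delta * np.eye(n)
        Vi = np.linalg.inv(V)
        for j in range(m):
            X = np.column_stack([np.ones(n), gt.dosages[:, j]])
            A = X.T @ Vi @ X
            beta = np.linalg.solve(A, X.T @ Vi @ y.to_numpy())
            assert res.loc[j, "beta"] == pytest.approx(beta[1], abs=1e-10)

    def test_null_calibration_and_inflation(self):
        # no genetic effect: p-value rate at 0.05 and genomic lambda ~ 1 at
        # n = 1000, m = 5000; lambda is averaged over independent panels
        # because a single median of 5000 chi2 draws has MC SE ~ 0.03
        n, m = 1000, 5000
        lams, ps = [], []
        for seed in (101, 102, 103):
            rng = np.random.default_rng(seed)
            config = SyntheticConfig(
                n_samples=(10, n),
                genetics=GeneticConfig(n_snps=m, n_chromosomes=5, effect_a=0.0,
                                       polygenic_h2=0.0),
                seed=seed,
            )
            gt = simulate_genotypes(config)
            y = pd.Series(rng.standard_normal(n), index=gt.sample_ids, name="y")
            res = lmm_gwas(y, gt, loco_grms(gt))
            ps.append(res["p"].to_numpy())
            lams.append(genomic_inflation(res["p"]))
        pooled = np.concatenate(ps)
        frac = (pooled < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / pooled.size)
        assert 0.95 < np.mean(lams) < 1.05

    def test_effect_monotonicity_and_loco_direction(self):
        # larger per-allele effects give smaller causal p; excluding the
        # causal chromosome from the GRM never weakens the test statistic
        from lipidratios.validation import causal_locus_trial
        ps = []
        for a in (0.05, 0.15):
            r = causal_locus_trial(seed=5, n_samples=800, n_snps=1000, effect_a=a)
            ps.append(r["causal_p"])
        assert ps[1] < ps[0]

    def test_loco_vs_included_chromosome(self):
        config = SyntheticConfig(
            n_samples=(10, 600), n_species=60, n_classes=10,
            genetics=GeneticConfig(n_snps=800, n_chromosomes=4, effect_a=0.2),
            seed=18,
        )
        from lipidratios.simulate import simulate_cohort
        from lipidratios.io import resolve_selector
        from lipidratios.ratios import _side_sum
        gt = simulate_genotypes(config)
        ds, co = simulate_cohort(config, cohort="b", genotypes=gt)
        conc = ds.concentrations.loc[ds.biological_samples()]
        g = config.genetics
        lr = np.log2(_side_sum(conc, resolve_selector(g.numerator_class, ds.annotations)))
        lr = lr - np.log2(_side_sum(conc, resolve_selector(g.denominator_class, ds.annotations)))
        lr = pd.Series((lr - lr.mean()) / lr.std(ddof=1), index=conc.index, name="r")
        causal_chrom = str(g.causal_chrom)
        on_chrom = (gt.variants["chrom"].astype(str) == causal_chrom).to_numpy()
        panel = gt.subset_variants(on_chrom)
        res_loco = lmm_gwas(lr, panel, {causal_chrom: compute_grm(gt, exclude_chrom=causal_chrom)})
        res_incl = lmm_gwas(lr, panel, {causal_chrom: compute_grm(gt)})
        t_loco = abs(res_loco.set_index("id").loc["rs_causal", "beta"]
                     / res_loco.set_index("id").loc["rs_causal", "se"])
        t_incl = abs(res_incl.set_index("id").loc["rs_causal", "beta"]
                     / res_incl.set_index("id").loc["rs_causal", "se"])
        assert t_loco >= t_incl


class TestSnpPGain:
    def _results(self, seed=19, m=30):
        rng = np.random.default_rng(seed)
        def frame():
            return pd.DataFrame({
                "chrom": ["1"] * m, "pos": np.arange(m), "id": [f"v{j}" for j in range(m)],
                "ref": "A", "alt": "G", "af": 0.3,
                "beta": rng.standard_normal(m), "se": 1.0,
                "p": rng.uniform(1e-12, 1, m), "n": 100,
            }).assign(significant=lambda d: d.p < 5e-8)
        return frame(), frame(), frame()

    def test_matches_scalar_loop(self):
        r, a, b = self._results()
        out = snp_p_gain(r, a, b, n_significant_snps=4)
        for i in range(len(r)):
            expect = min(a.loc[i, "p"], b.loc[i, "p"]) / r.loc[i, "p"]
            assert out.loc[i, "p_gain"] == pytest.approx(expect, rel=1e-12)
            assert out.loc[i, "p_gain_significant"] == (expect > 40)

    def test_equal_ps_give_unit_gain(self):
        r, a, b = self._results()
        a["p"] = r["p"]; b["p"] = r["p"] * 2
        out = snp_p_gain(r, a, b, n_significant_snps=1)
        np.testing.assert_allclose(out["p_gain"], 1.0)

    def test_mismatched_variants_rejected(self):
        r, a, b = self._results()
        with pytest.raises(ValueError):
            snp_p_gain(r, a.iloc[:-1], b)


class TestVcfRoundTrip:
    def test_write_read_dosages(self, tmp_path, small_config):
        gt = simulate_genotypes(small_config)
        path = tmp_path / "panel.vcf"
        write_vcf(gt, path)
        back = read_vcf(path)
        assert list(back.sample_ids) == list(gt.sample_ids)
        np.testing.assert_allclose(back.dosages, gt.dosages, atol=5e-4)
        assert back.variants["chrom"].tolist() == gt.variants["chrom"].tolist()
        assert back.variants["pos"].tolist() == gt.variants["pos"].tolist()

    def test_missing_dosage_round_trip(self, tmp_path):
        rng = np.random.default_rng(20)
        d = rng.binomial(2, 0.3, (10, 4)).astype(float)
        d[2, 1] = np.nan
        gt = make_genotypes(d)
        write_vcf(gt, tmp_path / "m.vcf")
        back = read_vcf(tmp_path / "m.vcf")
        assert np.isnan(back.dosages[2, 1])


def test_ld_prune_removes_block(small_config):
    gt = simulate_genotypes(small_config)
    pruned = ld_prune(gt, r2_threshold=0.2)
    block_ids = set(gt.variants.loc[gt.variants["ld_block"], "id"])
    kept = set(pruned.variants["id"])
    assert len(kept & block_ids) <= 2  # at most the block seed survives pruning
    assert pruned.n_variants > 0.8 * gt.n_variants
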
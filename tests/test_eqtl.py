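import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netpres.eqtl import (
    classify_cis_trans,
    conditional_scan,
    fit_eqtl,
    hwe_chisq,
    snp_qc,
    trans_set_enrichment,
)
from netpres.types import DosageMatrix, ExpressionMatrix, GenePosition, SnpInfo


def _dm(values, snps=None, samples=None, **kw):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    snps = snps or [f"rs{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return DosageMatrix(pd.DataFrame(values, index=snps, columns=samples), **kw)


def _em(values, genes=None, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestSnpQc:
    def test_low_maf_removed(self):
        rng = np.random.default_rng(0)
        dm = _dm(rng.binomial(2, [[0.005], [0.3]], size=(2, 200)))
        rep = snp_qc(dm)
        assert "rs0" not in rep.kept.snps and "rs1" in rep.kept.snps
        assert rep.fails.iloc[0]["reason"] == "maf"

    def test_hwe_equilibrium_retained(self):
        stat, p = hwe_chisq(25, 50, 25)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hwe_chisq_matches_hand_oracle(self):
        # counts (40, 20, 40): p = q = 0.5, expected (25, 50, 25)
        stat, p = hwe_chisq(40, 20, 40)
        expected_stat = (40 - 25) ** 2 / 25 + (20 - 50) ** 2 / 50 + (40 - 25) ** 2 / 25
        assert stat == pytest.approx(expected_stat, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(expected_stat, 1), abs=1e-15)

    def test_hwe_failure_removes_snp(self):
        rng = np.random.default_rng(1)
        dm = _dm(rng.binomial(2, 0.5, size=(1, 100)))
        counts = pd.DataFrame({"n_aa": [40], "n_ab": [20], "n_bb": [40]}, index=["rs0"])
        _, p = hwe_chisq(40, 20, 40)
        rep = snp_qc(dm, genotype_counts=counts)
        assert ("rs0" in rep.kept.snps) == (p >= 1e-5)

    def test_low_imputation_quality_removed(self):
        rng = np.random.default_rng(2)
        values = rng.binomial(2, 0.4, size=(2, 100)).astype(float)
        dm = _dm(values, r2=pd.Series([0.2, 0.9], index=["rs0", "rs1"]))
        rep = snp_qc(dm)
        assert list(rep.kept.snps) == ["rs1"]

    def test_empty_output_warns(self):
        dm = _dm(np.full((1, 50), 0.005))
        with pytest.warns(UserWarning):
            rep = snp_qc(dm)
        assert len(rep.kept.snps) == 0


class TestFitEqtl:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.3, 60).astype(float)
        em = _em(2.0 * d)
        rec = fit_eqtl(_dm(d), em).iloc[0]
        assert rec["beta"] == pytest.approx(2.0, abs=1e-10)
        assert rec["p"] < 1e-30

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 80
        d = rng.binomial(2, 0.25, n).astype(float)
        cov = pd.DataFrame(
            rng.normal(size=(n, 2)), index=[f"s{i}" for i in range(n)], columns=["age", "sex"]
        )
        y = 0.3 * d + 0.5 * cov["age"].values + rng.normal(size=n)
        rec = fit_eqtl(_dm(d), _em(y), covariates=cov).iloc[0]
        x = sm.add_constant(np.column_stack([d, cov.values]))
        fit = sm.OLS(y, x).fit()
        assert rec["beta"] == pytest.approx(fit.params[1], abs=1e-10)
        assert rec["se"] == pytest.approx(fit.bse[1], abs=1e-10)
        assert rec["p"] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_simulated_beta_recovered_within_3_se(self):
        rng = np.random.default_rng(5)
        n = 300
        d = rng.binomial(2, 0.2, n).astype(float)
        y = 0.4 * d + rng.normal(size=n)
        rec = fit_eqtl(_dm(d), _em(y)).iloc[0]
        assert abs(rec["beta"] - 0.4) < 3 * rec["se"]

    def test_power_matches_noncentral_t(self):
        # many replicate phenotypes against one dosage vector: empirical
        # power at genome-wide alpha vs the exact noncentral-t computation
        rng = np.random.default_rng(14)
        n, beta, maf, n_rep = 300, 0.4, 0.2, 4000
        d = rng.binomial(2, maf, n).astype(float)
        y = beta * d + rng.normal(size=(n_rep, n))
        em = _em(y)
        recs = fit_eqtl(_dm(d), em)
        alpha = 5e-8
        power_emp = (recs["p"] < alpha).mean()
        sxx = np.sum((d - d.mean()) ** 2)
        ncp = beta * np.sqrt(sxx)
        df = n - 2
        t_crit = stats.t.ppf(1 - alpha / 2, df)
        power_th = stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
        sd = np.sqrt(power_th * (1 - power_th) / n_rep)
        assert abs(power_emp - power_th) < 4 * sd

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(6)
        n = 100
        d = rng.binomial(2, 0.3, n).astype(float)
        em = _em(rng.normal(size=(800, n)))
        recs = fit_eqtl(_dm(d), em)
        # Kolmogorov-Smirnov against uniform, generous alpha
        ks = stats.kstest(recs["p"].values, "uniform")
        assert ks.pvalue > 0.001
        frac = (recs["p"] < 0.05).mean()
        assert 0.02 < frac < 0.09

    def test_zero_variance_dosage_skipped(self):
        rng = np.random.default_rng(7)
        dm = _dm(np.ones((1, 50)))
        em = _em(rng.normal(size=(2, 50)))
        with pytest.warns(UserWarning, match="zero dosage variance"):
            recs = fit_eqtl(dm, em)
        assert recs.empty

    def test_too_few_shared_samples_raises(self):
        rng = np.random.default_rng(8)
        dm = _dm(rng.binomial(2, 0.5, 10).astype(float))
        em = _em(rng.normal(size=(1, 10)))
        with pytest.raises(ValueError):
            fit_eqtl(dm, em)

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(9)
        n = 50
        d = rng.binomial(2, 0.5, n).astype(float)
        c = rng.normal(size=n)
        cov = pd.DataFrame(
            {"a": c, "b": 2 * c}, index=[f"s{i}" for i in range(n)]
        )
        with pytest.raises(ValueError):
            fit_eqtl(_dm(d), _em(rng.normal(size=n)), covariates=cov)


class TestCisTrans:
    def _gene(self):
        return GenePosition("g", "1", 5_000_000, 5_000_500)

    def test_exact_window_boundary_is_cis(self):
        gene = self._gene()
        assert classify_cis_trans(SnpInfo("s", "1", 4_000_000), gene) == "cis"
        assert classify_cis_trans(SnpInfo("s", "1", 3_999_999), gene) == "trans"
        assert classify_cis_trans(SnpInfo("s", "1", 6_000_500), gene) == "cis"
        assert classify_cis_trans(SnpInfo("s", "1", 6_000_501), gene) == "trans"

    def test_other_chromosome_is_trans(self):
        assert classify_cis_trans(SnpInfo("s", "2", 5_000_000), self._gene()) == "trans"

    def test_random_placements_match_bruteforce(self):
        rng = np.random.default_rng(10)
        gene = self._gene()
        for _ in range(1000):
            chrom = str(rng.integers(1, 3))
            pos = int(rng.integers(1, 10_000_000))
            got = classify_cis_trans(SnpInfo("s", chrom, pos), gene)
            expected = (
                "cis"
                if chrom == gene.chrom
                and gene.start - 1_000_000 <= pos <= gene.end + 1_000_000
                else "trans"
            )
            assert got == expected

    def test_window_symmetric(self):
        gene = self._gene()
        up = classify_cis_trans(SnpInfo("s", "1", gene.start - 999_999), gene)
        down = classify_cis_trans(SnpInfo("s", "1", gene.end + 999_999), gene)
        assert up == down == "cis"


class TestConditionalScan:
    def test_identical_snps_flagged_collinear(self):
        rng = np.random.default_rng(11)
        d = rng.binomial(2, 0.4, 60).astype(float)
        dm = _dm(np.vstack([d, d]), snps=["lead", "cond"])
        em = _em(rng.normal(size=(1, 60)))
        with pytest.warns(UserWarning, match="collinear"):
            out = conditional_scan(dm, em, None, "lead", "cond")
        assert out["collinear_flag"].all()
        assert np.isinf(out["se"]).all()

    def test_mediated_effect_vanishes(self):
        # lead is a proxy (LD r^2 ~ 0.55) of the causal SNP: conditioning on
        # the causal SNP removes the lead association in most runs
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 400
            causal = rng.binomial(2, 0.3, n).astype(float)
            # correlated proxy: copy with noise re-draws
            swap = rng.random(n) < 0.25
            lead = causal.copy()
            lead[swap] = rng.binomial(2, 0.3, int(swap.sum()))
            y = 0.4 * causal + rng.normal(size=n)
            dm = _dm(np.vstack([lead, causal]), snps=["lead", "causal"])
            out = conditional_scan(dm, _em(y), None, "lead", "causal")
            hits += out.iloc[0]["p"] > 0.05
        assert hits >= 17  # >= 90% of runs, allowing Monte-Carlo slack

    def test_conditioning_on_independent_snp_keeps_beta(self):
        rng = np.random.default_rng(12)
        n = 300
        lead = rng.binomial(2, 0.3, n).astype(float)
        other = rng.binomial(2, 0.4, n).astype(float)
        y = 0.4 * lead + rng.normal(size=n)
        dm = _dm(np.vstack([lead, other]), snps=["lead", "other"])
        em = _em(y)
        plain = fit_eqtl(_dm(lead, snps=["lead"]), em).iloc[0]
        cond = conditional_scan(dm, em, None, "lead", "other").iloc[0]
        assert abs(cond["beta"] - plain["beta"]) < plain["se"]

    def test_missing_snp_raises(self):
        rng = np.random.default_rng(13)
        dm = _dm(rng.binomial(2, 0.5, 40).astype(float), snps=["lead"])
        with pytest.raises(ValueError):
            conditional_scan(dm, _em(rng.normal(size=40)), None, "lead", "nope")


class TestEndToEndTransModule:
    def test_planted_module_trans_snp_hits_majority(self):
        from netpres.synthetic_data import SimConfig, TransEffect, generate_paired_study

        cfg = SimConfig(
            n_genes=600, n_samples_ref=300, n_samples_test=40,
            module_sizes=(100,), preserved_flags=(True,),
            loading_range=(0.7, 0.9), maf_range=(0.2, 0.4), n_snps=8,
            n_probes_per_gene=(1, 1),
            trans_effect=TransEffect(snp_index=0, module_index=1, beta=0.6),
            seed=21,
        )
        study = generate_paired_study(cfg)
        em = study.ref_expression()
        records = fit_eqtl(study.dosages, em, covariates=study.covariates)
        targets = set(study.truth.eqtls[0]["genes"])
        snp = study.truth.eqtls[0]["snp"]
        sub = records[records["snp"] == snp]
        hit_frac = (sub[sub["gene"].isin(targets)]["p"] < 0.01).mean()
        assert hit_frac > 0.5  # majority of module genes
        res = trans_set_enrichment(sub, targets, p_cut=0.01)
        assert res["p"] < 0.01

    def test_null_runs_rarely_enrich(self):
        from netpres.synthetic_data import SimConfig, generate_paired_study

        runs_with_hit = 0
        for seed in range(10):
            cfg = SimConfig(
                n_genes=400, n_samples_ref=200, n_samples_test=40,
                module_sizes=(80,), preserved_flags=(True,),
                loading_range=(0.6, 0.9), n_snps=5, n_probes_per_gene=(1, 1),
                seed=300 + seed,
            )
            study = generate_paired_study(cfg)
            em = study.ref_expression()
            records = fit_eqtl(study.dosages, em, covariates=study.covariates)
            targets = set(
                study.truth.module_labels.index[study.truth.module_labels == 1]
            )
            for snp in study.dosages.snps:
                sub = records[records["snp"] == snp]
                majority = (sub[sub["gene"].isin(targets)]["p"] < 0.01).mean() > 0.5
                res = trans_set_enrichment(sub, targets, p_cut=0.01)
                # the full planted-trans signature: majority of module genes
                # sub-threshold AND significant set enrichment
                if majority and res["p"] < 0.01:
                    runs_with_hit += 1
                    break
        assert runs_with_hit == 0


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric-sum definition of the two-sided exact p."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        pk = stats.hypergeom.pmf(k, n, row1, col1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


class TestTransSetEnrichment:
    def _records(self, target_hits, target_miss, bg_hits, bg_miss):
        genes, ps, targets = [], [], set()
        i = 0
        for count, p, is_target in (
            (target_hits, 1e-4, True),
            (target_miss, 0.5, True),
            (bg_hits, 1e-4, False),
            (bg_miss, 0.5, False),
        ):
            for _ in range(count):
                g = f"g{i}"
                genes.append(g)
                ps.append(p)
                if is_target:
                    targets.add(g)
                i += 1
        return pd.DataFrame({"gene": genes, "p": ps}), targets

    def test_printed_counts_example(self):
        # 15/28 target hits vs 1833/7862 background hits
        records, targets = self._records(15, 13, 1833, 6029)
        res = trans_set_enrichment(records, targets, p_cut=0.01)
        assert res["n_target"] == 28
        assert res["prop_target"] == pytest.approx(15 / 28)
        assert res["prop_background"] == pytest.approx(1833 / 7862)
        assert res["p"] == pytest.approx(
            fisher_two_sided_oracle(15, 13, 1833, 6029), rel=1e-9
        )
        # reproduces the printed P = 5.2e-4 of the proportion comparison
        assert res["p"] == pytest.approx(5.2e-4, abs=0.05e-4)

    def test_equal_proportions_odds_ratio_one(self):
        records, targets = self._records(5, 15, 25, 75)
        res = trans_set_enrichment(records, targets, p_cut=0.01)
        assert res["odds_ratio"] == pytest.approx(1.0)

    def test_extreme_table_minimal_tail(self):
        records, targets = self._records(10, 0, 0, 90)
        res = trans_set_enrichment(records, targets, p_cut=0.01)
        assert res["p"] == pytest.approx(
            fisher_two_sided_oracle(10, 0, 0, 90), rel=1e-9
        )

    def test_empty_target_set_raises(self):
        records, _ = self._records(1, 1, 1, 1)
        with pytest.raises(ValueError):
            trans_set_enrichment(records, set())

    def test_chi2_flag(self):
        records, targets = self._records(15, 13, 1833, 6029)
        res = trans_set_enrichment(records, targets, p_cut=0.01, method="chi2")
        assert 0 < res["p"] < 0.05
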
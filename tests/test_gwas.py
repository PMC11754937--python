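"""Genotype I/O, IBS kinship, and the P3D mixed-model scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exuvar.gwas import (
    GenotypeMatrix,
    KinshipMatrix,
    allele_difference_distance,
    annotate_flanking,
    call_significant,
    ibs_kinship,
    mlm_null_fit,
    mlm_scan,
    preprocess,
    read_genotypes,
    write_genotypes_tsv,
)
from exuvar.simulate import (
    SimulationConfig,
    simulate_gene_models,
    simulate_genotypes,
    write_gff3,
    write_vcf,
)


def toy_genotypes(calls, chroms=None, poss=None):
    calls = np.asarray(calls, dtype=np.int8)
    m = calls.shape[1]
    snps = pd.DataFrame(
        {
            "chrom": chroms or ["1"] * m,
            "pos": poss or list(range(100, 100 + m)),
        }
    )
    return GenotypeMatrix([f"s{i}" for i in range(calls.shape[0])], snps, calls)


class TestGenotypeIO:
    def test_vcf_roundtrip(self, tmp_path, structured_genotypes):
        _, g, _ = structured_genotypes
        sub = g.subset_snps(np.arange(g.n_snps) < 50)
        vcf = tmp_path / "g.vcf"
        write_vcf(sub, vcf)
        back = read_genotypes(vcf)
        assert back.accessions == sub.accessions
        np.testing.assert_array_equal(back.calls, sub.calls)

    def test_tsv_roundtrip_preserves_het_missing(self, tmp_path):
        g = toy_genotypes([[0, 1, 2], [1, -9, 0]])
        p = tmp_path / "g.tsv"
        write_genotypes_tsv(g, p)
        back = read_genotypes(p)
        np.testing.assert_array_equal(back.calls, g.calls)

    def test_multiallelic_skipped_counted(self, tmp_path):
        p = tmp_path / "m.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\n"
            "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t1/1\n"
            "1\t200\t.\tA\tT,G\t.\tPASS\t.\tGT\t0/0\t1/1\n"
        )
        g = read_genotypes(p)
        assert g.n_snps == 1
        assert g.n_skipped_records == 1

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            toy_genotypes([[0, 1], [1, 0]], poss=[200, 100])


class TestPreprocess:
    def test_maf_below_threshold_removed(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 2, size=(105, 3)).astype(np.int8)
        calls[:, 0] = 0
        calls[:4, 0] = 1  # minor count 4 < 5 -> removed
        g = toy_genotypes(calls)
        g2, _ = preprocess(g, maf_min_accessions=5)
        assert g2.n_snps == 2

    def test_het_recoded_to_major(self):
        calls = np.zeros((105, 1), dtype=np.int8)
        calls[:45, 0] = 1
        calls[50, 0] = 2  # het; majority is 0 (60 vs 45)
        g = toy_genotypes(calls)
        g2, _ = preprocess(g, maf_min_accessions=5)
        assert g2.calls[50, 0] == 0

    def test_trait_outlier_masked_per_trait(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 2, size=(30, 2)).astype(np.int8)
        g = toy_genotypes(calls)
        traits = pd.DataFrame(
            {"t1": rng.normal(0, 1, 30), "t2": rng.normal(0, 1, 30)},
            index=g.accessions,
        )
        traits.loc["s5", "t1"] = 50.0  # ~8 SD out
        _, t2 = preprocess(g, traits)
        assert np.isnan(t2.loc["s5", "t1"])
        assert np.isfinite(t2.loc["s5", "t2"])


class TestKinship:
    def test_direct_counts(self):
        g = toy_genotypes([[0, 0, 1, 1], [0, 1, 1, 1]])
        k = ibs_kinship(g)
        assert k.k[0, 1] == pytest.approx(0.75)
        assert np.allclose(np.diag(k.k), 1.0)

    def test_complementary_accessions(self):
        g = toy_genotypes([[0, 0, 0], [1, 1, 1]])
        assert ibs_kinship(g).k[0, 1] == 0.0

    def test_distance_is_exact_complement(self, structured_genotypes):
        _, g, _ = structured_genotypes
        mac = g.minor_allele_counts()
        g2 = g.subset_snps(mac >= 2)
        k = ibs_kinship(g2)
        d = allele_difference_distance(g)
        np.testing.assert_allclose(d.d + k.k, 1.0, atol=1e-12)
        assert np.allclose(np.diag(d.d), 0.0)

    def test_structure_visible_in_kinship(self, structured_genotypes):
        _, g, mem = structured_genotypes
        k = ibs_kinship(g)
        home = mem.to_numpy().argmax(axis=1)
        same = home[:, None] == home[None, :]
        off = ~np.eye(len(home), dtype=bool)
        assert k.k[same & off].mean() > k.k[~same].mean()


class TestMlm:
    def test_identity_kinship_equals_ols(self, structured_genotypes):
        _, g, _ = structured_genotypes
        g2, _ = preprocess(g)
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, g2.n_accessions)
        kin = KinshipMatrix(g2.accessions, np.eye(g2.n_accessions))
        res = mlm_scan(y, g2, kin)
        n = g2.n_accessions
        for j in range(0, 40):
            x = g2.calls[:, j].astype(float)
            sl = stats.linregress(x, y)
            f = sl.rvalue**2 / (1 - sl.rvalue**2) * (n - 2)
            p_ols = stats.f.sf(f, 1, n - 2)
            assert res.table["p"].iloc[j] == pytest.approx(p_ols, abs=1e-8)

    def test_matches_dense_gls_oracle(self):
        """n = 30 brute force with explicit V = sg2 K + se2 I inverse."""
        rng = np.random.default_rng(3)
        cfg = SimulationConfig(n_accessions=30, n_snps=60, seed=4)
        g, _ = simulate_genotypes(cfg)
        g2, _ = preprocess(g, maf_min_accessions=2)
        kin = ibs_kinship(g2)
        y = rng.normal(0, 1, 30) + np.linalg.cholesky(
            kin.k + 1e-8 * np.eye(30)
        ) @ rng.normal(0, 1, 30)
        res = mlm_scan(y, g2, kin)
        v = res.sigma2_g * kin.k + res.sigma2_e * np.eye(30)
        vinv = np.linalg.inv(v)
        for j in range(g2.n_snps):
            x = np.column_stack([np.ones(30), g2.calls[:, j].astype(float)])
            xvx = x.T @ vinv @ x
            beta = np.linalg.solve(xvx, x.T @ vinv @ y)
            resid = y - x @ beta
            s2 = (resid @ vinv @ resid) / (30 - 2)
            se = np.sqrt(np.linalg.inv(xvx)[1, 1] * s2)
            f = (beta[1] / se) ** 2
            p = stats.f.sf(f, 1, 28)
            assert res.table["p"].iloc[j] == pytest.approx(p, rel=1e-6, abs=1e-10)

    def test_variance_component_recovery(self):
        rng = np.random.default_rng(5)
        n = 200
        a = rng.normal(0, 1, (n, 50))
        k = a @ a.T
        d = np.sqrt(np.diag(k))
        corr = k / d[:, None] / d[None, :]
        # map into the IBS range [0, 1]; still PSD (0.5*corr + 0.5*ones)
        k = 0.5 + 0.5 * corr
        np.fill_diagonal(k, 1.0)
        kin = KinshipMatrix([f"s{i}" for i in range(n)], k)
        lam, u = np.linalg.eigh(k)
        ratios = []
        for _ in range(30):
            gvals = u @ (rng.normal(0, 1, n) * np.sqrt(np.maximum(lam, 0)))
            y = np.sqrt(2.0) * gvals + rng.normal(0, 1, n)
            sg, se, _ = mlm_null_fit(y, kin)
            ratios.append([sg / 2.0, se / 1.0])
        mean_ratio = np.mean(ratios, axis=0)
        assert np.all(np.abs(mean_ratio - 1.0) < 0.3)

    def test_constant_trait_rejected(self, structured_genotypes):
        _, g, _ = structured_genotypes
        kin = ibs_kinship(g)
        with pytest.raises(ValueError, match="constant"):
            mlm_null_fit(np.ones(g.n_accessions), kin)

    def test_scan_invariances(self, structured_genotypes):
        """Results stable under SNP column order and accession permutation."""
        _, g, _ = structured_genotypes
        g2, _ = preprocess(g)
        kin = ibs_kinship(g2)
        rng = np.random.default_rng(6)
        y = rng.normal(0, 1, g2.n_accessions)
        res = mlm_scan(y, g2, kin)
        p_fwd = res.table["p"].to_numpy()
        # accession permutation applied consistently
        perm = rng.permutation(g2.n_accessions)
        gp = GenotypeMatrix(
            [g2.accessions[i] for i in perm], g2.snps, g2.calls[perm]
        )
        kp = KinshipMatrix([kin.labels[i] for i in perm], kin.k[np.ix_(perm, perm)])
        res_p = mlm_scan(y[perm], gp, kp)
        np.testing.assert_allclose(res_p.table["p"].to_numpy(), p_fwd, rtol=1e-6)


class TestSignificanceAndAnnotation:
    def test_threshold_calls(self):
        table = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "pos": [100, 200],
                "p": [1e-8, 1e-7],
                "neglog10p": [8.0, 7.0],
            }
        )
        from exuvar.gwas import GwasResult

        res = GwasResult("t", table, 1.0, 1.0, 1.0, 105)
        hits = call_significant(res, threshold_neglog10p=7.5)
        assert list(hits["pos"]) == [100]
        empty = call_significant(
            GwasResult("t", table.iloc[:0], 1.0, 1.0, 1.0, 105)
        )
        assert len(empty) == 0

    def test_genic_and_flanking_assignment(self, tmp_path):
        genes = pd.DataFrame(
            [
                dict(gene_id="G1", chrom="1", start=100, end=200, strand="+"),
                dict(gene_id="G2", chrom="1", start=300, end=400, strand="-"),
            ]
        )
        gff = tmp_path / "g.gff3"
        write_gff3(genes, gff)
        hits = pd.DataFrame(
            {"chrom": ["1", "1", "1", "2"], "pos": [150, 250, 50, 500]}
        )
        ann = annotate_flanking(hits, gff)
        assert ann[0].relation == "genic"
        assert [l["gene_id"] for l in ann[0].loci] == ["G1"]
        assert ann[1].relation == "intergenic"
        assert sorted(l["gene_id"] for l in ann[1].loci) == ["G1", "G2"]
        assert ann[2].one_sided and len(ann[2].loci) == 1
        assert ann[3].relation == "unannotated"

    def test_simulated_gene_models_roundtrip(self, tmp_path):
        cfg = SimulationConfig(seed=1)
        genes = simulate_gene_models(cfg, genes_per_chrom=5)
        gff = tmp_path / "s.gff3"
        write_gff3(genes, gff)
        hits = pd.DataFrame({"chrom": ["1"], "pos": [genes.iloc[0]["start"] + 10]})
        ann = annotate_flanking(hits, gff)
        assert ann[0].relation == "genic"
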
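"""Readers, writers and QC filters."""

import numpy as np
import pytest
from scipy import stats

from apoeld.data import (
    MISSING,
    GenotypeDataset,
    QCConfig,
    apply_qc,
    attach_phenotypes,
    compute_maf,
    hwe_test,
    read_genotypes,
    read_phenotypes,
    write_dosage_table,
    write_phenotype_table,
    write_variant_table,
    write_vcf,
)
from conftest import make_sample, make_variant


class TestReadVcf:
    def test_het_alt_effect_gives_dosage_one(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\trsX\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
        )
        ds = read_genotypes(vcf, format="vcf")
        assert ds.dosage_vector("rsX").tolist() == [1]
        assert ds.variant("rsX").effect_allele == "G"

    def test_missing_genotype(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "1\t100\trsX\tA\tG\t.\tPASS\t.\tGT\t./.\t1/1\n"
        )
        ds = read_genotypes(vcf, format="vcf")
        assert ds.dosage_vector("rsX").tolist() == [MISSING, 2]

    def test_ref_effect_allele_flips_dosage(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\trsX\tA\tG\t.\tPASS\t.\tGT\t0/0\n"
        )
        ds = read_genotypes(vcf, format="vcf", effect_alleles={"rsX": "A"})
        assert ds.dosage_vector("rsX").tolist() == [2]


def test_vcf_round_trip_reproduces_matrix(tmp_path):
    rng = np.random.default_rng(42)
    variants = [make_variant(f"rs{k}", chrom=str(1 + k % 3), pos=100 + k)
                for k in range(10)]
    dosages = rng.integers(-1, 3, size=(10, 10)).astype(np.int8)
    samples = [make_sample(f"S{i}") for i in range(10)]
    ds = GenotypeDataset(dosages, variants, samples, "D1")
    path = tmp_path / "rt.vcf"
    write_vcf(ds, path)
    back = read_genotypes(path, format="vcf", dataset_id="D1")
    # writer sorts variants by position; compare by id
    for v in ds.variant_ids:
        np.testing.assert_array_equal(back.dosage_vector(v), ds.dosage_vector(v))


def test_dosage_table_round_trip(tmp_path):
    rng = np.random.default_rng(7)
    variants = [make_variant(f"rs{k}") for k in range(5)]
    dosages = rng.integers(-1, 3, size=(8, 5)).astype(np.int8)
    ds = GenotypeDataset(dosages, variants, [make_sample(f"S{i}") for i in range(8)])
    write_dosage_table(ds, tmp_path / "d.tsv")
    write_variant_table(variants, tmp_path / "v.tsv")
    back = read_genotypes(
        tmp_path / "d.tsv", format="dosage_table", variant_table=tmp_path / "v.tsv"
    )
    np.testing.assert_array_equal(back.dosages, ds.dosages)


def test_dosage_table_rejects_out_of_range(tmp_path):
    (tmp_path / "d.tsv").write_text("sample_id\trs0\nS1\t3\n")
    write_variant_table([make_variant("rs0")], tmp_path / "v.tsv")
    with pytest.raises(ValueError, match="rs0"):
        read_genotypes(tmp_path / "d.tsv", format="dosage_table",
                       variant_table=tmp_path / "v.tsv")


class TestPhenotypes:
    def test_case_and_censored_rows(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "sample_id\tdataset_id\tfamily_id\tsex\tad_status\tage_onset\tage_censor\n"
            "S1\tD1\tF1\tmale\tAD\t78\tNA\n"
            "S2\tD1\tF2\tfemale\tNAD\tNA\t85\n"
        )
        recs = read_phenotypes(path)
        assert recs[0].time == 78 and recs[0].event == 1
        assert recs[1].time == 85 and recs[1].event == 0

    def test_case_without_onset_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "sample_id\tdataset_id\tfamily_id\tsex\tad_status\tage_onset\tage_censor\n"
            "S1\tD1\tF1\tmale\tAD\tNA\t80\n"
        )
        with pytest.raises(ValueError, match="S1"):
            read_phenotypes(path)

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "sample_id\tdataset_id\tfamily_id\tsex\tad_status\tage_onset\tage_censor\n"
            "S1\tD1\tF1\tmale\tAD\t78\tNA\n"
            "S1\tD1\tF1\tmale\tAD\t79\tNA\n"
        )
        with pytest.raises(ValueError, match="S1"):
            read_phenotypes(path)

    def test_attach_reports_unmatched(self, small_dataset, tmp_path):
        write_phenotype_table(small_dataset.samples[:8], tmp_path / "p.tsv")
        phenos = read_phenotypes(tmp_path / "p.tsv")
        joined, unmatched = attach_phenotypes(small_dataset, phenos)
        assert joined.n_samples == 8
        assert unmatched == ["S8", "S9"]


class TestMaf:
    def test_known_values(self):
        assert compute_maf(np.array([0, 0, 1, 1, 2])) == pytest.approx(0.4)
        assert compute_maf(np.array([0, 0, 0, 0])) == 0.0

    def test_matches_direct_allele_counting(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = rng.integers(0, 3, size=50)
            # independent counting oracle: tally alleles one by one
            minor = sum(int(x) for x in d)
            p = minor / (2 * len(d))
            assert compute_maf(d) == pytest.approx(min(p, 1 - p))

    def test_missing_ignored_and_all_missing_errors(self):
        assert compute_maf(np.array([1, 0, MISSING, MISSING])) == pytest.approx(0.25)
        with pytest.raises(ValueError):
            compute_maf(np.array([MISSING]))

    def test_range_invariant(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            d = rng.integers(0, 3, size=rng.integers(1, 30))
            assert 0.0 <= compute_maf(d) <= 0.5


class TestHwe:
    def test_exact_proportions_give_p_one(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_all_heterozygote_chi2_equals_n(self):
        # chi2 = n when every subject is heterozygous
        n = 100
        p = hwe_test(0, n, 0)
        assert p == pytest.approx(float(stats.chi2.sf(n, df=1)))
        assert p < 1e-6

    def test_monomorphic_returns_one(self):
        assert hwe_test(50, 0, 0) == 1.0
        assert hwe_test(0, 0, 50) == 1.0

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            nAA, nAa, naa = rng.integers(1, 100, size=3)
            n = nAA + nAa + naa
            q = (2 * naa + nAa) / (2 * n)
            p = 1 - q
            chi2 = (
                (nAA - n * p * p) ** 2 / (n * p * p)
                + (nAa - 2 * n * p * q) ** 2 / (2 * n * p * q)
                + (naa - n * q * q) ** 2 / (n * q * q)
            )
            expected = stats.chi2.sf(chi2, 1)
            assert hwe_test(int(nAA), int(nAa), int(naa)) == pytest.approx(
                expected, abs=1e-12
            )

    def test_exact_midp_in_unit_interval_and_sane(self):
        p_eq = hwe_test(25, 50, 25, method="exact")
        p_bad = hwe_test(0, 100, 0, method="exact")
        assert 0 < p_bad < 1e-6 < 0.5 < p_eq <= 1


class TestApplyQc:
    def _dataset_with_planted_failures(self):
        rng = np.random.default_rng(11)
        n = 200
        variants = [
            make_variant("rs_ok", pos=1),
            make_variant("rs_low_r2", pos=2, r2=0.65),
            make_variant("rs_missing", pos=3),
            make_variant("rs_rare", pos=4),
            make_variant("rs_hwe", pos=5),
        ]
        good = rng.binomial(2, 0.3, size=(n, 1))
        low_r2 = rng.binomial(2, 0.3, size=(n, 1))
        missing = rng.binomial(2, 0.3, size=(n, 1))
        missing[: int(0.2 * n)] = MISSING
        rare = np.zeros((n, 1), int)
        rare[0] = 1  # MAF 1/400
        hwe_bad = np.ones((n, 1), int)  # all heterozygous
        dosages = np.hstack([good, low_r2, missing, rare, hwe_bad]).astype(np.int8)
        samples = [make_sample(f"S{i}") for i in range(n)]
        return GenotypeDataset(dosages, variants, samples, "D1")

    def test_one_drop_per_rule(self):
        ds = self._dataset_with_planted_failures()
        out, rep = apply_qc(ds)
        assert out.variant_ids == ["rs_ok"]
        assert (
            rep.n_variants_imputation,
            rep.n_variants_missing,
            rep.n_variants_maf,
            rep.n_variants_hwe,
        ) == (1, 1, 1, 1)
        assert rep.dropped_variants["rs_low_r2"] == "imputation_r2"
        assert rep.dropped_variants["rs_hwe"] == "hwe"

    def test_r2_boundary(self):
        # r2 = 0.7 exactly is retained (rule is strictly below threshold)
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, size=(100, 2)).astype(np.int8)
        ds = GenotypeDataset(
            d,
            [make_variant("rs_a", pos=1, r2=0.7), make_variant("rs_b", pos=2, r2=0.69)],
            [make_sample(f"S{i}") for i in range(100)],
        )
        out, _ = apply_qc(ds)
        assert out.variant_ids == ["rs_a"]

    def test_maf_boundary_exactly_five_percent_retained(self):
        n = 100
        d = np.zeros((n, 1), np.int8)
        d[:10, 0] = 1  # MAF = 10/200 = 0.05 exactly
        ds = GenotypeDataset(
            d, [make_variant("rs_b")], [make_sample(f"S{i}") for i in range(n)]
        )
        out, rep = apply_qc(ds, QCConfig(hwe_p_floor=0.0))
        assert out.variant_ids == ["rs_b"]

    def test_idempotent(self):
        ds = self._dataset_with_planted_failures()
        once, _ = apply_qc(ds)
        twice, rep2 = apply_qc(once)
        np.testing.assert_array_equal(once.dosages, twice.dosages)
        assert sum(rep2.to_frame()["n_dropped"]) == 0

    def test_exempt_variants_survive(self):
        n = 50
        d = np.zeros((n, 2), np.int8)
        d[:, 1] = np.random.default_rng(0).binomial(2, 0.3, n)
        ds = GenotypeDataset(
            d,
            [make_variant("rs7412_like", pos=1), make_variant("rs_b", pos=2)],
            [make_sample(f"S{i}") for i in range(n)],
        )
        out, _ = apply_qc(ds, exempt={"rs7412_like"})
        assert "rs7412_like" in out.variant_ids

    def test_empty_after_filtering_errors(self):
        n = 50
        d = np.zeros((n, 1), np.int8)  # monomorphic -> dropped by MAF
        ds = GenotypeDataset(
            d, [make_variant("rs_mono")], [make_sample(f"S{i}") for i in range(n)]
        )
        with pytest.raises(ValueError, match="empty"):
            apply_qc(ds)
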
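"""Site QC: VCF reading, INFO thresholds, exact HWE, filter application."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import hwe_oracle, make_matrix
from sweepscan.vcf_qc import (
    MISSING,
    QCThresholds,
    UnphasedGenotypeError,
    apply_qc,
    filter_info_thresholds,
    hwe_exact_test,
    read_phased_vcf,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=100000>\n"
    "##contig=<ID=X,length=100000>\n"
    '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n'
    '##INFO=<ID=QD,Number=1,Type=Float,Description="qd">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\tS1\n"
)


def _write(tmp_path, body: str):
    path = tmp_path / "in.vcf"
    path.write_text(VCF_HEADER + body)
    return path


class TestReadPhasedVCF:
    def test_aa_tag_flips_polarity(self, tmp_path):
        # AA=G is the ALT base, so ALT carriers are ancestral (coded 0)
        path = _write(
            tmp_path,
            "chr1\t100\t.\tA\tG\t.\tPASS\tAA=G\tGT\t0|1\t1|1\n"
            "chr1\t200\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t1|1\n",
        )
        matrices, _ = read_phased_vcf(path, ancestral_source="AA")
        hm = matrices[0]
        assert hm.alleles[:, 0].tolist() == [1, 0, 0, 0]
        assert hm.alleles[:, 1].tolist() == [0, 1, 1, 1]

    def test_unknown_ancestral_state_dropped_and_counted(self, tmp_path):
        path = _write(
            tmp_path,
            "chr1\t100\t.\tA\tG\t.\tPASS\tAA=T\tGT\t0|1\t1|1\n"
            "chr1\t200\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t0|0\n",
        )
        matrices, report = read_phased_vcf(path, ancestral_source="AA")
        assert report.n_unknown_ancestral == 1
        assert matrices[0].n_sites == 1

    def test_unphased_genotype_raises_with_record_name(self, tmp_path):
        path = _write(tmp_path, "chr1\t100\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0/1\t0|0\n")
        with pytest.raises(UnphasedGenotypeError, match="chr1:100"):
            read_phased_vcf(path)

    def test_sex_chromosome_excluded_and_counted(self, tmp_path):
        path = _write(
            tmp_path,
            "chr1\t100\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t0|0\n"
            "X\t200\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t0|0\n",
        )
        matrices, report = read_phased_vcf(path)
        assert report.n_sex_chrom == 1
        assert {m.chrom for m in matrices} == {"chr1"}

    def test_multiallelic_dropped(self, tmp_path):
        path = _write(
            tmp_path,
            "chr1\t100\t.\tA\tG,T\t.\tPASS\tAA=A\tGT\t0|1\t0|2\n"
            "chr1\t200\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t0|0\n",
        )
        matrices, report = read_phased_vcf(path)
        assert report.n_not_biallelic == 1
        assert matrices[0].n_sites == 1


class TestInfoThresholds:
    def test_boundary_values_pass(self):
        flags = filter_info_thresholds(
            {"QD": 2.0, "FS": 60.0, "MQ": 40.0, "MQRankSum": -12.5, "ReadPosRankSum": -8.0}
        )
        assert all(flags.values())

    @pytest.mark.parametrize(
        "info",
        [{"QD": 1.9}, {"FS": 60.1}, {"MQ": 39.9}, {"MQRankSum": -12.6}, {"ReadPosRankSum": -8.1}],
    )
    def test_each_violation_fails(self, info):
        flags = filter_info_thresholds(info)
        field = next(iter(info))
        assert flags[field] is False
        assert all(v for k, v in flags.items() if k != field)

    def test_absent_fields_pass_by_default_fail_in_strict(self):
        assert all(filter_info_thresholds({}).values())
        assert not any(filter_info_thresholds({}, strict=True).values())

    def test_non_numeric_raises(self):
        with pytest.raises(ValueError, match="non-numeric"):
            filter_info_thresholds({"QD": "high"})


class TestHWEExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(25, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 25) == 1.0

    def test_two_homozygotes_matches_enumeration(self):
        # alleles 2+2: het counts {0, 2}; P(het=0)=1/3, P(het=2)=2/3
        p = hwe_exact_test(1, 0, 1)
        assert p == pytest.approx(hwe_oracle(1, 0, 1), abs=1e-15)
        assert p == pytest.approx(1 / 3, abs=1e-15)

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 51))
            n_aa = int(rng.integers(0, n + 1))
            n_ab = int(rng.integers(0, n - n_aa + 1))
            n_bb = n - n_aa - n_ab
            p = hwe_exact_test(n_aa, n_ab, n_bb)
            assert p == pytest.approx(hwe_oracle(n_aa, n_ab, n_bb), abs=1e-12)

    def test_symmetric_in_homozygote_classes(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 30, size=3)
            if counts.sum() == 0:
                continue
            a, h, b = (int(x) for x in counts)
            assert hwe_exact_test(a, h, b) == hwe_exact_test(b, h, a)

    def test_excess_heterozygosity_is_extreme(self):
        assert hwe_exact_test(0, 50, 0) < 1e-6


class TestApplyQC:
    @staticmethod
    def _hw_column() -> np.ndarray:
        """30 diploids in perfect Hardy-Weinberg proportions at freq 0.5:
        8 hom-ancestral, 15 het, 7 hom-derived."""
        genotypes = [(0, 0)] * 8 + [(0, 1)] * 15 + [(1, 1)] * 7
        return np.array([a for g in genotypes for a in g], dtype=np.int8)

    def test_planted_violations_attributed_to_right_filters(self):
        clean_col = self._hw_column()
        low_maf = np.zeros(60, dtype=np.int8)
        low_maf[0] = 1  # maf 1/60 < 0.05
        gappy = self._hw_column()
        gappy[:8] = MISSING  # 8/60 = 0.133 > 0.10
        all_het = np.array([0, 1] * 30, dtype=np.int8)  # every diploid 0|1
        hm = make_matrix(np.column_stack([clean_col, low_maf, gappy, all_het]))
        clean, records = apply_qc(hm, QCThresholds())
        assert [r.fail_reason for r in records] == [None, "maf", "missing", "hwe"]
        assert clean.n_sites == 1
        assert np.array_equal(clean.alleles[:, 0], clean_col)

    def test_all_het_site_fails_hwe(self):
        alleles = np.tile(np.array([[0], [1]], dtype=np.int8), (30, 1))
        hm = make_matrix(alleles)
        _, records = apply_qc(hm)
        assert records[0].fail_reason == "hwe"
        assert records[0].hwe_p < 1e-6

    def test_boundary_missing_rate_kept(self):
        # exactly 10% missing is retained ("greater than 10%" excludes)
        col = np.array([0, 1] * 20, dtype=np.int8)
        col[:4] = MISSING  # 4/40 = 0.10
        hm = make_matrix(col[:, None])
        _, records = apply_qc(hm)
        assert records[0].missing_rate == pytest.approx(0.10)
        assert records[0].kept

    def test_maf_just_below_threshold_removed(self):
        col = np.zeros(40, dtype=np.int8)
        col[:1] = 1  # maf 0.025
        hm = make_matrix(col[:, None])
        _, records = apply_qc(hm)
        assert records[0].fail_reason == "maf"

    def test_clean_input_is_identity(self, rng):
        cols = []
        for _ in range(30):
            c = rng.integers(0, 2, size=40).astype(np.int8)
            f = c.mean()
            if 0.2 <= f <= 0.8:
                cols.append(c)
        hm = make_matrix(np.column_stack(cols))
        clean, records = apply_qc(hm)
        kept = [r for r in records if r.kept and r.fail_reason is None]
        # HWE may reject a random column by chance; everything kept is identical
        assert clean.n_sites == len(kept)
        idx = [i for i, r in enumerate(records) if r.kept]
        assert np.array_equal(clean.alleles, hm.alleles[:, idx])

    def test_info_failures_rank_first(self):
        col = np.zeros(40, dtype=np.int8)  # would fail maf too
        col[:1] = 1
        hm = make_matrix(col[:, None])
        hm.site_info = [{"QD": 1.0}]
        _, records = apply_qc(hm)
        assert records[0].fail_reason == "info"
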
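"""Pseudo-sibling construction, Mendelian checks, and VCF/pedigree I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from titans import trio_genotypes as tg
from conftest import make_matrix

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
)


def write_vcf(tmp_path, body):
    path = tmp_path / "test.vcf"
    path.write_text(VCF_HEADER + body)
    return str(path)


class TestLoadPhasedVcf:
    def test_roundtrip_single_variant(self, tmp_path):
        path = write_vcf(tmp_path, "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0\n")
        m = tg.load_phased_vcf(path)
        assert m.n_variants == 1 and m.n_samples == 3
        assert m.variants[0].key == ("1", 100, "A", "G")
        np.testing.assert_array_equal(m.dosage("S2"), [2])

    def test_unphased_and_multiallelic_skipped(self, tmp_path):
        body = (
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0\n"
            "1\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t0/1\t1|1\t0|0\n"
            "1\t300\trs3\tA\tG,T\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0\n"
            "1\t400\trs4\tA\tG\t.\tPASS\t.\tGT\t.|.\t1|1\t0|0\n"
        )
        m = tg.load_phased_vcf(write_vcf(tmp_path, body))
        assert m.n_variants == 1
        assert m.skipped == {"multiallelic": 1, "unphased": 1, "missing": 1,
                             "non_biallelic_allele": 0}

    def test_region_filter_and_empty_warning(self, tmp_path):
        body = (
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0\n"
            "1\t500\trs5\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0\n"
        )
        path = write_vcf(tmp_path, body)
        m = tg.load_phased_vcf(path, region="1:400-600")
        assert [v.pos for v in m.variants] == [500]
        with pytest.warns(UserWarning, match="no phased"):
            empty = tg.load_phased_vcf(path, region="1:700-900")
        assert empty.n_variants == 0

    def test_missing_sample_raises(self, tmp_path):
        path = write_vcf(tmp_path, "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0\n")
        with pytest.raises(KeyError, match="S9"):
            tg.load_phased_vcf(path, sample_subset=["S1", "S9"])


class TestPedigree:
    def test_trios_from_fam(self, tmp_path):
        fam = tmp_path / "t.fam"
        fam.write_text(
            "fam1\tF1\t0\t0\t1\t1\n"
            "fam1\tM1\t0\t0\t2\t1\n"
            "fam1\tP1\tF1\tM1\t1\t2\n"
        )
        trios = tg.load_fam(str(fam))
        assert len(trios) == 1
        assert (trios[0].proband_id, trios[0].affected) == ("P1", 2)

    def test_duplicate_member_ids_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            tg.Trio("f", "A", "A", "B")


def _trio_matrix(father, mother, proband):
    m = make_matrix({"F": father, "M": mother, "P": proband})
    return m, tg.Trio("fam1", "P", "F", "M")


class TestPseudoSiblings:
    def test_single_snp_configuration_dosages(self):
        # father 0|1, mother 0|0 -> configuration dosages {0, 0, 1, 1}
        m, trio = _trio_matrix([(0, 1)], [(0, 0)], [(0, 0)])
        s = tg.generate_pseudo_siblings(m, trio)
        assert sorted(s.config_dosages[:, 0].tolist()) == [0, 0, 1, 1]

    def test_two_snp_enumeration_and_conservation(self):
        # brute-force enumeration of the 4 haplotype pairings:
        # father haps (0,0) and (1,1); mother haps (0,1) and (0,0)
        # pairings: (0,1), (0,0), (1,2), (1,1)
        father = [(0, 1), (0, 1)]   # per-variant (h1, h2)
        mother = [(0, 0), (1, 0)]
        m, trio = _trio_matrix(father, mother, [(0, 0), (0, 1)])
        s = tg.generate_pseudo_siblings(m, trio)
        expected = {(0, 1), (0, 0), (1, 2), (1, 1)}
        got = {tuple(int(d) for d in row) for row in s.config_dosages}
        assert got == expected
        fd = np.array([f[0] + f[1] for f in father])
        md = np.array([x[0] + x[1] for x in mother])
        np.testing.assert_array_equal(s.config_dosages.sum(axis=0), 2 * (fd + md))

    def test_proband_match_index(self):
        # proband carries paternal hap 1 + maternal hap 2
        father = [(0, 1), (1, 0)]
        mother = [(1, 0), (0, 1)]
        proband = [(0, 0), (1, 1)]
        m, trio = _trio_matrix(father, mother, proband)
        s = tg.generate_pseudo_siblings(m, trio)
        assert s.proband_match_index == (1, 2)

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_dosage_sum_conservation_property(self, data):
        n_var = data.draw(st.integers(1, 6))
        draw_h = lambda: [(data.draw(st.integers(0, 1)), data.draw(st.integers(0, 1)))
                          for _ in range(n_var)]
        father, mother = draw_h(), draw_h()
        fpick = data.draw(st.integers(0, 1))
        mpick = data.draw(st.integers(0, 1))
        proband = [(father[i][fpick], mother[i][mpick]) for i in range(n_var)]
        m, trio = _trio_matrix(father, mother, proband)
        s = tg.generate_pseudo_siblings(m, trio)
        fd = m.dosage("F")
        md = m.dosage("M")
        np.testing.assert_array_equal(s.config_dosages.sum(axis=0), 2 * (fd + md))
        # Mendelian closure: every configuration dosage bounded by parents
        assert s.proband_match_index is not None
        # determinism
        s2 = tg.generate_pseudo_siblings(m, trio)
        np.testing.assert_array_equal(s.config_dosages, s2.config_dosages)


class TestMendelianConsistency:
    def test_simulator_output_consistent(self, small_dataset):
        # consistency is a per-cis-window property (one window per gene)
        mat, trios = small_dataset.matrix, small_dataset.trios
        m = small_dataset.config.n_snps
        for g in range(len(small_dataset.models)):
            window = list(range(g * m, (g + 1) * m))
            sets = [tg.generate_pseudo_siblings(mat, t, window) for t in trios]
            report = tg.check_mendelian_consistency(sets)
            assert report.consistent.all()
            assert (report.best_mismatch_count == 0).all()

    def test_flipped_allele_flagged(self):
        father = [(0, 1), (0, 0)]
        mother = [(0, 0), (0, 0)]
        proband = [(1, 0), (1, 0)]  # second variant allele impossible
        m, trio = _trio_matrix(father, mother, proband)
        report = tg.check_mendelian_consistency([tg.generate_pseudo_siblings(m, trio)])
        assert not report.consistent.iloc[0]
        assert report.best_mismatch_count.iloc[0] == 1

    def test_homozygous_parents_degenerate(self):
        m, trio = _trio_matrix([(1, 1)], [(0, 0)], [(1, 0)])
        s = tg.generate_pseudo_siblings(m, trio)
        assert np.all(s.config_dosages == 1)
        assert s.proband_match_index == (1, 1)  # lowest index on full tie


class TestSnpPseudoControls:
    @pytest.mark.parametrize(
        "father, mother, proband, expect_proband, expect_controls",
        [
            ((0, 1), (0, 1), (1, 1), 2, [0, 1, 1]),
            ((0, 0), (0, 0), (0, 0), 0, [0, 0, 0]),
            ((1, 1), (0, 0), (1, 0), 1, [1, 1, 1]),
        ],
    )
    def test_control_counts(self, father, mother, proband, expect_proband, expect_controls):
        m, trio = _trio_matrix([father], [mother], [proband])
        res = tg.snp_pseudo_controls(m, trio, 0)
        assert res.consistent
        assert res.proband_count == expect_proband
        assert sorted(res.control_counts.tolist()) == expect_controls
        total = res.proband_count + res.control_counts.sum()
        assert total == 2 * (sum(father) + sum(mother))

    def test_inconsistent_family_flagged(self):
        m, trio = _trio_matrix([(0, 0)], [(0, 0)], [(1, 1)])
        res = tg.snp_pseudo_controls(m, trio, 0)
        assert not res.consistent


def test_parse_region():
    assert tg.parse_region("chr2:1,000-2000") == ("chr2", 1000, 2000)
    assert tg.parse_region("chr2") == ("chr2", None, None)
    with pytest.raises(ValueError):
        tg.parse_region("chr2:50-10")
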
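import numpy as np
import pytest

from sealdrift import genotype_io as gio
from sealdrift.genotype_io import MISSING

from conftest import make_gm


VCF_BODY = """\
##fileformat=VCFv4.2
##INFO=<ID=RAD,Number=1,Type=String,Description="RAD locus identifier">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2
chr1\t100\tL0\tA\tC\t.\t.\tRAD=r1\tGT\t0/0\t0/1\t./.
chr1\t200\tL1\tG\tT\t.\t.\tRAD=r1\tGT\t1/1\t0/0\t0/1
chr1\t300\tL2\tA\tC,G\t.\t.\tRAD=r2\tGT\t0/1\t0/2\t1/2
"""

META = "sample_id\tcolony\tcohort\tyear\ns0\tA\t1973-74\t1973-74\n" \
       "s1\tA\tk1\t1985\ns2\tB\tk1\t1985\n"


@pytest.fixture
def vcf_files(tmp_path):
    vcf = tmp_path / "x.vcf"
    meta = tmp_path / "x.tsv"
    vcf.write_text(VCF_BODY)
    meta.write_text(META)
    return vcf, meta


class TestReadGenotypes:
    def test_dosage_encoding_and_missing(self, vcf_files):
        gm = gio.read_genotypes(*vcf_files)
        assert list(gm.locus_ids) == ["L0", "L1"]
        np.testing.assert_array_equal(
            gm.calls, [[0, 1, MISSING], [2, 0, 1]])
        assert list(gm.radlocus_ids) == ["r1", "r1"]

    def test_multiallelic_dropped_by_default(self, vcf_files):
        gm = gio.read_genotypes(*vcf_files)
        assert "L2" not in gm.locus_ids

    def test_multiallelic_error_policy(self, vcf_files):
        with pytest.raises(ValueError, match="non-biallelic"):
            gio.read_genotypes(*vcf_files, multiallelic="error")

    def test_metadata_missing_sample_named_in_error(self, tmp_path, vcf_files):
        vcf, _ = vcf_files
        meta = tmp_path / "short.tsv"
        meta.write_text("sample_id\tcolony\tcohort\tyear\n"
                        "s0\tA\tk\t1990\ns1\tA\tk\t1990\n")
        with pytest.raises(ValueError, match="s2"):
            gio.read_genotypes(vcf, meta)

    def test_cohort_span_year_is_midpoint(self, vcf_files):
        gm = gio.read_genotypes(*vcf_files)
        assert gm.samples.loc[0, "year"] == pytest.approx(1973.5)


def test_round_trip_preserves_calls_and_metadata(tmp_path):
    rng = np.random.default_rng(5)
    calls = rng.choice([0, 1, 2, MISSING], size=(40, 6))
    calls[(calls == MISSING).all(axis=1), 0] = 1
    gm = make_gm(calls, colonies=["A"] * 3 + ["B"] * 3,
                 cohorts=["k1", "k2"] * 3, years=[1990.0, 2005.0] * 3)
    gio.write_genotypes(gm, tmp_path / "rt.vcf", tmp_path / "rt.tsv")
    back = gio.read_genotypes(tmp_path / "rt.vcf", tmp_path / "rt.tsv")
    np.testing.assert_array_equal(back.calls, gm.calls)
    assert list(back.locus_ids) == list(gm.locus_ids)
    assert list(back.radlocus_ids) == list(gm.radlocus_ids)
    assert back.samples[["sample_id", "colony", "cohort"]].equals(
        gm.samples[["sample_id", "colony", "cohort"]])
    np.testing.assert_allclose(back.samples["year"], gm.samples["year"])


class TestPresenceFilter:
    @pytest.fixture
    def two_group_gm(self):
        # locus 0 typed 8/10 in group A and 2/5 in group B; locus 1 complete
        calls = np.zeros((2, 15), dtype=np.int8)
        calls[0, 8:10] = MISSING       # A: 8/10 typed
        calls[0, 10:13] = MISSING      # B: 2/5 typed
        return make_gm(calls, colonies=["A"] * 10 + ["B"] * 5)

    def test_any_keeps_locus_passing_one_group(self, two_group_gm):
        out = gio.filter_group_presence(two_group_gm, 0.8, "colony", "any")
        assert "L0" in out.locus_ids

    def test_all_drops_locus_failing_one_group(self, two_group_gm):
        out = gio.filter_group_presence(two_group_gm, 0.8, "colony", "all")
        assert "L0" not in out.locus_ids and "L1" in out.locus_ids

    def test_full_presence_boundary(self, two_group_gm):
        out = gio.filter_group_presence(two_group_gm, 1.0, "colony", "any")
        assert list(out.locus_ids) == ["L1"]

    def test_all_subset_of_any(self):
        rng = np.random.default_rng(11)
        calls = rng.choice([0, 1, 2, MISSING], size=(60, 12),
                           p=[0.3, 0.3, 0.2, 0.2])
        calls[(calls == MISSING).all(axis=1), 0] = 0
        gm = make_gm(calls, colonies=["A"] * 6 + ["B"] * 6)
        any_ids = set(gio.filter_group_presence(gm, 0.8, "colony", "any").locus_ids)
        all_ids = set(gio.filter_group_presence(gm, 0.8, "colony", "all").locus_ids)
        assert all_ids <= any_ids

    def test_idempotent(self, two_group_gm):
        once = gio.filter_group_presence(two_group_gm, 0.8, "colony", "all")
        twice = gio.filter_group_presence(once, 0.8, "colony", "all")
        assert list(once.locus_ids) == list(twice.locus_ids)


class TestMafFilter:
    def test_threshold_is_inclusive(self):
        # pooled frequencies 0.04, 0.05, 0.50 over 50 diploids
        n = 50
        calls = np.zeros((3, n), dtype=np.int8)
        calls[0, :4] = 1   # p = 4/100
        calls[1, :5] = 1   # p = 5/100
        calls[2, :50] = 1  # p = 0.5
        gm = make_gm(calls)
        out = gio.filter_maf(gm, 0.05)
        assert list(out.locus_ids) == ["L1", "L2"]

    def test_minor_allele_folding(self):
        calls = np.full((1, 50), 2, dtype=np.int8)
        calls[0, :4] = 1   # alt freq 0.96 -> minor 0.04
        gm = make_gm(calls)
        assert gio.filter_maf(gm, 0.05).n_loci == 0

    def test_zero_threshold_is_identity(self):
        calls = np.array([[0, 1], [2, 2]], dtype=np.int8)
        gm = make_gm(calls)
        assert gio.filter_maf(gm, 0.0) is gm


class TestOneSnpPerRadLocus:
    def test_cardinality(self):
        calls = np.ones((3, 4), dtype=np.int8)
        gm = make_gm(calls, radlocus_ids=["r1", "r1", "r1"], pos=[5, 2, 9])
        out = gio.select_one_snp_per_radlocus(gm, "first")
        assert out.n_loci == 1 and out.pos[0] == 2

    def test_most_complete_keeps_fewest_missing(self):
        calls = np.array([[1, MISSING, MISSING, 1],
                          [1, 1, 1, 1],
                          [1, MISSING, 1, 1]], dtype=np.int8)
        gm = make_gm(calls, radlocus_ids=["r1"] * 3, pos=[1, 2, 3])
        out = gio.select_one_snp_per_radlocus(gm, "most_complete")
        assert list(out.locus_ids) == ["L1"]

    def test_singletons_identity(self):
        calls = np.ones((3, 2), dtype=np.int8)
        gm = make_gm(calls, radlocus_ids=["a", "b", "c"])
        out = gio.select_one_snp_per_radlocus(gm, "first")
        assert list(out.locus_ids) == list(gm.locus_ids)


class TestAlleleFrequencies:
    def test_basic_arithmetic(self):
        gm = make_gm(np.array([[1, 2]], dtype=np.int8))
        ft = gio.allele_frequencies(gm, "all")
        assert ft.freq[0, 0] == pytest.approx(0.75)
        assert ft.n_genes[0, 0] == 4

    def test_all_missing_group_flagged_undefined(self):
        calls = np.array([[1, MISSING]], dtype=np.int8)
        gm = make_gm(calls, colonies=["A", "B"])
        ft = gio.allele_frequencies(gm, "colony")
        j = ft.groups.index("B")
        assert np.isnan(ft.freq[0, j]) and ft.n_genes[0, j] == 0

    def test_single_group_matches_pooled_maf(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([0, 1, 2, MISSING], size=(30, 8))
        calls[(calls == MISSING).all(axis=1), 0] = 0
        gm = make_gm(calls)
        ft = gio.allele_frequencies(gm, "all")
        folded = np.minimum(ft.freq[:, 0], 1 - ft.freq[:, 0])
        np.testing.assert_allclose(folded, gio.pooled_maf(gm))


@pytest.mark.parametrize("value,expected", [
    ("1973-74", 1973.5), ("1973–74", 1973.5), ("1992-1998", 1995.0),
    ("2015", 2015.0), (2004, 2004.0),
])
def test_parse_year(value, expected):
    assert gio.parse_year(value) == pytest.approx(expected)


def test_duplicate_locus_ids_rejected():
    import pandas as pd
    from sealdrift.genotype_io import GenotypeMatrix
    samples = pd.DataFrame({"sample_id": ["s0"], "colony": ["A"],
                            "cohort": ["k"], "year": [2000.0]})
    with pytest.raises(ValueError, match="duplicated locus"):
        GenotypeMatrix(locus_ids=np.array(["L", "L"], dtype=object),
                       radlocus_ids=np.array(["L", "L"], dtype=object),
                       calls=np.array([[1], [2]], dtype=np.int8),
                       samples=samples)
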
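import numpy as np
import pytest

from bingogs import data_io
from bingogs.data_io import (
    FormatError,
    GeneModel,
    GenotypeMatrix,
    GOAnnotationMap,
    MarkerInfo,
    read_gene_models,
    read_genotypes,
    read_go_map,
    read_marker_subset,
    read_phenotypes,
    write_marker_subset,
)
from bingogs.synthetic_fixtures import SimConfig, simulate_genotypes

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1,length=10000>\n"
)


def _write_vcf(tmp_path, body, samples=("s1",)):
    path = tmp_path / "test.vcf"
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
    path.write_text(VCF_HEADER + cols + "\t".join(samples) + "\n" + body)
    return path


class TestReadVCF:
    def test_het_call_is_dosage_one(self, tmp_path):
        path = _write_vcf(tmp_path, "chr1\t100\tm1\tA\tT\t.\tPASS\t.\tGT\t0/1\n")
        geno = read_genotypes(path, "vcf")
        assert geno.dosages.tolist() == [[1.0]]

    def test_missing_genotype_is_nan_not_zero(self, tmp_path):
        path = _write_vcf(tmp_path, "chr1\t100\tm1\tA\tT\t.\tPASS\t.\tGT\t./.\n")
        geno = read_genotypes(path, "vcf")
        assert np.isnan(geno.dosages[0, 0])

    def test_multiallelic_record_skipped(self, tmp_path):
        body = ("chr1\t100\tm1\tA\tT,G\t.\tPASS\t.\tGT\t0/1\n"
                "chr1\t200\tm2\tA\tT\t.\tPASS\t.\tGT\t1/1\n")
        geno = read_genotypes(_write_vcf(tmp_path, body), "vcf")
        assert geno.marker_ids == ["m2"]

    def test_round_trip_small_fixture(self, tmp_path):
        markers = [MarkerInfo("m1", "chr1", 10), MarkerInfo("m2", "chr1", 20)]
        dosages = np.array([[0.0, 2.0], [1.0, np.nan], [2.0, 0.0]])
        geno = GenotypeMatrix(dosages, markers, ["a", "b", "c"])
        data_io.write_vcf(geno, tmp_path / "rt.vcf")
        back = read_genotypes(tmp_path / "rt.vcf", "vcf")
        np.testing.assert_array_equal(back.dosages, geno.dosages)
        assert back.marker_ids == geno.marker_ids
        assert back.sample_ids == geno.sample_ids


class TestPlinkRoundTrip:
    def test_round_trip(self, tmp_path):
        geno = simulate_genotypes(
            SimConfig(n_samples=13, n_markers=50, n_chrom=2, qtn_count=5,
                      missing_frac=0.05, seed=5))
        data_io.write_plink(geno, tmp_path / "g")
        back = read_genotypes(tmp_path / "g", "plink")
        np.testing.assert_array_equal(back.dosages, geno.dosages)
        assert back.marker_ids == geno.marker_ids
        assert back.sample_ids == geno.sample_ids


class TestDosageTSV:
    def test_round_trip(self, tmp_path):
        geno = simulate_genotypes(
            SimConfig(n_samples=7, n_markers=20, n_chrom=1, qtn_count=3, seed=6))
        data_io.write_dosage_tsv(geno, tmp_path / "d.tsv")
        back = read_genotypes(tmp_path / "d.tsv", "tsv")
        np.testing.assert_array_equal(back.dosages, geno.dosages)


class TestGenotypeMatrix:
    def test_markers_resorted_by_position(self):
        markers = [MarkerInfo("b", "chr1", 20), MarkerInfo("a", "chr1", 10)]
        geno = GenotypeMatrix(np.array([[1.0, 2.0]]), markers, ["s"])
        assert geno.marker_ids == ["a", "b"]
        assert geno.dosages.tolist() == [[2.0, 1.0]]

    def test_rejects_bad_dosage_value(self):
        with pytest.raises(ValueError, match="dosage"):
            GenotypeMatrix(np.array([[3.0]]), [MarkerInfo("m", "chr1", 1)], ["s"])

    def test_rejects_duplicate_marker_ids(self):
        markers = [MarkerInfo("m", "chr1", 1), MarkerInfo("m", "chr1", 2)]
        with pytest.raises(ValueError, match="duplicate"):
            GenotypeMatrix(np.zeros((1, 2)), markers, ["s"])

    def test_dosages_in_valid_domain_after_read(self, mini_geno):
        vals = mini_geno.dosages[np.isfinite(mini_geno.dosages)]
        assert np.isin(vals, (0.0, 1.0, 2.0)).all()


class TestPhenotypes:
    def test_na_count(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("sample_id\ttr\n" + "\n".join(
            f"s{i}\t{v}" for i, v in enumerate(["1.0", "2.0", "NA", "0.5", "3"])) + "\n")
        tab = read_phenotypes(path)
        _, vals = tab.complete_cases("tr")
        assert len(vals) == 4

    def test_header_only_gives_empty_table(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("sample_id\ttr\n")
        tab = read_phenotypes(path)
        assert len(tab.sample_ids) == 0

    def test_duplicate_sample_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("sample_id\ttr\ns1\t1\ns1\t2\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_phenotypes(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("sample_id\ttr\ns1\thello\n")
        with pytest.raises(FormatError, match="non-numeric"):
            read_phenotypes(path)

    def test_fixture_round_trip_shape(self, tmp_path, rng):
        n, t = 40, 5
        tab = data_io.PhenotypeTable(
            sample_ids=[f"s{i}" for i in range(n)],
            trait_names=[f"tr{j}" for j in range(t)],
            values=rng.standard_normal((n, t)),
        )
        data_io.write_phenotypes(tab, tmp_path / "p.tsv")
        back = read_phenotypes(tmp_path / "p.tsv")
        assert len(back.trait_names) == 5
        np.testing.assert_allclose(back.values, tab.values)


class TestGeneModels:
    def test_gff3_coordinates_become_half_open(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text("##gff-version 3\n"
                        "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n")
        genes = read_gene_models(path, "gff3")
        assert (genes[0].start, genes[0].end) == (0, 100)

    def test_bed_passes_through(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr1\t0\t100\tgeneA\n")
        genes = read_gene_models(path, "bed")
        assert (genes[0].start, genes[0].end) == (0, 100)
        assert genes[0].gene_id == "geneA"

    def test_missing_id_rejected(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text("chr1\tsrc\tgene\t1\t100\t.\t+\t.\tName=g1\n")
        with pytest.raises(FormatError, match="ID"):
            read_gene_models(path, "gff3")

    def test_start_after_end_rejected(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text("chr1\tsrc\tgene\t200\t100\t.\t+\t.\tID=g1\n")
        with pytest.raises(FormatError, match="start > end"):
            read_gene_models(path, "gff3")

    def test_fixture_count_and_involution(self, tmp_path):
        genes = [GeneModel(f"g{i}", "chr1", 10 * i, 10 * i + 8, "+")
                 for i in range(50)]
        data_io.write_gene_models_gff3(genes, tmp_path / "g.gff3")
        back = read_gene_models(tmp_path / "g.gff3", "gff3")
        assert len(back) == 50
        assert [(g.start, g.end) for g in back] == [(g.start, g.end) for g in genes]


class TestGOMap:
    def test_two_distinct_terms(self, tmp_path):
        path = tmp_path / "go.tsv"
        path.write_text("GO:0000001\tg1\nGO:0000001\tg2\nGO:0000002\tg1\n")
        go = read_go_map(path)
        assert len(go) == 2

    def test_duplicate_rows_collapse(self, tmp_path):
        path = tmp_path / "go.tsv"
        path.write_text("GO:0000001\tg1\nGO:0000001\tg1\n")
        go = read_go_map(path)
        assert go.term_to_genes["GO:0000001"] == {"g1"}

    def test_malformed_term_skipped(self, tmp_path):
        path = tmp_path / "go.tsv"
        path.write_text("NOT_A_TERM\tg1\nGO:0000001\tg1\n")
        go = read_go_map(path)
        assert len(go) == 1

    def test_propagated_parent_contains_child(self, tmp_path):
        lines = [f"GO:0000002\tg{i}" for i in range(3)]
        lines += [f"GO:0000001\tg{i}" for i in range(5)]  # parent superset
        (tmp_path / "go.tsv").write_text("\n".join(lines) + "\n")
        go = read_go_map(tmp_path / "go.tsv")
        assert go.term_to_genes["GO:0000002"] <= go.term_to_genes["GO:0000001"]

    def test_empty_gene_set_invalid(self):
        with pytest.raises(ValueError, match="empty"):
            GOAnnotationMap({"GO:0000001": set()})


class TestMarkerSubsetIO:
    def test_empty_subset_empty_file(self, tmp_path):
        write_marker_subset([], tmp_path / "s.txt")
        assert (tmp_path / "s.txt").read_text() == ""
        assert read_marker_subset(tmp_path / "s.txt") == []

    def test_line_count(self, tmp_path):
        ids = [f"m{i}" for i in range(10)]
        write_marker_subset(ids, tmp_path / "s.txt")
        assert len((tmp_path / "s.txt").read_text().splitlines()) == 10

    def test_round_trip_1000_ids(self, tmp_path):
        ids = [f"snp{i:05d}" for i in range(1000)]
        write_marker_subset(ids, tmp_path / "s.txt")
        assert read_marker_subset(tmp_path / "s.txt") == ids

    def test_unknown_id_rejected_against_reference(self, tmp_path, mini_geno):
        with pytest.raises(KeyError, match="nope"):
            write_marker_subset(["nope"], tmp_path / "s.txt", reference=mini_geno)
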
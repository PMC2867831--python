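import numpy as np
import pytest

from depthcn import iolib
from depthcn.iolib import (
    Chromosome,
    EmptyInputError,
    FormatError,
    GenomeLayout,
    ReadCoordinates,
    UnknownReferenceError,
    load_alignments,
    load_loci,
    read_profile,
    write_alignments_tabular,
    write_profile,
)

SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:1000000\n@SQ\tSN:chr2\tLN:600000\n"


def _write(path, text):
    path.write_text(text)
    return str(path)


class TestGenomeLayout:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GenomeLayout([("chr1", 100), ("chr1", 200)])

    def test_at_most_one_mitochondrial(self):
        with pytest.raises(ValueError, match="mitochondrial"):
            GenomeLayout(
                [("chrM", 100, "mitochondrial"), ("MT", 100, "mitochondrial")]
            )

    def test_role_inference_from_table(self, tmp_path):
        path = _write(tmp_path / "g.tsv", "chr1\t100\nchrX\t50\nchrY\t40\nchrM\t16\n")
        layout = GenomeLayout.from_table(path)
        assert [c.role for c in layout] == [
            "autosome", "allosome_X", "allosome_Y", "mitochondrial",
        ]
        assert layout.mitochondrial == "chrM"
        assert layout.autosomes == ["chr1"]

    def test_from_fasta_lengths(self, tmp_path):
        path = _write(tmp_path / "g.fa", ">chr1\nACGTACGT\nACGT\n>chrM\nACGTAC\n")
        layout = GenomeLayout.from_fasta(path)
        assert layout.length("chr1") == 12
        assert layout.role("chrM") == "mitochondrial"

    def test_table_round_trip(self, toy_layout, tmp_path):
        toy_layout.to_table(tmp_path / "layout.tsv")
        assert GenomeLayout.from_table(tmp_path / "layout.tsv") == toy_layout


class TestLoadAlignmentsSAM:
    def test_unique_filter_and_coordinate_conversion(self, toy_layout, tmp_path):
        # unmapped + MAPQ 0 + MAPQ 60 at chr1:1001 (1-based SAM) -> one
        # retained read at 0-based position 1000
        sam = SAM_HEADER + (
            "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t####\n"
            "r2\t0\tchr1\t500\t0\t4M\t*\t0\t0\tACGT\t####\n"
            "r3\t0\tchr1\t1001\t60\t4M\t*\t0\t0\tACGT\t####\n"
        )
        path = _write(tmp_path / "a.sam", sam)
        reads = load_alignments(path, toy_layout)
        assert reads.n_total_reads == 3
        assert reads.n_aligned == 2
        assert reads.n_unique == 1
        assert list(reads.chrom_positions("chr1")) == [1000]

    def test_secondary_and_supplementary_not_counted(self, toy_layout, tmp_path):
        sam = SAM_HEADER + (
            "r1\t0\tchr1\t101\t60\t4M\t*\t0\t0\tACGT\t####\n"
            "r1\t256\tchr2\t101\t60\t4M\t*\t0\t0\tACGT\t####\n"
            "r1\t2048\tchr2\t201\t60\t4M\t*\t0\t0\tACGT\t####\n"
        )
        reads = load_alignments(_write(tmp_path / "a.sam", sam), toy_layout)
        assert reads.n_total_reads == 1
        assert reads.n_unique == 1

    def test_unknown_reference_is_hard_error(self, toy_layout, tmp_path):
        sam = (
            SAM_HEADER
            + "@SQ\tSN:chrZ\tLN:1000\n"
            + "r1\t0\tchrZ\t10\t60\t4M\t*\t0\t0\tACGT\t####\n"
        )
        with pytest.raises(UnknownReferenceError, match="chrZ"):
            load_alignments(_write(tmp_path / "a.sam", sam), toy_layout)

    def test_empty_file_distinct_from_zero_retained(self, toy_layout, tmp_path):
        with pytest.raises(EmptyInputError):
            load_alignments(_write(tmp_path / "e.sam", SAM_HEADER), toy_layout)
        sam = SAM_HEADER + "r1\t0\tchr1\t10\t0\t4M\t*\t0\t0\tACGT\t####\n"
        with pytest.warns(UserWarning, match="none retained"):
            reads = load_alignments(_write(tmp_path / "z.sam", sam), toy_layout)
        assert reads.n_unique == 0 and reads.n_aligned == 1


class TestLoadAlignmentsTabular:
    def test_multiplicity_preserved(self, toy_layout, tmp_path):
        path = _write(tmp_path / "r.tsv", "chr2\t500\n" * 4)
        reads = load_alignments(path, toy_layout)
        assert list(reads.chrom_positions("chr2")) == [500] * 4
        assert reads.n_unique == 4

    def test_order_independence(self, toy_layout, tmp_path):
        rows = ["chr1\t10", "chr2\t5", "chr1\t3", "chr1\t10", "chr2\t0"]
        a = load_alignments(
            _write(tmp_path / "a.tsv", "\n".join(rows) + "\n"), toy_layout, sample_id="s"
        )
        b = load_alignments(
            _write(tmp_path / "b.tsv", "\n".join(rows[::-1]) + "\n"), toy_layout,
            sample_id="s",
        )
        a.sample_id = b.sample_id = "s"
        assert a == b

    def test_accounting_directives_round_trip(self, toy_layout, tmp_path):
        # library accounting in the style of a real sequencing run: totals
        # survive the write/load cycle even though only retained reads are rows
        reads = ReadCoordinates(
            "female_pool",
            {"chr1": [10, 20, 30]},
            toy_layout,
            n_total_reads=3_283_370,
            n_aligned=3_038_662,
        )
        path = tmp_path / "fp.tsv"
        write_alignments_tabular(reads, path)
        back = load_alignments(path, toy_layout)
        assert back.sample_id == "female_pool"
        assert back.n_total_reads == 3_283_370
        assert back.n_aligned == 3_038_662
        assert back == reads

    def test_out_of_bounds_position(self, toy_layout, tmp_path):
        with pytest.raises(ValueError, match="out of bounds"):
            load_alignments(
                _write(tmp_path / "r.tsv", "chr2\t600000\n"), toy_layout
            )

    def test_accounting_invariant_enforced(self, toy_layout):
        with pytest.raises(ValueError, match="accounting"):
            ReadCoordinates("s", {"chr1": [1, 2, 3]}, toy_layout, n_aligned=2)


class TestLoadLoci:
    def test_bed_is_native_half_open(self, toy_layout, tmp_path):
        path = _write(tmp_path / "l.bed", "chr1\t219000\t319000\tCDKN2A\n")
        assert load_loci(path, toy_layout) == [
            iolib.Locus("CDKN2A", "chr1", 219000, 319000)
        ]

    def test_gff_converted_from_one_based_closed(self, toy_layout, tmp_path):
        gff = "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=G1\n"
        path = _write(tmp_path / "l.gff3", gff)
        assert load_loci(path, toy_layout) == [iolib.Locus("G1", "chr1", 100, 200)]

    def test_degenerate_interval_skipped_with_warning(self, toy_layout, tmp_path):
        path = _write(
            tmp_path / "l.bed", "chr1\t500\t500\tEMPTY\nchr1\t0\t100\tOK\n"
        )
        with pytest.warns(UserWarning, match="EMPTY"):
            loci = load_loci(path, toy_layout)
        assert [l.locus_id for l in loci] == ["OK"]

    def test_malformed_line_reports_line_number(self, toy_layout, tmp_path):
        path = _write(tmp_path / "l.bed", "chr1\t0\t100\tOK\nchr1\tnope\n")
        with pytest.raises(FormatError, match=":2:"):
            load_loci(path, toy_layout)


class TestProfileIO:
    def test_tsv_round_trip_and_seg_values(self, tumor_run, tmp_path):
        profile = tumor_run["profile"]
        write_profile(profile, tmp_path / "p.tsv", "tsv")
        back = read_profile(tmp_path / "p.tsv")
        assert back.sample_id == profile.sample_id
        assert back.mode == pytest.approx(profile.mode, rel=1e-9)
        np.testing.assert_allclose(
            back.table["cn"], profile.table["cn"], rtol=1e-5, equal_nan=True
        )
        np.testing.assert_allclose(
            back.table["sigma"], profile.table["sigma"], rtol=1e-4, equal_nan=True
        )
        assert list(back.table["status"]) == list(profile.table["status"])

        # SEG is log2(CN / ploidy): CN 2 on a diploid autosome -> 0, CN 4 -> 1
        write_profile(profile, tmp_path / "p.seg", "seg")
        lines = (tmp_path / "p.seg").read_text().splitlines()[1:]
        seg = {parts[1] + ":" + parts[2]: float(parts[4])
               for parts in (l.split("\t") for l in lines)}
        truth = tumor_run["truth"]
        for e in tumor_run["windows"]:
            key = f"{e.chrom}:{e.start}"
            if truth.get(e.element_id) == 2:
                assert abs(seg[key]) < 0.3
            elif truth.get(e.element_id) == 4:
                assert abs(seg[key] - 1) < 0.2

    def test_masked_elements_written_as_na(self, tmp_path, toy_layout):
        from conftest import make_count_pair

        from depthcn import normalize

        sample, reference = make_count_pair(
            [100] * 30, [100] * 29 + [10]  # final window under-covered
        )
        dist = normalize.estimate_mode(sample, reference, min_ref_reads=50)
        prof = normalize.normalize_to_reference(
            sample, reference, dist, {"c1": 2.0}
        )
        write_profile(prof, tmp_path / "p.tsv")
        masked_row = (tmp_path / "p.tsv").read_text().splitlines()[-1]
        assert "masked" in masked_row and "\tNA\t" in masked_row
        back = read_profile(tmp_path / "p.tsv")
        assert back.table["status"].iloc[-1] == "masked"
        assert np.isnan(back.table["cn"].iloc[-1])
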
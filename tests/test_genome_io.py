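import numpy as np
import pytest

from chance_qc.genome_io import (
    GenomeTable,
    ParseError,
    UsageError,
    bin_reads,
    deduplicate,
    read_alignments,
    read_genome_table,
    read_quality_records,
    write_bed,
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestGenomeTable:
    def test_round_trip_tsv(self, tmp_path, genome):
        p = write(tmp_path, "g.sizes", "chr1\t5000\nchr2\t2500\n")
        assert read_genome_table(p) == genome

    def test_rejects_duplicate_names_and_bad_lengths(self):
        with pytest.raises(ValueError):
            GenomeTable((("chr1", 100), ("chr1", 200)))
        with pytest.raises(ValueError):
            GenomeTable((("chr1", 0),))

    def test_malformed_line_names_line_number(self, tmp_path):
        p = write(tmp_path, "g.sizes", "chr1\t100\nchr2\n")
        with pytest.raises(ParseError, match=":2"):
            read_genome_table(p)


class TestReadAlignments:
    def test_bed_five_prime_by_strand(self, tmp_path, genome):
        # + strand: 5' is start; - strand: 5' is end-1 (0-based half-open)
        p = write(
            tmp_path,
            "r.bed",
            "chr1\t100\t136\tr1\t0\t+\nchr1\t100\t136\tr2\t0\t-\n",
        )
        rs = read_alignments(p, "BED", genome)
        assert rs.records() == [("chr1", 100, "+"), ("chr1", 135, "-")]

    def test_bed_three_columns_defaults_plus_strand(self, tmp_path, genome):
        p = write(tmp_path, "r.bed", "chr1\t10\t46\n")
        rs = read_alignments(p, "BED", genome)
        assert rs.records() == [("chr1", 10, "+")]

    def test_off_genome_reads_counted_and_dropped(self, tmp_path, genome):
        p = write(tmp_path, "r.bed", "chrUn\t0\t36\nchr1\t0\t36\n")
        rs = read_alignments(p, "BED", genome)
        assert rs.total == 1 and rs.n_off_genome == 1

    def test_malformed_bed_raises_with_line_number(self, tmp_path, genome):
        p = write(tmp_path, "r.bed", "chr1\t0\t36\nchr1\tnope\t36\n")
        with pytest.raises(ParseError, match=":2"):
            read_alignments(p, "BED", genome)

    def test_unknown_format_is_usage_error(self, tmp_path, genome):
        p = write(tmp_path, "r.bed", "chr1\t0\t36\n")
        with pytest.raises(UsageError):
            read_alignments(p, "CRAM", genome)

    def test_sam_unmapped_flag_skipped_and_pos_converted(self, tmp_path, genome):
        sam = (
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:5000\n@SQ\tSN:chr2\tLN:2500\n"
            "r1\t0\tchr1\t101\t30\t36M\t*\t0\t0\t*\t*\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
            "r3\t16\tchr1\t101\t30\t36M\t*\t0\t0\t*\t*\n"
        )
        p = write(tmp_path, "r.sam", sam)
        rs = read_alignments(p, "SAM", genome)
        # SAM POS is 1-based: 101 -> 100; reverse read 5' end = 100+36-1
        assert rs.records() == [("chr1", 100, "+"), ("chr1", 135, "-")]

    def test_bowtie_dialect(self, tmp_path, genome):
        p = write(
            tmp_path,
            "r.bwt",
            "r1\t+\tchr1\t100\tACGT\tIIII\t0\nr2\t-\tchr1\t100\tACGT\tIIII\t0\n",
        )
        rs = read_alignments(p, "bowtie", genome)
        assert rs.records() == [("chr1", 100, "+"), ("chr1", 103, "-")]

    def test_bed_round_trip(self, tmp_path, genome):
        p = write(
            tmp_path,
            "r.bed",
            "chr1\t100\t136\tr1\t0\t+\nchr2\t64\t100\tr2\t0\t-\nchr1\t0\t36\tr3\t0\t+\n",
        )
        rs = read_alignments(p, "BED", genome)
        out = tmp_path / "out.bed"
        write_bed(rs, out)
        rs2 = read_alignments(str(out), "BED", genome)
        assert rs.records() == rs2.records()


class TestDeduplicate:
    def test_identical_records_collapse(self, tmp_path, genome):
        p = write(tmp_path, "r.bed", "chr1\t100\t136\tr\t0\t+\n" * 3)
        rs = deduplicate(read_alignments(p, "BED", genome))
        assert rs.total == 1 and rs.n_duplicates_removed == 2

    def test_strand_distinguishes_keys(self, tmp_path, genome):
        p = write(
            tmp_path, "r.bed", "chr1\t100\t101\tr\t0\t+\nchr1\t99\t101\tr\t0\t-\n"
        )
        # both have 5' position 100 but opposite strand
        rs = deduplicate(read_alignments(p, "BED", genome))
        assert rs.total == 2

    def test_idempotent_and_empty(self, tmp_path, genome):
        p = write(tmp_path, "r.bed", "chr1\t1\t2\tr\t0\t+\nchr1\t1\t2\tr\t0\t+\n")
        once = deduplicate(read_alignments(p, "BED", genome))
        twice = deduplicate(once)
        assert twice.total == once.total and twice.n_duplicates_removed == 0
        empty = write(tmp_path, "e.bed", "")
        assert deduplicate(read_alignments(empty, "BED", genome)).total == 0


class TestBinReads:
    def test_floor_division_binning(self, tmp_path, genome):
        p = write(
            tmp_path,
            "r.bed",
            "chr1\t0\t1\ta\t0\t+\nchr1\t999\t1000\tb\t0\t+\nchr1\t1000\t1001\tc\t0\t+\n",
        )
        cov = bin_reads(read_alignments(p, "BED", genome), genome, 1000)
        assert cov.counts["chr1"][:2].tolist() == [2, 1]

    def test_partial_terminal_bin(self, genome, tmp_path):
        p = write(tmp_path, "e.bed", "")
        cov = bin_reads(read_alignments(p, "BED", genome), genome, 1000)
        assert len(cov.counts["chr2"]) == 3  # 2500 bp -> ceil = 3 bins
        assert cov.total == 0

    def test_count_conservation(self, small_pair):
        ip, _ = small_pair
        assert ip.total == int(ip.concatenated().sum())

    def test_bad_bin_width(self, genome, tmp_path):
        p = write(tmp_path, "e.bed", "chr1\t0\t1\n")
        rs = read_alignments(p, "BED", genome)
        with pytest.raises(UsageError):
            bin_reads(rs, genome, 0)


class TestQualityRecords:
    def test_base_counts_and_phred(self, tmp_path):
        fq = "@a\nAC\n+\nII\n@b\nAN\n+\nI#\n"
        p = write(tmp_path, "r.fq", fq)
        rec = read_quality_records(p, "FASTQ")
        A, C, G, T, N = rec.base_counts
        assert A[0] == 2 and C[1] == 1 and N[1] == 1
        assert rec.qual_hist[40, 0] == 2  # 'I' = 73 - 33 = 40
        assert rec.qual_hist[2, 1] == 1  # '#' = 35 - 33 = 2

    def test_variable_length_reads(self, tmp_path):
        p = write(tmp_path, "r.fq", "@a\nA\n+\nI\n@b\nAC\n+\nII\n")
        rec = read_quality_records(p, "FASTQ")
        assert rec.coverage().tolist() == [2, 1]

    def test_seq_qual_length_mismatch(self, tmp_path):
        p = write(tmp_path, "r.fq", "@a\nACG\n+\nII\n")
        with pytest.raises(ParseError):
            read_quality_records(p, "FASTQ")

    def test_empty_file_gives_zero_records(self, tmp_path):
        p = write(tmp_path, "r.fq", "")
        rec = read_quality_records(p, "FASTQ")
        assert rec.n_reads == 0 and rec.read_length == 0
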
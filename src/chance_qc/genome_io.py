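"""Readers for mapped-read files and reduction to binned genome coverage.

Supported alignment dialects: BED (>=3 columns), tagAlign (6 columns), SAM,
BAM, and bowtie legacy default output.  Every mapped read is reduced to its
5' position (BED start on the + strand, end-1 on the - strand); no fragment
extension or strand shift is applied before binning.  Coordinates are kept
0-based half-open internally; SAM/BAM 1-based POS is converted on input.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam

DEFAULT_BIN_WIDTH = 1000

ALIGNMENT_FORMATS = ("BED", "tagAlign", "SAM", "BAM", "bowtie")


class ParseError(ValueError):
    """A line of an input file does not parse in the declared dialect."""


class UsageError(ValueError):
    """Invalid arguments (unknown format tag, bad parameter)."""


class InputDataError(ValueError):
    """Input data is structurally valid but unusable (e.g. zero reads)."""


@dataclass(frozen=True)
class GenomeTable:
    """Ordered table of (chromosome name, length in bp).

    The ordering is fixed and reused for every genome-wide concatenation of
    per-chromosome vectors, so results are deterministic.
    """

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c for c, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for c, n in self.entries:
            if n <= 0:
                raise ValueError(f"chromosome {c!r} has non-positive length {n}")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.entries]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.entries)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def n_bins(self, bin_width: int) -> dict[str, int]:
        return {c: -(-n // bin_width) for c, n in self.entries}


def read_genome_table(path: str | os.PathLike) -> GenomeTable:
    """Read a two-column chrom-sizes TSV (name, length)."""
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom\\tlength'")
            try:
                length = int(parts[1])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: length {parts[1]!r} is not an integer"
                ) from None
            entries.append((parts[0], length))
    return GenomeTable(tuple(entries))


@dataclass
class ReadSet:
    """Mapped reads reduced to (chromosome, 5' position, strand)."""

    chroms: np.ndarray  # integer codes into genome order
    positions: np.ndarray  # 0-based 5' positions
    strands: np.ndarray  # bool, True == '+'
    genome: GenomeTable
    source_format: str = "unknown"
    n_off_genome: int = 0  # reads dropped: chromosome absent from genome
    n_duplicates_removed: int = 0

    @property
    def total(self) -> int:
        return len(self.positions)

    def records(self) -> list[tuple[str, int, str]]:
        names = self.genome.names
        return [
            (names[c], int(p), "+" if s else "-")
            for c, p, s in zip(self.chroms, self.positions, self.strands)
        ]


@dataclass
class BinnedCoverage:
    """Per-chromosome read counts in fixed-width non-overlapping bins."""

    bin_width: int
    counts: dict[str, np.ndarray]
    genome: GenomeTable

    @property
    def total(self) -> int:
        return int(sum(int(v.sum()) for v in self.counts.values()))

    def concatenated(self) -> np.ndarray:
        """Genome-wide vector in GenomeTable order."""
        return np.concatenate([self.counts[c] for c in self.genome.names])

    @property
    def n_bins(self) -> int:
        return int(sum(len(v) for v in self.counts.values()))

    @classmethod
    def from_concatenated(
        cls, flat: np.ndarray, template: "BinnedCoverage"
    ) -> "BinnedCoverage":
        """Split a genome-wide vector back into per-chromosome pieces."""
        counts, i = {}, 0
        for c in template.genome.names:
            n = len(template.counts[c])
            counts[c] = np.asarray(flat[i : i + n])
            i += n
        if i != len(flat):
            raise ValueError("flat vector length does not match template")
        return cls(template.bin_width, counts, template.genome)


@dataclass
class QualityRecords:
    """Per-position base composition and Phred-quality histograms."""

    read_length: int
    base_counts: np.ndarray  # shape (5, read_length): rows A,C,G,T,N
    qual_hist: np.ndarray  # shape (94, read_length): Phred 0..93
    n_reads: int

    BASES = "ACGTN"

    def coverage(self) -> np.ndarray:
        """Number of reads covering each position (variable-length aware)."""
        return self.base_counts.sum(axis=0)


def _records_to_readset(records, genome, source_format, n_off_genome):
    code = {c: i for i, c in enumerate(genome.names)}
    if records:
        chroms = np.array([code[r[0]] for r in records], dtype=np.int32)
        positions = np.array([r[1] for r in records], dtype=np.int64)
        strands = np.array([r[2] == "+" for r in records], dtype=bool)
    else:
        chroms = np.empty(0, dtype=np.int32)
        positions = np.empty(0, dtype=np.int64)
        strands = np.empty(0, dtype=bool)
    return ReadSet(chroms, positions, strands, genome, source_format, n_off_genome)


def _parse_bed_like(path, genome, n_min_cols, fmt):
    """BED (>=3 cols) and tagAlign (6 cols) share coordinate semantics."""
    records, off = [], 0
    lengths = genome.lengths
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < n_min_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {n_min_cols} columns, got {len(parts)}"
                )
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            strand = parts[5] if len(parts) >= 6 else "+"
            if strand not in "+-":
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if chrom not in lengths:
                off += 1
                continue
            # 5' end: start on +, end-1 on - (0-based half-open interval)
            pos = start if strand == "+" else end - 1
            if not 0 <= pos < lengths[chrom]:
                raise ParseError(
                    f"{path}:{lineno}: position {pos} outside {chrom} (length {lengths[chrom]})"
                )
            records.append((chrom, pos, strand))
    return _records_to_readset(records, genome, fmt, off)


def _parse_sam_bam(path, genome, fmt):
    mode = "rb" if fmt == "BAM" else "r"
    records, off = [], 0
    lengths = genome.lengths
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            chrom = aln.reference_name
            if chrom not in lengths:
                off += 1
                continue
            if aln.is_reverse:
                pos, strand = aln.reference_end - 1, "-"
            else:
                pos, strand = aln.reference_start, "+"
            records.append((chrom, pos, strand))
    return _records_to_readset(records, genome, fmt, off)


def _parse_bowtie(path, genome):
    """Bowtie legacy default output: name, strand, chrom, 0-based offset, seq, quals, ..."""
    records, off = [], 0
    lengths = genome.lengths
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected >= 5 tab-separated columns")
            strand, chrom = parts[1], parts[2]
            if strand not in "+-":
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                start = int(parts[3])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer offset") from None
            if chrom not in lengths:
                off += 1
                continue
            pos = start if strand == "+" else start + len(parts[4]) - 1
            records.append((chrom, pos, strand))
    return _records_to_readset(records, genome, "bowtie", off)


def read_alignments(
    path: str | os.PathLike, format: str, genome: GenomeTable
) -> ReadSet:
    """Read mapped reads in the declared dialect, reduced to 5' positions.

    Unmapped SAM/BAM records are skipped.  Reads on chromosomes absent from
    *genome* are counted in ``n_off_genome`` and dropped.
    """
    if format not in ALIGNMENT_FORMATS:
        raise UsageError(
            f"unknown format {format!r}; expected one of {ALIGNMENT_FORMATS}"
        )
    if format == "BED":
        return _parse_bed_like(path, genome, 3, "BED")
    if format == "tagAlign":
        return _parse_bed_like(path, genome, 6, "tagAlign")
    if format in ("SAM", "BAM"):
        return _parse_sam_bam(path, genome, format)
    return _parse_bowtie(path, genome)


def deduplicate(reads: ReadSet) -> ReadSet:
    """Keep at most one record per (chromosome, position, strand) key.

    Duplicate reads at one genomic coordinate typically reflect PCR
    over-amplification during library preparation.
    """
    if reads.total == 0:
        return ReadSet(
            reads.chroms,
            reads.positions,
            reads.strands,
            reads.genome,
            reads.source_format,
            reads.n_off_genome,
            0,
        )
    keys = np.stack(
        [reads.chroms.astype(np.int64), reads.positions, reads.strands.astype(np.int64)]
    )
    _, idx = np.unique(keys, axis=1, return_index=True)
    idx.sort()
    removed = reads.total - len(idx)
    return ReadSet(
        reads.chroms[idx],
        reads.positions[idx],
        reads.strands[idx],
        reads.genome,
        reads.source_format,
        reads.n_off_genome,
        removed,
    )


def bin_reads(
    reads: ReadSet, genome: GenomeTable | None = None, bin_width: int = DEFAULT_BIN_WIDTH
) -> BinnedCoverage:
    """Count reads' 5' positions in fixed-width non-overlapping bins."""
    if bin_width <= 0:
        raise UsageError(f"bin width must be positive, got {bin_width}")
    genome = genome or reads.genome
    counts = {}
    for i, (chrom, length) in enumerate(genome.entries):
        n_bins = -(-length // bin_width)
        mask = reads.chroms == i
        bins = reads.positions[mask] // bin_width
        counts[chrom] = np.bincount(bins, minlength=n_bins).astype(np.int64)
    return BinnedCoverage(bin_width, counts, genome)


def write_bed(reads: ReadSet, path: str | os.PathLike, read_length: int = 36) -> None:
    """Write a ReadSet as BED6; round-trips through :func:`read_alignments`."""
    names = reads.genome.names
    lengths = reads.genome.lengths
    with open(path, "w") as fh:
        for i, (c, p, s) in enumerate(
            zip(reads.chroms, reads.positions, reads.strands)
        ):
            chrom = names[c]
            if s:  # + strand: 5' end is the interval start
                start = int(p)
                end = min(start + read_length, lengths[chrom])
            else:  # - strand: 5' end is end-1
                end = int(p) + 1
                start = max(end - read_length, 0)
            fh.write(f"{chrom}\t{start}\t{end}\tr{i}\t0\t{'+' if s else '-'}\n")


def read_quality_records(path: str | os.PathLike, format: str) -> QualityRecords:
    """Accumulate per-position base counts and Phred histograms.

    FASTQ qualities are Phred+33.  Variable read lengths are allowed:
    positions beyond a read's length contribute nothing, and per-position
    denominators downstream use the number of reads covering each position.
    """
    if format not in ("FASTQ", "SAM", "BAM"):
        raise UsageError(f"unknown format {format!r}; expected FASTQ, SAM or BAM")
    base_idx = {b: i for i, b in enumerate(QualityRecords.BASES)}
    pairs_iter = _fastq_pairs(path) if format == "FASTQ" else _sambam_pairs(path, format)

    max_len, n_reads = 0, 0
    base_counts = np.zeros((5, 0), dtype=np.int64)
    qual_hist = np.zeros((94, 0), dtype=np.int64)
    for seq, quals in pairs_iter:
        if len(seq) != len(quals):
            raise ParseError(
                f"{path}: SEQ length {len(seq)} != QUAL length {len(quals)}"
            )
        if len(seq) > max_len:
            grow = len(seq) - max_len
            base_counts = np.pad(base_counts, ((0, 0), (0, grow)))
            qual_hist = np.pad(qual_hist, ((0, 0), (0, grow)))
            max_len = len(seq)
        for pos, (b, q) in enumerate(zip(seq.upper(), quals)):
            base_counts[base_idx.get(b, 4), pos] += 1
            qual_hist[min(q, 93), pos] += 1
        n_reads += 1
    return QualityRecords(max_len, base_counts, qual_hist, n_reads)


def _fastq_pairs(path):
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ParseError(f"{path}: malformed FASTQ record at {header!r}")
            yield seq, [ord(c) - 33 for c in qual]


def _sambam_pairs(path, fmt):
    mode = "rb" if fmt == "BAM" else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.query_sequence is None or aln.query_qualities is None:
                continue
            yield aln.query_sequence, list(aln.query_qualities)
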
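"""Seeded synthetic-data generators for every analysis in the package.

These emulate the background/signal mixture that signal extraction scaling
assumes: Input coverage is a Poisson-Gamma (negative-binomial) track, and an
IP track shares the same Gamma-distributed background means with a chosen
fraction of bins amplified by a fold factor before Poisson sampling, so the
planted percentage of genome enriched is 100*s by construction.  Further
generators emit read files in every supported dialect that bin back exactly
to a given coverage, divergence-statistic training tables, reference panels,
and FASTQ files with a planted content/quality artifact window.

All generators take an explicit integer seed; there is no hidden global RNG
state, and outputs are bit-reproducible per seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .genome_io import BinnedCoverage, GenomeTable
from .ses import CATEGORIES, TrainingTable, _divergence_stat

#: fraction of the genome that duplicate-spike reads are concentrated onto;
#: below the 1% amplification-bias rule so a sufficient spike rate trips it
SPIKE_GENOME_FRACTION = 0.005


@dataclass
class EnrichmentSpec:
    """Parameters of a planted-enrichment IP/Input pair.

    Defaults emulate a mammalian-scale run at desk size: 50k 1-kbp bins with
    a background of ~6 reads/kbp (Gamma shape 2, scale 3 — overdispersed, as
    real Input is), 10% of the genome enriched 10-fold, no duplicate spikes.
    """

    n_bins: int = 50_000
    gamma_shape: float = 2.0
    gamma_scale: float = 3.0
    signal_fraction: float = 0.1
    signal_fold: float = 10.0
    duplicate_spike_rate: float = 0.0
    seed: int = 0


def _default_genome(n_bins: int, bin_width: int = 1000) -> GenomeTable:
    return GenomeTable((("chrS", n_bins * bin_width),))


def _as_coverage(counts: np.ndarray, bin_width: int = 1000) -> BinnedCoverage:
    genome = _default_genome(len(counts), bin_width)
    return BinnedCoverage(bin_width, {"chrS": counts.astype(np.int64)}, genome)


def _inject_spikes(counts: np.ndarray, rate: float, rng) -> np.ndarray:
    """Move *rate* of the reads onto a tiny set of bins (duplicate pile-ups)."""
    removed = rng.binomial(counts, rate)
    counts = counts - removed
    n_spike = max(1, int(SPIKE_GENOME_FRACTION * len(counts)))
    spike_bins = rng.choice(len(counts), size=n_spike, replace=False)
    add = rng.multinomial(int(removed.sum()), np.full(n_spike, 1.0 / n_spike))
    counts[spike_bins] += add
    return counts


def gen_binned_pair(spec: EnrichmentSpec) -> tuple[BinnedCoverage, BinnedCoverage]:
    """Planted-enrichment (IP, Input) pair of binned tracks."""
    rng = np.random.default_rng(spec.seed)
    lam = rng.gamma(spec.gamma_shape, spec.gamma_scale, spec.n_bins)
    input_counts = rng.poisson(lam)
    n_signal = int(round(spec.signal_fraction * spec.n_bins))
    ip_lam = lam.copy()
    if n_signal > 0:
        signal_bins = rng.choice(spec.n_bins, size=n_signal, replace=False)
        ip_lam[signal_bins] *= spec.signal_fold
    ip_counts = rng.poisson(ip_lam)
    if spec.duplicate_spike_rate > 0:
        input_counts = _inject_spikes(input_counts, spec.duplicate_spike_rate, rng)
        ip_counts = _inject_spikes(ip_counts, spec.duplicate_spike_rate, rng)
    return _as_coverage(ip_counts), _as_coverage(input_counts)


def gen_reads(
    cov: BinnedCoverage, format: str, path: str | os.PathLike, seed: int = 0
) -> None:
    """Write a read file whose binned coverage equals *cov* exactly.

    Positions are uniform within each bin; strands are random.  Reads are
    emitted with length 1 so the 5' position round-trips identically in
    every dialect.
    """
    rng = np.random.default_rng(seed)
    lengths = cov.genome.lengths
    records = []  # (chrom, pos, strand)
    for chrom in cov.genome.names:
        counts = cov.counts[chrom]
        for b in np.nonzero(counts)[0]:
            lo = int(b) * cov.bin_width
            hi = min(lo + cov.bin_width, lengths[chrom])
            pos = rng.integers(lo, hi, size=int(counts[b]))
            strands = rng.random(len(pos)) < 0.5
            records.extend(
                (chrom, int(p), "+" if s else "-") for p, s in zip(pos, strands)
            )

    if format in ("BED", "tagAlign"):
        with open(path, "w") as fh:
            for i, (chrom, pos, strand) in enumerate(records):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\tr{i}\t0\t{strand}\n")
    elif format == "bowtie":
        with open(path, "w") as fh:
            for i, (chrom, pos, strand) in enumerate(records):
                fh.write(f"r{i}\t{strand}\t{chrom}\t{pos}\tA\tI\t0\n")
    elif format in ("SAM", "BAM"):
        header = {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [
                {"SN": c, "LN": n} for c, n in cov.genome.entries
            ],
        }
        ref_id = {c: i for i, (c, _) in enumerate(cov.genome.entries)}
        mode = "wb" if format == "BAM" else "w"
        with pysam.AlignmentFile(str(path), mode, header=header) as fh:
            for i, (chrom, pos, strand) in enumerate(records):
                a = pysam.AlignedSegment(fh.header)
                a.query_name = f"r{i}"
                a.reference_id = ref_id[chrom]
                a.reference_start = pos
                a.cigarstring = "1M"
                a.mapping_quality = 30
                a.flag = 16 if strand == "-" else 0
                a.query_sequence = "A"
                a.query_qualities = pysam.qualitystring_to_array("I")
                fh.write(a)
    else:
        raise ValueError(f"unknown read format {format!r}")


def gen_training_table(
    n_per_cell: int = 40,
    effect_grid: tuple[float, ...] = (2.0, 4.0, 8.0),
    n_bins: int = 2000,
    seed: int = 0,
) -> TrainingTable:
    """Synthetic divergence-statistic training table.

    Stands in for a repository-trained table.  Input-Input rows carry
    divergence statistics from null replicate pairs; IP-Input rows from
    planted-enrichment pairs across the effect grid.  Cancer categories draw
    their null pairs with sporadic regional copy-number-like distortions, so
    their Input-Input statistic distribution is heavier tailed than the
    normal-tissue categories'.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cat in CATEGORIES:
        cancer = cat.endswith("_cancer")
        for i in range(n_per_cell):
            # Input-Input: two replicates of one background
            lam = rng.gamma(2.0, 3.0, n_bins)
            a = rng.poisson(lam).astype(float)
            lam2 = lam.copy()
            if cancer and rng.random() < 0.3:
                # sporadic CNV-like regional distortion in one replicate
                frac = rng.uniform(0.01, 0.05)
                bins = rng.choice(n_bins, size=int(frac * n_bins), replace=False)
                lam2[bins] *= rng.uniform(1.5, 3.0)
            b = rng.poisson(lam2).astype(float)
            rows.append((cat, "Input_Input", _divergence_stat(a, b)))
            # IP-Input: planted enrichment
            fold = float(effect_grid[i % len(effect_grid)])
            s = rng.uniform(0.05, 0.2)
            lam = rng.gamma(2.0, 3.0, n_bins)
            inp = rng.poisson(lam).astype(float)
            ip_lam = lam.copy()
            bins = rng.choice(n_bins, size=int(s * n_bins), replace=False)
            ip_lam[bins] *= fold
            ip = rng.poisson(ip_lam).astype(float)
            rows.append((cat, "IP_Input", _divergence_stat(ip, inp)))
    frame = pd.DataFrame(rows, columns=["category", "pair_type", "divergence_stat"])
    return TrainingTable(frame)


def gen_panel(
    out_dir: str | os.PathLike,
    n_samples: int = 20,
    peak_density: float = 0.01,
    genome: GenomeTable | None = None,
    log_odds_mu: float = 1.0,
    log_odds_sigma: float = 0.5,
    seed: int = 0,
) -> tuple[str, str]:
    """Write a synthetic reference panel directory.

    Emits ``union_peaks.bed`` (non-overlapping peaks covering *peak_density*
    of the genome) and ``panel_logodds.tsv`` with per-sample log odds drawn
    from Normal(log_odds_mu, log_odds_sigma).
    """
    rng = np.random.default_rng(seed)
    genome = genome or _default_genome(50_000)
    os.makedirs(out_dir, exist_ok=True)
    peaks_path = os.path.join(out_dir, "union_peaks.bed")
    with open(peaks_path, "w") as fh:
        for chrom, length in genome.entries:
            peak_len = 1000
            n_peaks = max(1, int(peak_density * length / peak_len))
            starts = np.sort(
                rng.choice(length // (2 * peak_len), size=n_peaks, replace=False)
            ) * (2 * peak_len)
            for s in starts:
                fh.write(f"{chrom}\t{s}\t{min(s + peak_len, length)}\n")
    lo = rng.normal(log_odds_mu, log_odds_sigma, n_samples)
    tsv_path = os.path.join(out_dir, "panel_logodds.tsv")
    pd.DataFrame({"sample_id": [f"panel{i}" for i in range(n_samples)], "log_odds": lo}).to_csv(
        tsv_path, sep="\t", index=False
    )
    return peaks_path, tsv_path


def gen_fastq(
    path: str | os.PathLike,
    n_reads: int = 1000,
    length: int = 36,
    bias_window: tuple[int, int] | None = (21, 24),
    seed: int = 0,
) -> None:
    """FASTQ with a planted artifact window (0-based, half-open positions).

    Inside the window: elevated GC content, a high uncallable-base rate, and
    depressed Phred quality — the signature of a localized sequencing
    problem.  With ``bias_window=None`` profiles are flat.
    """
    rng = np.random.default_rng(seed)
    base_probs_flat = np.array([0.25, 0.25, 0.25, 0.25])
    base_probs_gc = np.array([0.06, 0.44, 0.44, 0.06])  # A C G T
    bases = np.array(list("ACGT"))
    with open(path, "w") as fh:
        for i in range(n_reads):
            seq = bases[rng.choice(4, size=length, p=base_probs_flat)]
            qual = np.clip(rng.normal(38, 2, length), 2, 40).astype(int)
            if bias_window is not None:
                w = slice(*bias_window)
                n_in = len(seq[w])
                seq[w] = bases[rng.choice(4, size=n_in, p=base_probs_gc)]
                ns = rng.random(n_in) < 0.10
                seq_w = seq[w]
                seq_w[ns] = "N"
                seq[w] = seq_w
                qual[w] = np.clip(rng.normal(18, 3, n_in), 2, 40).astype(int)
            fh.write(
                f"@read{i}\n{''.join(seq)}\n+\n"
                + "".join(chr(q + 33) for q in qual)
                + "\n"
            )
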
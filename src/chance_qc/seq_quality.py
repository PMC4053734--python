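"""Per-position sequence-content and base-call-quality statistics.

Summarizes raw reads into nucleotide frequency profiles, the frequency of
uncallable (N) bases, and a Phred-score exceedance matrix: E[y][pos] is the
fraction of reads covering *pos* with a quality score of y or more.  A
stretch of positions with unusual nucleotide content, a high N rate, or
depressed quality flags a sequencing problem worth reporting to the
facility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import InputDataError, QualityRecords

MAX_PHRED = 93


@dataclass
class QualitySummary:
    base_freq: np.ndarray  # (5, L): A,C,G,T,N frequency per position
    n_freq: np.ndarray  # (L,): uncallable-base frequency per position
    exceedance: np.ndarray  # (94, L): fraction of reads with Phred >= y


def nucleotide_profile(records: QualityRecords) -> tuple[np.ndarray, np.ndarray]:
    """Per-position A/C/G/T/N frequencies, normalized by reads covering each position."""
    if records.n_reads == 0 or records.read_length == 0:
        raise InputDataError("no reads to profile")
    cov = records.coverage().astype(float)
    if np.any(cov == 0):
        raise InputDataError("position with zero coverage inside read span")
    freq = records.base_counts / cov
    return freq, freq[QualityRecords.BASES.index("N")]


def quality_exceedance(records: QualityRecords) -> np.ndarray:
    """E[y][pos] = fraction of reads at pos with Phred score >= y.

    Computed as the reverse cumulative sum of the per-position score
    histogram; E[0] is 1 everywhere and E is nonincreasing in y.
    """
    if records.n_reads == 0 or records.read_length == 0:
        raise InputDataError("no reads to profile")
    cov = records.qual_hist.sum(axis=0).astype(float)
    if np.any(cov == 0):
        raise InputDataError("position with zero coverage inside read span")
    tail = np.cumsum(records.qual_hist[::-1], axis=0)[::-1]
    return tail / cov


def quality_summary(records: QualityRecords) -> QualitySummary:
    freq, n_freq = nucleotide_profile(records)
    return QualitySummary(freq, n_freq, quality_exceedance(records))
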
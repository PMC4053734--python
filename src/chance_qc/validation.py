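"""Spot validation of candidate loci and reference-panel comparison.

Spot validation answers "are my ChIP-qPCR control regions enriched in the
sequencing data?": per region, the IP tag count is tested against a Poisson
null whose mean is the (depth-scaled) Input tag count in that region, and
the fold change is reported.  The panel comparison scores a sample against a
reference collection by the odds ratio that an IP read versus an Input read
falls inside the union of the panel's peaks; the user's log odds ratio is
placed on a normal fit to the panel's log odds to gauge how much of an
outlier the sample is.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, poisson

from .genome_io import GenomeTable, InputDataError, ReadSet

#: Poisson mean floor — an empty Input region would otherwise give a
#: degenerate Poisson(0) null
LAMBDA_FLOOR = 1.0

OUTLIER_PERCENTILE = 0.05


@dataclass
class SpotResult:
    regions: list[tuple[str, int, int]]
    ip_counts: np.ndarray
    input_counts: np.ndarray
    fold_change: np.ndarray
    p_values: np.ndarray
    skipped: list[tuple[str, int, int]]


@dataclass
class PanelComparison:
    p: float  # fraction of IP reads in union peaks (pseudocounted)
    q: float  # fraction of Input reads in union peaks (pseudocounted)
    odds_ratio: float
    log_odds: float
    mu: float
    sigma: float
    percentile: float
    poor_overlap: bool


def read_bed_regions(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            regions.append((parts[0], int(parts[1]), int(parts[2])))
    return regions


def _merge_intervals(regions):
    """Merge overlapping/adjacent intervals per chromosome; sorted starts/ends."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in regions:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = (
            np.array([s for s, _ in out]),
            np.array([e for _, e in out]),
        )
    return merged


def _count_in_regions(reads: ReadSet, merged) -> int:
    """Reads whose 5' position lies in any [start, end) interval."""
    names = reads.genome.names
    total = 0
    for code in np.unique(reads.chroms):
        chrom = names[code]
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        pos = reads.positions[reads.chroms == code]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        total += int(np.count_nonzero(ok & (pos < ends[np.clip(idx, 0, None)])))
    return total


def spot_check(
    ip: ReadSet,
    input: ReadSet,
    regions: list[tuple[str, int, int]],
    depth_scale: bool = True,
) -> SpotResult:
    """Poisson test of IP tag counts in user-specified candidate regions.

    Per region: k = IP reads with 5' position in [start, end); the null mean
    is the Input count there, scaled by the IP/Input library-size ratio
    (disable with ``depth_scale=False`` for the unscaled convention) and
    floored at 1 read; p-value = P(X >= k) under Poisson; fold change = k /
    lambda.  Regions on undeclared chromosomes are skipped with a warning
    entry.
    """
    if ip.total == 0 or input.total == 0:
        raise InputDataError("both channels need at least one read")
    ratio = ip.total / input.total if depth_scale else 1.0
    kept, skipped = [], []
    for region in regions:
        (kept if region[0] in ip.genome else skipped).append(region)
    ks, n_ins, lams = [], [], []
    for chrom, start, end in kept:
        merged = {chrom: (np.array([start]), np.array([end]))}
        k = _count_in_regions(ip, merged)
        n_in = _count_in_regions(input, merged)
        ks.append(k)
        n_ins.append(n_in)
        lams.append(max(n_in * ratio, LAMBDA_FLOOR))
    ks = np.array(ks, dtype=float)
    lams = np.array(lams, dtype=float)
    # upper tail P(X >= k) = sf(k - 1)
    pvals = poisson.sf(ks - 1, lams) if len(ks) else np.empty(0)
    folds = ks / lams if len(ks) else np.empty(0)
    return SpotResult(
        kept, ks.astype(int), np.array(n_ins, dtype=int), folds, pvals, skipped
    )


def odds_ratio(p: float, q: float) -> float:
    """OR = [p/(1-p)] / [q/(1-q)]."""
    return (p / (1.0 - p)) / (q / (1.0 - q))


def panel_odds_ratio(
    ip: ReadSet, input: ReadSet, union_peaks: list[tuple[str, int, int]]
) -> tuple[float, float, float]:
    """Fractions of IP/Input reads inside the union peak set, and their OR.

    Peaks are merged internally.  A half-read pseudocount on the numerator
    and a full read on the denominator keeps both fractions strictly inside
    (0, 1), so the odds ratio is always finite and positive.
    """
    if not union_peaks:
        raise InputDataError("empty union peak set")
    if ip.total == 0 or input.total == 0:
        raise InputDataError("both channels need at least one read")
    merged = _merge_intervals(union_peaks)
    p = (_count_in_regions(ip, merged) + 0.5) / (ip.total + 1.0)
    q = (_count_in_regions(input, merged) + 0.5) / (input.total + 1.0)
    return p, q, odds_ratio(p, q)


def panel_percentile(
    user_or: float, panel_log_odds: np.ndarray
) -> tuple[float, float, float]:
    """Place the user's log odds ratio on a normal fit to the panel's.

    Returns ``(mu, sigma, percentile)``; a percentile in the extreme left
    tail (< 0.05) indicates poor overlap with the reference collection.
    """
    lo = np.asarray(panel_log_odds, dtype=float)
    if len(lo) < 3:
        raise InputDataError("reference panel needs at least 3 samples")
    mu = float(lo.mean())
    sigma = float(lo.std(ddof=1))
    if sigma == 0:
        raise InputDataError("degenerate reference panel: zero spread in log odds")
    pct = float(norm.cdf((np.log(user_or) - mu) / sigma))
    return mu, sigma, pct


def compare_to_panel(
    ip: ReadSet,
    input: ReadSet,
    union_peaks: list[tuple[str, int, int]],
    panel_log_odds: np.ndarray,
) -> PanelComparison:
    p, q, orat = panel_odds_ratio(ip, input, union_peaks)
    mu, sigma, pct = panel_percentile(orat, panel_log_odds)
    return PanelComparison(
        p=p,
        q=q,
        odds_ratio=orat,
        log_odds=float(np.log(orat)),
        mu=mu,
        sigma=sigma,
        percentile=pct,
        poor_overlap=pct < OUTLIER_PERCENTILE,
    )


def read_panel(panel_dir: str | os.PathLike):
    """Load a reference panel directory: union_peaks.bed + panel_logodds.tsv."""
    peaks = read_bed_regions(os.path.join(panel_dir, "union_peaks.bed"))
    tbl = pd.read_csv(os.path.join(panel_dir, "panel_logodds.tsv"), sep="\t")
    return peaks, tbl["log_odds"].to_numpy()


def make_tss_regions(
    tss: list[tuple[str, int]], window: int = 3000, genome: GenomeTable | None = None
) -> list[tuple[str, int, int]]:
    """Promoter regions: +/- *window* bp around transcription start sites."""
    out = []
    lengths = genome.lengths if genome is not None else None
    for chrom, pos in tss:
        start = max(pos - window, 0)
        end = pos + window
        if lengths is not None and chrom in lengths:
            end = min(end, lengths[chrom])
        out.append((chrom, start, end))
    return out
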
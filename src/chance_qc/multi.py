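"""Multi-sample IP normalization, consensus building, and batch-effect detection.

Depth-normalizes n binned IP samples to their mean library size, forms a
consensus track c_j = sum_i w_i s_ij with nonnegative weights summing to 1
chosen to maximize the quadratic form w'Mw over the sample covariance matrix
M (the leading-eigenvector combiner), then reuses SES to quantify the
percentage of the genome differentially enriched for every ordered sample
pair and for each sample against the consensus.  Significant pairwise
differences between replicate groups flag batch effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import BinnedCoverage, InputDataError
from . import ses as _ses

DIFFERENTIAL_ALPHA = 0.05


@dataclass
class ConsensusResult:
    weights: np.ndarray
    consensus: np.ndarray  # genome-wide concatenated track
    covariance: np.ndarray  # n x n sample covariance of normalized tracks
    vs_consensus: list[_ses.SESResult] = field(default_factory=list)
    pairwise_pct: np.ndarray | None = None  # D[a][b], zero when non-significant
    pairwise_pvalues: np.ndarray | None = None
    labels: list[str] | None = None


def _flatten(samples) -> list[np.ndarray]:
    out = []
    for s in samples:
        if isinstance(s, BinnedCoverage):
            out.append(s.concatenated().astype(np.float64))
        else:
            out.append(np.asarray(s, dtype=np.float64))
    n_bins = {len(v) for v in out}
    if len(n_bins) != 1:
        raise InputDataError("samples must share one genome and bin width")
    return out


def depth_normalize(samples) -> list[np.ndarray]:
    """Scale each track so every library size equals the mean library size."""
    tracks = _flatten(samples)
    if len(tracks) < 2:
        raise InputDataError("need at least 2 samples; consensus undefined for 1")
    totals = np.array([t.sum() for t in tracks])
    if np.any(totals == 0):
        raise InputDataError("a sample has zero reads")
    target = totals.mean()
    return [t * (target / tot) for t, tot in zip(tracks, totals)]


def consensus_weights(M: np.ndarray) -> np.ndarray:
    """Combiner weights: leading eigenvector of the covariance matrix.

    The quadratic form w'Mw under a sum constraint is maximized along the
    principal eigenvector (Rayleigh quotient); the sign is chosen so the
    dominant mass is nonnegative, negative components are clipped to zero,
    and the result rescaled to sum to 1.
    """
    M = np.asarray(M, dtype=np.float64)
    if not np.allclose(M, M.T):
        raise InputDataError("covariance matrix must be symmetric")
    if np.allclose(M, 0):
        raise InputDataError("no covariance structure: all-zero matrix")
    vals, vecs = np.linalg.eigh(M)
    w = vecs[:, -1]
    if w.sum() < 0:
        w = -w
    w = np.clip(w, 0.0, None)
    if w.sum() == 0:
        raise InputDataError("degenerate leading eigenvector")
    return w / w.sum()


def build_consensus(tracks, weights: np.ndarray) -> np.ndarray:
    """Per-bin weighted sum of the normalized tracks."""
    tracks = _flatten(tracks)
    weights = np.asarray(weights, dtype=np.float64)
    if len(weights) != len(tracks):
        raise InputDataError("one weight per track required")
    if not np.isclose(weights.sum(), 1.0):
        raise InputDataError("weights must sum to 1")
    return np.sum([w * t for w, t in zip(weights, tracks)], axis=0)


def _round_counts(track: np.ndarray) -> np.ndarray:
    # SES is defined on counts; nearest integer, ties to even
    return np.rint(track)


def _pct_enriched(ip_track, input_track, n_resamples, rng):
    """SES percentage-of-genome differentially enriched, with its p-value."""
    ip_counts = _round_counts(ip_track)
    input_counts = _round_counts(input_track)
    if ip_counts.sum() == 0 or input_counts.sum() == 0:
        return 0.0, 1.0
    curves = _ses.allocation_curves(ip_counts, input_counts)
    alpha_star, d = _ses.max_separation(curves)
    p = _ses.divergence_test(ip_counts, input_counts, n_resamples=n_resamples, seed=rng)
    pct = 100.0 * (1.0 - alpha_star) if d > 0 else 0.0
    return pct, p


def differential_matrix(
    samples,
    weights: np.ndarray | None = None,
    n_resamples: int = 100,
    seed: int | np.random.Generator = 0,
) -> ConsensusResult:
    """Consensus plus pairwise and sample-vs-consensus differential statistics.

    ``D[a][b]`` is the percentage of the genome differentially enriched with
    sample a as IP and sample b as Input, reported as 0 (p-value retained)
    when that orientation's divergence test is not significant at 0.05.
    The statistic d = max(q - p) is one-sided — it detects enrichment of
    the IP-role sample over the Input-role sample — so a genuine
    differential pair typically shows a large entry in the orientation
    whose IP carries the extra signal and a weaker one in the reverse.
    The diagonal is zero; both orientations of every pair are reported.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    raw = _flatten(samples)
    tracks = depth_normalize(samples)
    n = len(tracks)
    M = np.cov(np.stack(tracks))
    w = consensus_weights(M) if weights is None else np.asarray(weights, float)
    consensus = build_consensus(tracks, w)

    # pairwise SES runs on the raw counts: allocation curves are cumulative
    # fractions, so library-size normalization cannot change d or alpha_star,
    # while rescaling counts would distort the resampling null's depth
    D = np.zeros((n, n))
    P = np.ones((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            D[a, b], P[a, b] = _pct_enriched(raw[a], raw[b], n_resamples, rng)
    D[P >= DIFFERENTIAL_ALPHA] = 0.0

    vs_consensus = []
    cons_counts = _round_counts(consensus)
    for a in range(n):
        ip_counts = _round_counts(raw[a])
        curves = _ses.allocation_curves(ip_counts, cons_counts)
        alpha_star, d = _ses.max_separation(curves)
        try:
            r = _ses.scale_factor(ip_counts, cons_counts, alpha_star)
        except InputDataError:
            r = 1.0
        res = _ses.enrichment_summary(ip_counts, cons_counts, alpha_star, d, r)
        res.p_value = _ses.divergence_test(
            ip_counts, cons_counts, n_resamples=n_resamples, seed=rng
        )
        vs_consensus.append(res)

    return ConsensusResult(
        weights=w,
        consensus=consensus,
        covariance=M,
        vs_consensus=vs_consensus,
        pairwise_pct=D,
        pairwise_pvalues=P,
    )


def batch_effect_report(
    result: ConsensusResult, labels: list[str] | None = None
) -> dict:
    """Flag sample pairs with significant differential enrichment.

    With group labels, also summarizes within-group vs between-group
    significance counts, the signature of a batch effect being significant
    between-group pairs alongside non-significant within-group pairs.
    """
    P = result.pairwise_pvalues
    D = result.pairwise_pct
    n = P.shape[0]
    flagged = [
        (a, b)
        for a in range(n)
        for b in range(a + 1, n)
        if min(P[a, b], P[b, a]) < DIFFERENTIAL_ALPHA and max(D[a, b], D[b, a]) > 0
    ]
    report = {
        "flagged_pairs": flagged,
        "any_batch_effect": bool(flagged),
        "message": (
            "potential batch effect: significant differential enrichment between "
            f"{len(flagged)} sample pair(s)"
            if flagged
            else "no batch effect detected"
        ),
    }
    if labels is not None:
        within = sum(1 for a, b in flagged if labels[a] == labels[b])
        between = len(flagged) - within
        n_within = sum(
            1
            for a in range(n)
            for b in range(a + 1, n)
            if labels[a] == labels[b]
        )
        n_between = n * (n - 1) // 2 - n_within
        report["within_group"] = {"significant": within, "pairs": n_within}
        report["between_group"] = {"significant": between, "pairs": n_between}
    return report


def multi_ip_analysis(
    samples,
    labels: list[str] | None = None,
    n_resamples: int = 100,
    seed: int = 0,
) -> tuple[ConsensusResult, dict]:
    """End-to-end multi-IP pipeline: normalize, combine, test, report."""
    result = differential_matrix(samples, n_resamples=n_resamples, seed=seed)
    result.labels = labels
    report = batch_effect_report(result, labels)
    return result, report
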
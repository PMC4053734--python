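"""IP enrichment strength by signal extraction scaling (SES).

SES sorts 1-kbp genomic bins by IP read density and compares the cumulative
read-allocation curves of the IP and Input channels under that single
ordering: p(alpha) is the fraction of IP reads in the first alpha fraction of
bins, q(alpha) the fraction of Input reads in the same bins.  The point of
maximal separation d = max(q - p) splits the genome into a background region
(where IP tracks Input) and a signal region; it yields the IP/Input scaling
factor, the percentage of the genome enriched for signal, and the percentage
of IP reads attributable to antibody pulldown.  Statistical significance
comes from a Monte-Carlo divergence test; category-specific q-values
(positive FDR) come from a training table of divergence statistics from
IP-Input and Input-Input comparisons.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import BinnedCoverage, InputDataError, UsageError

CATEGORIES = ("histone_cancer", "histone_normal", "tf_cancer", "tf_normal")
CATEGORY_LABELS = {
    "histone_cancer": "HC",
    "histone_normal": "HN",
    "tf_cancer": "TC",
    "tf_normal": "TN",
}
PAIR_TYPES = ("IP_Input", "Input_Input")

# warnings
LOW_INPUT_DEPTH = "LOW_INPUT_DEPTH"
LOW_IP_DEPTH = "LOW_IP_DEPTH"
AMPLIFICATION_BIAS = "AMPLIFICATION_BIAS"

#: reads-on-tiny-fraction rule: warn if >= AMP_READ_FRACTION of reads map to
#: less than AMP_GENOME_FRACTION of the genome
AMP_READ_FRACTION = 0.25
AMP_GENOME_FRACTION = 0.01

FAILED_SAMPLE_Q_THRESHOLD = 0.05


@dataclass
class AllocationCurves:
    """Cumulative read-allocation curves under the IP-density sort.

    ``alpha[k-1] = k/B``; ``p``/``q`` are the cumulative IP/Input read
    fractions over the first k bins, bins sorted by IP count ascending with
    ties broken by genomic order (stable sort).
    """

    alpha: np.ndarray
    p: np.ndarray
    q: np.ndarray
    permutation: np.ndarray  # IP sort order over concatenated bins


@dataclass
class SESResult:
    alpha_star: float
    d: float
    scale_factor: float
    pct_genome_enriched: float
    pct_signal_reads: float
    differential_pct_increase: float
    alpha0: float
    p_value: float | None = None
    q_values: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    failed_sample_alert: bool = False
    curves: AllocationCurves | None = None
    n_ip: int = 0
    n_input: int = 0

    def to_dict(self) -> dict:
        return {
            "alpha_star": self.alpha_star,
            "divergence": self.d,
            "scale_factor": self.scale_factor,
            "pct_genome_enriched": self.pct_genome_enriched,
            "pct_signal_reads": self.pct_signal_reads,
            "differential_pct_increase": self.differential_pct_increase,
            "alpha0": self.alpha0,
            "p_value": self.p_value,
            "q_values": self.q_values,
            "warnings": list(self.warnings),
            "failed_sample_alert": self.failed_sample_alert,
            "n_ip": self.n_ip,
            "n_input": self.n_input,
        }


@dataclass
class TrainingTable:
    """Labelled divergence statistics from IP-Input and Input-Input pairs.

    Rows: (category, pair_type, divergence_stat).  Used to turn an observed
    divergence statistic into a positive-FDR-style q-value per category.
    """

    frame: pd.DataFrame  # columns: category, pair_type, divergence_stat

    def __post_init__(self):
        required = {"category", "pair_type", "divergence_stat"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"training table needs columns {sorted(required)}")
        stats = self.frame["divergence_stat"]
        if ((stats < -1) | (stats > 1)).any():
            raise ValueError("divergence statistics must lie in [-1, 1]")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "TrainingTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def subset(self, category: str) -> pd.DataFrame:
        if category == "ALL":
            return self.frame
        return self.frame[self.frame["category"] == category]


def _as_flat(cov) -> np.ndarray:
    if isinstance(cov, BinnedCoverage):
        return cov.concatenated().astype(np.float64)
    return np.asarray(cov, dtype=np.float64)


def _check_pair(ip_flat, input_flat):
    if len(ip_flat) != len(input_flat):
        raise UsageError("IP and Input must be binned on the same genome/bin width")
    if ip_flat.sum() <= 0:
        raise InputDataError("IP channel has zero reads")
    if input_flat.sum() <= 0:
        raise InputDataError("Input channel has zero reads")


def allocation_curves(ip, input) -> AllocationCurves:
    """Build p(alpha), q(alpha) under the IP-induced bin ordering."""
    ip_flat, input_flat = _as_flat(ip), _as_flat(input)
    _check_pair(ip_flat, input_flat)
    order = np.argsort(ip_flat, kind="stable")
    b = len(ip_flat)
    p = np.cumsum(ip_flat[order]) / ip_flat.sum()
    q = np.cumsum(input_flat[order]) / input_flat.sum()
    alpha = np.arange(1, b + 1) / b
    return AllocationCurves(alpha, p, q, order)


def max_separation(curves: AllocationCurves) -> tuple[float, float]:
    """Maximal vertical separation of the two allocation curves.

    Returns ``(alpha_star, d)`` where ``d = max(q - p)`` and ``alpha_star``
    is the smallest alpha attaining it.
    """
    gap = curves.q - curves.p
    k = int(np.argmax(gap))  # argmax returns the first maximizer
    return float(curves.alpha[k]), float(gap[k])


def scale_factor(ip, input, alpha_star: float) -> float:
    """IP/Input normalization ratio from the background region.

    The background is the first ``alpha_star`` fraction of bins in the IP
    sort; r is the ratio of mean IP to mean Input count there, so that
    r-scaled Input matches the IP background level.
    """
    ip_flat, input_flat = _as_flat(ip), _as_flat(input)
    _check_pair(ip_flat, input_flat)
    order = np.argsort(ip_flat, kind="stable")
    n_bg = int(round(alpha_star * len(ip_flat)))
    if n_bg < 1:
        raise InputDataError("empty background region; check enrichment estimate")
    bg = order[:n_bg]
    mean_input = input_flat[bg].mean()
    if mean_input <= 0:
        raise InputDataError(
            "Input has zero mean coverage in the background region; "
            "check Input sequencing depth"
        )
    return float(ip_flat[bg].mean() / mean_input)


def enrichment_summary(ip, input, alpha_star: float, d: float, r: float) -> SESResult:
    """Assemble the headline SES percentages.

    - pct_genome_enriched = 100*(1 - alpha_star): size of the signal region.
    - pct_signal_reads = 100*max(0, 1 - r*N_input/N_ip): IP reads above the
      r-scaled background level, attributed to antibody pulldown.
    - differential_pct_increase: percentage increase of mean IP density over
      r-scaled Input density on the signal region.

    When d <= 0 the channels are declared not enriched and both pie
    percentages are reported as 0.
    """
    ip_flat, input_flat = _as_flat(ip), _as_flat(input)
    n_ip, n_input = ip_flat.sum(), input_flat.sum()
    alpha0 = float((ip_flat == 0).mean())
    if d <= 0:
        return SESResult(
            alpha_star=alpha_star,
            d=d,
            scale_factor=r,
            pct_genome_enriched=0.0,
            pct_signal_reads=0.0,
            differential_pct_increase=0.0,
            alpha0=alpha0,
            n_ip=int(n_ip),
            n_input=int(n_input),
        )
    pct_genome = 100.0 * (1.0 - alpha_star)
    pct_signal = 100.0 * max(0.0, 1.0 - r * n_input / n_ip)
    order = np.argsort(ip_flat, kind="stable")
    n_bg = int(round(alpha_star * len(ip_flat)))
    sig = order[n_bg:]
    diff_pct = 0.0
    if len(sig) > 0:
        scaled_input_sig = r * input_flat[sig].mean()
        if scaled_input_sig > 0:
            diff_pct = 100.0 * (ip_flat[sig].mean() - scaled_input_sig) / scaled_input_sig
    return SESResult(
        alpha_star=alpha_star,
        d=d,
        scale_factor=r,
        pct_genome_enriched=pct_genome,
        pct_signal_reads=pct_signal,
        differential_pct_increase=diff_pct,
        alpha0=alpha0,
        n_ip=int(n_ip),
        n_input=int(n_input),
    )


def _divergence_stat(ip_flat: np.ndarray, input_flat: np.ndarray) -> float:
    order = np.argsort(ip_flat, kind="stable")
    p = np.cumsum(ip_flat[order]) / ip_flat.sum()
    q = np.cumsum(input_flat[order]) / input_flat.sum()
    return float(np.max(q - p))


def divergence_test(
    ip, input, n_resamples: int = 100, seed: int | np.random.Generator = 0
) -> float:
    """Monte-Carlo significance of the divergence statistic d = max(q - p).

    The null pools the two binned count vectors and re-splits the pooled
    count of every bin between the channels (multivariate hypergeometric,
    preserving both channel totals exactly), recomputing d per resample.
    Returns ``p = (1 + #{d_null >= d_obs}) / (1 + n_resamples)``.
    """
    if n_resamples < 1:
        raise UsageError(f"n_resamples must be >= 1, got {n_resamples}")
    ip_flat = _as_flat(ip)
    input_flat = _as_flat(input)
    _check_pair(ip_flat, input_flat)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    d_obs = _divergence_stat(ip_flat, input_flat)
    pooled = (np.rint(ip_flat) + np.rint(input_flat)).astype(np.int64)
    n_ip = int(np.rint(ip_flat).sum())
    exceed = 0
    for _ in range(n_resamples):
        ip_null = rng.multivariate_hypergeometric(pooled, n_ip, method="marginals")
        input_null = pooled - ip_null
        if _divergence_stat(ip_null.astype(float), input_null.astype(float)) >= d_obs:
            exceed += 1
    return (1 + exceed) / (1 + n_resamples)


def q_value(d: float, table: TrainingTable, category: str = "ALL") -> float:
    """Positive-FDR-style q-value for an observed divergence statistic.

    q = (Input-Input rows with stat >= d) / (all rows with stat >= d) within
    the requested category ("ALL" pools every row).  An empty denominator --
    d exceeds every training comparison -- gives q = 0.
    """
    sub = table.subset(category)
    if len(sub) == 0:
        raise InputDataError(f"training table has no rows for category {category!r}")
    tail = sub[sub["divergence_stat"] >= d]
    if len(tail) == 0:
        return 0.0
    return float((tail["pair_type"] == "Input_Input").sum() / len(tail))


def detect_input_depth(curves: AllocationCurves) -> bool:
    """Warn when the Input allocation curve dips strictly below the IP curve.

    With adequate Input depth q(alpha) >= p(alpha) everywhere, since IP reads
    concentrate in a small targeted subset while Input spreads uniformly;
    a strict crossing q < p signals abundant zero-count Input bins.
    """
    return bool(np.any(curves.q < curves.p))


def detect_ip_depth(
    ip, input, curves: AllocationCurves, alpha_star: float
) -> tuple[bool, float, SESResult | None]:
    """Check whether zero-coverage IP bins drive the separation point.

    Returns ``(warn, alpha0, excised_rerun)``.  ``alpha0`` is the fraction of
    bins with zero IP count.  When the maximal separation occurs within the
    zero-coverage prefix (alpha_star <= alpha0 > 0), the zero-IP bins are
    excised and SES recomputed on the remainder.
    """
    ip_flat, input_flat = _as_flat(ip), _as_flat(input)
    if np.all(ip_flat == 0):
        raise InputDataError("all IP bins have zero coverage")
    alpha0 = float((ip_flat == 0).mean())
    if alpha0 <= 0 or alpha_star > alpha0:
        return False, alpha0, None
    keep = ip_flat > 0
    rerun = None
    if input_flat[keep].sum() > 0:
        sub_curves = allocation_curves(ip_flat[keep], input_flat[keep])
        a_star, d = max_separation(sub_curves)
        r = scale_factor(ip_flat[keep], input_flat[keep], a_star)
        rerun = enrichment_summary(ip_flat[keep], input_flat[keep], a_star, d, r)
        rerun.curves = sub_curves
    return True, alpha0, rerun


def detect_amplification_bias(cov) -> tuple[bool, float]:
    """PCR-amplification rule: >= 25% of reads on < 1% of the genome.

    Returns ``(warn, g)`` where g is the smallest genome fraction, taking
    bins densest-first, holding at least 25% of the reads.
    """
    flat = _as_flat(cov)
    total = flat.sum()
    if total <= 0:
        raise InputDataError("channel has zero reads")
    desc = np.sort(flat)[::-1]
    cum = np.cumsum(desc)
    m = int(np.searchsorted(cum, AMP_READ_FRACTION * total)) + 1
    g = m / len(flat)
    return g < AMP_GENOME_FRACTION, float(g)


def ip_strength(
    ip: BinnedCoverage,
    input: BinnedCoverage,
    training: TrainingTable | None = None,
    n_resamples: int = 100,
    seed: int = 0,
) -> SESResult:
    """Full IP-strength pipeline on a binned IP/Input pair.

    Runs SES, the divergence test, the three bias/depth checks (rerunning
    SES with zero-coverage IP bins excised when they drive the separation
    point), and -- given a training table -- per-category q-values plus the
    failed-sample alert (all q-values above 5%).
    """
    curves = allocation_curves(ip, input)
    alpha_star, d = max_separation(curves)
    warnings = []

    ip_warn, alpha0, rerun = detect_ip_depth(ip, input, curves, alpha_star)
    if ip_warn:
        warnings.append(LOW_IP_DEPTH)
    if ip_warn and rerun is not None:
        result = rerun
        result.alpha0 = alpha0
    else:
        r = scale_factor(ip, input, alpha_star)
        result = enrichment_summary(ip, input, alpha_star, d, r)
        result.curves = curves

    if detect_input_depth(curves):
        warnings.append(LOW_INPUT_DEPTH)
    for cov in (ip, input):
        warn, _ = detect_amplification_bias(cov)
        if warn:
            if AMPLIFICATION_BIAS not in warnings:
                warnings.append(AMPLIFICATION_BIAS)

    result.warnings = warnings
    result.p_value = divergence_test(ip, input, n_resamples=n_resamples, seed=seed)

    if training is not None:
        qv = {cat: q_value(result.d, training, cat) for cat in CATEGORIES}
        qv["ALL"] = q_value(result.d, training, "ALL")
        result.q_values = qv
        result.failed_sample_alert = all(
            v > FAILED_SAMPLE_Q_THRESHOLD for v in qv.values()
        )
    return result
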
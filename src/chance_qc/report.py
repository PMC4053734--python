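"""Human-readable summaries, JSON session logs, and static plots."""

from __future__ import annotations

import datetime
import json
import os

import numpy as np

from . import __version__
from .ses import CATEGORIES, CATEGORY_LABELS, SESResult
from .spectral import SpectrumResult

SIGNIFICANCE_ALPHA = 0.05


def _fmt(x: float) -> str:
    """Fixed 4-significant-digit float formatting for stable, diffable output."""
    return f"{float(x):.4g}"


def render_ipstrength_summary(ses: SESResult) -> str:
    """Text summary of an IP-strength run.

    Mirrors the tool's statistical summary statement: a significance line,
    the two pie percentages (omitted for a weak IP where no enrichment
    estimate is possible), the four per-category FDRs plus the pooled one,
    and any warnings, each on its own line.
    """
    lines = []
    significant = (
        ses.p_value is not None and ses.p_value < SIGNIFICANCE_ALPHA and ses.d > 0
    )
    if significant:
        lines.append(
            f"IP is significantly enriched over Input (divergence d={_fmt(ses.d)}, "
            f"P={_fmt(ses.p_value)})."
        )
        lines.append(
            f"Percentage of genome enriched for signal: {_fmt(ses.pct_genome_enriched)}%"
        )
        lines.append(
            f"Percentage of IP reads attributable to antibody pulldown: "
            f"{_fmt(ses.pct_signal_reads)}%"
        )
        lines.append(f"IP/Input scaling factor: {_fmt(ses.scale_factor)}")
    else:
        pval = "n/a" if ses.p_value is None else _fmt(ses.p_value)
        lines.append(
            f"No significant IP enrichment detected (divergence d={_fmt(ses.d)}, "
            f"P={pval}); enrichment pie estimates are not reported."
        )
    if ses.q_values:
        for cat in CATEGORIES:
            if cat in ses.q_values:
                lines.append(
                    f"FDR ({CATEGORY_LABELS[cat]}): {_fmt(ses.q_values[cat])}"
                )
        if "ALL" in ses.q_values:
            lines.append(f"FDR (pooled): {_fmt(ses.q_values['ALL'])}")
        if ses.failed_sample_alert:
            lines.append(
                "ALERT: possibly failed sample — all q-values are above 5%."
            )
    for w in ses.warnings:
        lines.append(f"WARNING: {w}")
    return "\n".join(lines)


def session_log(command: str, parameters: dict, results: dict, warnings=()) -> dict:
    return {
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "command": command,
        "parameters": parameters,
        "results": results,
        "warnings": list(warnings),
        "version": __version__,
    }


def write_session_log(log: dict, path: str | os.PathLike) -> None:
    class _Encoder(json.JSONEncoder):
        def default(self, obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return super().default(obj)

    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, cls=_Encoder)


def plot_allocation_curves(ses: SESResult, out_path: str, amp_fraction=None) -> None:
    """p/q allocation curves with the separation, zero-coverage and
    amplification annotation lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = ses.curves
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.plot(curves.alpha, curves.p, label="IP p(alpha)", color="tab:blue")
    ax.plot(curves.alpha, curves.q, label="Input q(alpha)", color="tab:red")
    ax.axvline(ses.alpha_star, color="green", label="max separation")
    if ses.alpha0 > 0:
        ax.axvline(ses.alpha0, color="black", label="zero IP coverage")
    if amp_fraction is not None:
        ax.axvline(1.0 - amp_fraction, color="turquoise", label="amplification bias")
    ax.set_xlabel("fraction of genome (bins, IP-sorted)")
    ax.set_ylabel("cumulative fraction of reads")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_spectrum(spec: SpectrumResult, out_path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.plot(spec.scales, spec.energy_pct, "o-", color="tab:blue", label="observed")
    ax.plot(
        spec.scales,
        spec.sim_energy_pct,
        "s-",
        color="tab:red",
        label="Poisson-Gamma simulation",
    )
    ax.set_xscale("log")
    ax.set_xlabel("length scale (bp)")
    ax.set_ylabel("percentage of variance")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
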
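"""Minimal diagnostic renderings (funnel and leave-one-out plots).

Plots are deliberately plain — the data tables written alongside them are
the primary output; these are quick visual checks.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .diagnostics import FunnelResult, LeaveOneOutResult  # noqa: E402


def plot_funnel(result: FunnelResult, path: str | Path, title: str = "") -> Path:
    """Per-SNP Wald estimate vs precision; symmetry about the weighted mean
    argues against directional pleiotropy."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(result.table["wald_ratio"], result.table["precision"],
               s=12, alpha=0.7, edgecolors="none")
    w = result.table["precision"] ** 2
    center = float((result.table["wald_ratio"] * w).sum() / w.sum())
    ax.axvline(center, color="0.3", lw=1, ls="--")
    ax.set_xlabel("per-SNP causal estimate (Wald ratio)")
    ax.set_ylabel("precision (1/SE)")
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_leave_one_out(result: LeaveOneOutResult, path: str | Path,
                       title: str = "") -> Path:
    """One IVW re-estimate (with 95% CI) per omitted SNP, against the
    full-sample estimate."""
    frame = result.to_frame()
    fig, ax = plt.subplots(figsize=(5, max(2.5, 0.16 * len(frame))))
    ypos = range(len(frame))
    ax.errorbar(
        frame["beta"], list(ypos),
        xerr=[frame["beta"] - frame["ci_low"], frame["ci_high"] - frame["beta"]],
        fmt="o", ms=3, lw=0.8, color="0.2",
    )
    ax.axvline(result.full.beta, color="firebrick", lw=1)
    ax.set_yticks(list(ypos))
    ax.set_yticklabels(frame["omitted_snp"], fontsize=6)
    ax.set_xlabel("IVW estimate omitting one SNP")
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
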
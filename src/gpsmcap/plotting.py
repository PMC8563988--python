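"""Optional figure helpers (r20 curves and Hamming tails)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import R20Result, loglog_rescale


def plot_r20(
    results: dict[str, R20Result],
    path: str | Path,
    bound: R20Result | None = None,
) -> None:
    """r20 vs word length for several models, with an optional estimation bound."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, res in results.items():
        ax.plot(res.word_lengths, res.mean_scores, "o-", label=name)
    if bound is not None:
        ax.plot(bound.word_lengths, bound.mean_scores, "k:", label="estimation bound")
    ax.set_xlabel("word length n")
    ax.set_ylabel(r"$r_{20}$")
    ax.set_ylim(-0.05, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_hamming_tails(hists: dict[str, np.ndarray], path: str | Path) -> None:
    """Mode-centered, max-normalized Hamming tails on log-log axes."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, hist in hists.items():
        t = loglog_rescale(np.asarray(hist))
        (rd, rf), (ld, lf) = t.right, t.left
        line = None
        if rd.size:
            (line,) = ax.plot(rd, rf, ".-", label=name)
        if ld.size:
            ax.plot(ld, lf, ".-", color=None if line is None else line.get_color())
    ax.plot([1.0], [1.0], "k+")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$d / d_{Mo}$")
    ax.set_ylabel(r"$f / f_{max}$")
    handles, labels = ax.get_legend_handles_labels()
    if handles:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
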
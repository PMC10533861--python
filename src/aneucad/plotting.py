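"""FROC-curve and FP-histogram figures (matplotlib, file output)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluation import FROCCurve

__all__ = ["plot_froc", "plot_fp_histogram"]


def plot_froc(curves: dict[str, FROCCurve], path) -> None:
    """Overlay one FROC curve per label (e.g. before/after tuning)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.plot(curve.fps_per_case, curve.sensitivity_pct, marker="o", label=label)
    ax.set_xlabel("false positives per case")
    ax.set_ylabel("sensitivity (%)")
    ax.set_ylim(0, 102)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_fp_histogram(histograms: dict[str, dict[str, int]], path) -> None:
    """Grouped bars of case counts per FP-count bin, one group per label."""
    fig, ax = plt.subplots(figsize=(5, 4))
    labels = list(histograms)
    bins = list(next(iter(histograms.values())))
    width = 0.8 / max(1, len(labels))
    for i, label in enumerate(labels):
        counts = [histograms[label][b] for b in bins]
        ax.bar([x + i * width for x in range(len(bins))], counts, width, label=label)
    ax.set_xticks([x + 0.4 - width / 2 for x in range(len(bins))])
    ax.set_xticklabels(bins)
    ax.set_xlabel("false positives per case")
    ax.set_ylabel("number of cases")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
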
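"""Diagnostic figures for the coin-toss comparison and the center scan.

Matplotlib is imported lazily so headless batch use of the library
never pays for it.  All functions accept and return Axes/Figure objects
in the usual matplotlib style.
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_comparison(result, ax_bar=None, ax_hist=None, color=None, label=None):
    """Bar chart of the +/-1 sign sequence plus the patch-size histogram."""
    plt = _plt()
    if ax_bar is None or ax_hist is None:
        _, (ax_bar, ax_hist) = plt.subplots(1, 2, figsize=(8, 3))
    ax_bar.bar(np.arange(result.n), result.signs, width=1.0, color=color, label=label)
    ax_bar.set_xlabel("point index")
    ax_bar.set_ylabel("sign")
    ax_bar.set_yticks([-1, 1])
    if result.patch_hist:
        lengths = sorted(result.patch_hist)
        ax_hist.bar(lengths, [result.patch_hist[l] for l in lengths],
                    width=0.8, color=color, alpha=0.7, label=label)
    ax_hist.set_xlabel("patch size")
    ax_hist.set_ylabel("count")
    ax_hist.set_title(f"longest {result.longest}, p = {result.p_value:.3g}", fontsize=9)
    if label:
        ax_hist.legend(fontsize=8)
    return ax_bar, ax_hist


def plot_center_scan(verdict, cuts=None, fig=None):
    """Three-panel center-scan figure: the opposing cuts (optional), the
    sign bar charts per offset and the patch-size histograms, with the
    p-value of each offset annotated."""
    plt = _plt()
    if fig is None:
        fig = plt.figure(figsize=(9, 6))
    n_off = len(verdict.results)
    colors = {0: "tab:blue", -1: "tab:green", 1: "tab:orange"}
    if cuts is not None:
        ax0 = fig.add_subplot(3, 1, 1)
        for cut in cuts:
            use = ~cut.empty if cut.empty is not None else slice(None)
            ax0.semilogy(cut.q[use], np.maximum(cut.intensity[use], 1e-12), label=cut.label)
        ax0.set_xlabel("q (1/A)")
        ax0.set_ylabel("I")
        ax0.legend(fontsize=8)
        ax0.set_title(f"axis {verdict.axis}: {verdict.recommendation}")
    for i, (off, res) in enumerate(sorted(verdict.results.items())):
        axb = fig.add_subplot(3, n_off, n_off + i + 1)
        axh = fig.add_subplot(3, n_off, 2 * n_off + i + 1)
        plot_comparison(res, axb, axh, color=colors.get(off))
        axb.set_title(f"offset {off:+d}, p = {res.p_value:.3g}", fontsize=9)
    fig.tight_layout()
    return fig


def plot_scaling_trace(result, ax=None):
    """Probed scaling factors with accepted / rejected markers."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    for idx, (f, c1, c2) in enumerate(result.trace):
        ok = not (c1 or c2)
        ax.plot(idx, f, "o" if ok else "x", color="tab:green" if ok else "tab:red", ms=4)
    ax.axhline(result.factor, ls="--", color="k", lw=0.8)
    ax.set_xlabel("probe")
    ax.set_ylabel("scaling factor")
    ax.set_title(f"final {result.factor:.4f} ({result.terminated_by})", fontsize=9)
    return ax
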
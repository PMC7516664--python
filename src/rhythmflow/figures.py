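"""Figure rendering: recurrence plots and null-distribution panels."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .inference import NullDistribution, PermutationTestResult
from .symbolic import SymbolSeries, pattern_labels, recurrence_plot

__all__ = ["plot_recurrence", "plot_null_panels"]


def plot_recurrence(
    sym: SymbolSeries, ax: Optional[plt.Axes] = None, max_len: int = 400
):
    """Render the symbol-resolved recurrence plot, one color per symbol.

    Only the leading ``max_len`` symbols are drawn so large plots stay
    legible; non-recurrent cells are white.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    codes = sym.codes[:max_len]
    mat = recurrence_plot(SymbolSeries(codes=codes, m=sym.m))
    k = sym.alphabet_size
    cmap = ListedColormap(plt.get_cmap("tab10").colors[:k])
    masked = np.ma.masked_less(mat, 0)
    ax.imshow(masked, cmap=cmap, vmin=0, vmax=k - 1, origin="lower",
              interpolation="nearest")
    ax.set_xlabel("time $s$")
    ax.set_ylabel("time $t$")
    labels = pattern_labels(sym.m)
    handles = [
        plt.Line2D([], [], marker="s", ls="", color=cmap(i), label=labels[i])
        for i in range(k)
    ]
    ax.legend(handles=handles, fontsize=6, loc="upper left", ncol=2,
              title="pattern", title_fontsize=6)
    return ax


def plot_null_panels(
    results: Sequence[tuple[NullDistribution, PermutationTestResult]],
    path: Optional[str] = None,
):
    """Histogram of each null distribution with the observed mean marked.

    One panel per metric and session: grey resampled means, red vertical
    line at the observed mean, dashed lines at the percentile band used by
    the significance rule.
    """
    n = len(results)
    if n == 0:
        raise ValueError("no null distributions to plot")
    ncols = min(4, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows),
                             squeeze=False)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    for ax, (null, test) in zip(axes.ravel(), results):
        ax.hist(null.samples, bins=40, color="0.7")
        ax.axvline(null.observed, color="red", lw=1.5)
        if test.sidedness == "two":
            ax.axvline(test.null_lo, color="0.3", ls="--", lw=0.8)
            ax.axvline(test.null_hi, color="0.3", ls="--", lw=0.8)
        else:
            ax.axvline(np.percentile(null.samples, 95), color="0.3", ls="--", lw=0.8)
        sess = f" s{null.session}" if null.session is not None else ""
        ax.set_title(f"{null.metric}{sess}  p={test.p_value:.3g}", fontsize=8)
        ax.tick_params(labelsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
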
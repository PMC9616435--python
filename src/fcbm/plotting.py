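"""Degree-distribution comparison panels (requires matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_degree_comparison(empirical_pmf, est_block, est_global, path):
    """Overlay an averaged empirical degree histogram with the
    block-resolved and single-scale closed-form estimates, on linear and
    log-log axes side by side."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = np.arange(len(empirical_pmf))
    grid = np.arange(max(len(empirical_pmf), 2))
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, scale in zip(axes, ("linear", "log")):
        ax.plot(k, empirical_pmf, drawstyle="steps-mid", color="0.4",
                label="sampled (ensemble mean)")
        ax.plot(grid, est_block(grid), "-", color="C0",
                label="block-resolved estimate")
        ax.plot(grid, est_global(grid), "--", color="C3",
                label="single-scale estimate")
        if scale == "log":
            ax.set_xscale("log")
            ax.set_yscale("log")
            positive = empirical_pmf[empirical_pmf > 0]
            if positive.size:
                ax.set_ylim(bottom=positive.min() / 10)
        ax.set_xlabel("degree k")
        ax.set_ylabel("p(k)")
    axes[0].legend(fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
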
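"""Manhattan plots for per-SNP score tracks. Plots are artifacts, not
contracts: no test asserts pixels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def manhattan(
    table: pd.DataFrame,
    value_cols: list[str],
    path,
    hlines: dict[str, float] | None = None,
) -> None:
    """One panel per score column, x = cumulative genome position."""
    chroms = table["chrom"].astype(str)
    offsets: dict[str, float] = {}
    cum = 0.0
    for chrom in pd.unique(chroms):
        offsets[chrom] = cum
        cum += table.loc[chroms == chrom, "pos_bp"].max() * 1.05
    x = table["pos_bp"].to_numpy() + np.array([offsets[c] for c in chroms])
    fig, axes = plt.subplots(len(value_cols), 1, figsize=(9, 2.6 * len(value_cols)), squeeze=False)
    palette = ("#33557799", "#77995599")
    for ax, col in zip(axes[:, 0], value_cols):
        for i, chrom in enumerate(pd.unique(chroms)):
            m = (chroms == chrom).to_numpy()
            ax.scatter(x[m], table[col].to_numpy()[m], s=6, color=palette[i % 2])
        if hlines:
            for name, y in hlines.items():
                ax.axhline(y, ls="--", lw=0.8, color="grey")
                ax.annotate(name, (x.max(), y), fontsize=7, ha="right", va="bottom")
        ax.set_ylabel(col)
    axes[-1, 0].set_xlabel("genome position (bp, chromosomes concatenated)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
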
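"""Optional Manhattan-style scatter of per-window -log10 p-values.

Figures are by-products of windows.tsv, never pipeline inputs; matplotlib
is imported lazily so the core package has no hard plotting dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_SCORE_COLORS = {-1: "#3366cc", 0: "#999999", 1: "#cc3333"}


def manhattan(windows: pd.DataFrame, condition: str, path: str | Path,
              gap: int = 100_000) -> None:
    """Plot -log10 p per window along a concatenated genome axis, colored
    by ternary score (hypo blue, neutral grey, hyper red)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = windows[windows[f"testable_{condition}"]].copy()
    offset = 0
    xs, boundaries = [], []
    for chrom, group in df.groupby("chrom", sort=True):
        xs.append(group["start"] + offset)
        offset += group["end"].max() + gap
        boundaries.append(offset)
    df["x"] = pd.concat(xs)

    fig, ax = plt.subplots(figsize=(10, 3))
    y = df[f"neglog10p_{condition}"].replace(np.inf, df[f"neglog10p_{condition}"]
                                             .replace(np.inf, np.nan).max())
    colors = df[f"score_{condition}"].map(_SCORE_COLORS)
    ax.scatter(df["x"], y, c=colors, s=6, linewidths=0)
    for b in boundaries[:-1]:
        ax.axvline(b, color="#dddddd", lw=0.5)
    ax.set_xlabel("genome position")
    ax.set_ylabel(r"$-\log_{10} P$")
    ax.set_title(condition)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
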
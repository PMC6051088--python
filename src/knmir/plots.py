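"""Optional figures: Kaplan-Meier curves and enrichment bar plots."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .survival import km_estimate  # noqa: E402


def km_plot(time, event, group, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, color in (("low", "tab:red"), ("high", "tab:blue")):
        sel = np.asarray(group) == label
        if not sel.any():
            continue
        km = km_estimate(np.asarray(time)[sel], np.asarray(event)[sel])
        ax.step(km["time"], km["survival"], where="post", color=color, label=label)
    ax.set_xlabel("days")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend(title="expression tertile")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def enrichment_barplot(results: pd.DataFrame, path: str | Path,
                       alpha: float = 0.05, top: int = 15) -> None:
    df = results.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(df) + 1.5))
    bars = ax.barh(df["pathway"], -np.log10(df["bh_p"].clip(lower=1e-300)))
    cmap = plt.get_cmap("viridis")
    vmax = max(df["n_overlap"].max(), 1)
    for b, n in zip(bars, df["n_overlap"]):
        b.set_color(cmap(n / vmax))
        ax.text(b.get_width(), b.get_y() + b.get_height() / 2, f" {n}",
                va="center", fontsize=8)
    ax.axvline(-np.log10(alpha), color="orange", linestyle="--")
    ax.set_xlabel("-log10(BH-p)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
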
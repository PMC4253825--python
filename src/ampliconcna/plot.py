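"""Basic per-sample copy-number profile plot."""

from __future__ import annotations

import numpy as np

STATUS_COLORS = {"neutral": "0.6", "gain": "tab:orange", "loss": "tab:purple"}


def plot_profile(result, panel, path=None, ax=None):
    """Scatter of centered log ratios colored by segment status, with
    segment means overlaid; amplicon index on the x-axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.2))
    lr = result.calibrated.log_ratio
    for _, seg in result.segments.iterrows():
        ids = np.arange(int(seg["first"]), int(seg["last"]) + 1)
        ids = ids[np.isfinite(lr[ids])]
        c = STATUS_COLORS.get(seg["status"], "0.6")
        ax.plot(ids, lr[ids], ".", color=c, ms=3)
        ax.hlines(seg["log_ratio"], seg["first"], seg["last"], color="k", lw=1.5)
    ax.axhline(0, color="0.8", lw=0.8, zorder=0)
    ax.set_xlabel("amplicon index")
    ax.set_ylabel("log ratio")
    ax.set_title(result.sample)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
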
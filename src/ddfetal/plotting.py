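"""One-dimensional droplet amplitude plots (per-channel clouds + cutoff)."""

from __future__ import annotations

import numpy as np

from .classify import ChannelCutoffs
from .droplets import DropletTable

__all__ = ["plot_droplets_1d"]

_CHANNEL_STYLE = {
    "FAM": ("tab:blue", "FAM (ch1)"),
    "HEX": ("tab:green", "HEX (ch2)"),
}


def plot_droplets_1d(
    table: DropletTable,
    cutoffs: ChannelCutoffs | None = None,
    ax=None,
):
    """Scatter droplet amplitudes against droplet index, one panel per
    channel, with the cutoff line when provided.  Returns the axes array."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(10, 3.2), sharex=True)
    axes = np.atleast_1d(ax)
    idx = np.arange(table.n_droplets)
    for panel, channel in zip(axes, ("FAM", "HEX")):
        color, label = _CHANNEL_STYLE[channel]
        amp = table.amplitudes(channel)
        panel.scatter(idx, amp, s=2, alpha=0.4, color=color, rasterized=True)
        if cutoffs is not None:
            cut = cutoffs.ch1_cutoff if channel == "FAM" else cutoffs.ch2_cutoff
            method = cutoffs.ch1_method if channel == "FAM" else cutoffs.ch2_method
            panel.axhline(cut, color="purple", lw=1.2, label=f"cutoff ({method})")
            panel.legend(loc="center right", fontsize=8)
        panel.set_title(f"{table.well_id} — {label}", fontsize=9)
        panel.set_xlabel("droplet")
        panel.set_ylabel("amplitude (a.u.)")
    return axes
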
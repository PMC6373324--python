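"""Optional plotting helper (matplotlib, Agg backend)."""

from __future__ import annotations

import numpy as np


def plot_cac_overlay(series, cac, path, boundaries=None, title=None):
    """Standard two-panel overlay: the raw series above its corrected curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(series, dtype=np.float64)
    fig, (ax0, ax1) = plt.subplots(2, 1, sharex=True, figsize=(10, 4))
    ax0.plot(x, lw=0.6)
    ax0.set_ylabel("series")
    ax1.plot(np.asarray(cac.values), color="tab:red", lw=0.8)
    ax1.set_ylim(-0.05, 1.05)
    ax1.set_ylabel("CAC")
    ax1.set_xlabel("sample")
    if boundaries is not None:
        for b in np.asarray(boundaries, dtype=int):
            ax0.axvline(b, color="k", ls="--", lw=0.8, alpha=0.6)
            ax1.axvline(b, color="k", ls="--", lw=0.8, alpha=0.6)
    if title:
        ax0.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
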
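"""Small plotting helpers for maps and quantification curves."""

from __future__ import annotations

import numpy as np

from .transform import SFFMap, VariationMap


def plot_variation_map(vmap, ax=None, levels: int = 12, cmap: str = "RdBu_r"):
    """Flooded contour plot of a variation (or SFF) map; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if isinstance(vmap, VariationMap):
        values = vmap.values
        title = f"V: frame {vmap.current_index} - frame {vmap.baseline_index}"
    elif isinstance(vmap, SFFMap):
        values = vmap.filtered
        title = f"SFF map F (frame {vmap.frame_index})"
    else:
        values = np.asarray(vmap, dtype=float)
        title = "map"
    vmax = float(np.abs(values).max()) or 1.0
    cs = ax.contourf(values[::-1], levels=levels, cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.figure.colorbar(cs, ax=ax)
    ax.set_title(title)
    ax.set_aspect("equal")
    return ax


def plot_increment_curves(quantification, ax=None):
    """Percent-increment curves (spectral vs conventional) over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    q = quantification
    ax.plot(q["time_s"], q["percent_increment"], label="SFF", lw=2)
    ax.plot(q["time_s"], q["conventional_percent"], label="conventional", lw=2, ls="--")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("contrast increment (%)")
    ax.legend()
    return ax
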
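"""Optional plots: a desirability function drawn over its data histogram.

Requires matplotlib (the ``plot`` extra); imported lazily so the core
package works without it.
"""

from __future__ import annotations

import numpy as np

from . import functions as fn

__all__ = ["plot_criterion"]


def plot_criterion(values, spec, ax=None, bins=50, n_grid=400):
    """Histogram of ``values`` with the desirability function overlaid.

    The histogram uses the left axis (density); the 0-1 desirability curve
    uses a twin right axis, the usual way a mapping is sanity-checked
    against the distribution it will score.
    """
    import matplotlib.pyplot as plt

    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if ax is None:
        _, ax = plt.subplots()
    ax.hist(values, bins=bins, color="0.8", density=True)
    ax2 = ax.twinx()
    lo, hi = values.min(), values.max()
    pad = 0.05 * (hi - lo if hi > lo else 1.0)
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    ax2.plot(grid, fn.desirability(grid, spec), color="black", lw=2)
    ax2.set_ylim(-0.02, 1.02)
    ax2.set_ylabel("desirability")
    return ax
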
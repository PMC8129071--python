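"""Diagnostic plots: gate summaries and convergence traces.

Matplotlib is an optional dependency; import errors surface only when a plot
is actually requested.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .gating import GateResult
from .io import ConvergenceTrace, EventTable


def plot_gate(events: EventTable, result: GateResult, path: str | Path) -> None:
    """Scatter density with the gate polygon and selected maximum overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = events.scatter()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hexbin(xy[:, 0], xy[:, 1], gridsize=80, bins="log", cmap="viridis")
    poly = np.vstack([result.polygon.vertices, result.polygon.vertices[:1]])
    ax.plot(poly[:, 0], poly[:, 1], "k-", lw=1.5)
    ax.plot(*result.target_maximum, "r+", ms=12, mew=2)
    fsc, ssc = events.scatter_channels or ("FSC", "SSC")
    ax.set_xlabel(fsc)
    ax.set_ylabel(ssc)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_convergence(trace: ConvergenceTrace, path: str | Path) -> None:
    """Per-iteration sd of errors, max |error| and the oscillation moving
    average, with the scale-switch / convergence / oscillation thresholds."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = trace.to_frame()
    fig, ax = plt.subplots(figsize=(5, 4))
    markers = frame.scale.map({"linear": "^", "biexp": "o"})
    for marker in ("^", "o"):
        sel = markers == marker
        if not sel.any():
            continue
        ax.semilogy(frame.iteration[sel], frame.sd_error[sel], marker,
                    color="sienna", label=f"sd(E) [{ 'linear' if marker=='^' else 'biexp'}]")
        ax.semilogy(frame.iteration[sel], frame.max_abs_error[sel], marker,
                    color="orange", mfc="none", label="max |E|")
    ax.semilogy(frame.iteration, frame.moving_average.clip(1e-12), "-",
                color="orchid", label="moving average")
    for threshold, style in ((1e-2, ":"), (1e-4, "--"), (1e-6, "-.")):
        ax.axhline(threshold, color="gray", ls=style, lw=0.8)
    ax.set_xlabel("iteration")
    ax.set_ylabel("compensation error")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
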
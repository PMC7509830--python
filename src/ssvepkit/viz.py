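"""Minimal plotting helpers: scalp topographies and tuning curves."""

from __future__ import annotations

import numpy as np

from .dynamics import TuningResult
from .montage import Montage


def plot_topography(montage: Montage, values: np.ndarray, ax=None,
                    annotate: list[int] | None = None, cmap: str = "RdBu_r"):
    """Scatter a per-sensor map on the azimuthal-equidistant projection."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    xy = montage.project_2d()
    vmax = np.abs(values).max() or 1.0
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=values, s=60, cmap=cmap,
                    vmin=-vmax, vmax=vmax, edgecolors="k", linewidths=0.3)
    for sid in annotate or []:
        ax.annotate(str(sid), xy[sid - 1], fontsize=7, ha="center", va="center")
    ax.set_aspect("equal")
    ax.axis("off")
    ax.figure.colorbar(sc, ax=ax, shrink=0.7)
    return ax


def plot_tuning(tunings: list[TuningResult], ax=None, what: str = "amplitude"):
    """Amplitude or phase tuning curves for a set of components."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    for t in tunings:
        y = getattr(t, "amplitude" if what == "amplitude" else "phase_deg")
        ax.plot(t.logmar_levels, y, marker="o", label=f"RC{t.component}")
        if what == "amplitude":
            ax.fill_between(t.logmar_levels, 0, t.noise_floor, alpha=0.2,
                            color="grey")
    ax.set_xlabel("logMAR")
    ax.set_ylabel("amplitude (µV)" if what == "amplitude" else "phase (deg)")
    ax.legend()
    return ax
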
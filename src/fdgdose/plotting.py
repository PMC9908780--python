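"""Matplotlib views of TACs and bladder trajectories."""

from __future__ import annotations

import numpy as np

from .bladder import BladderTrajectory
from .system import TimeActivitySet


def plot_tacs(tacs: TimeActivitySet, compartments=None, ax=None, pct_ia: bool = True):
    """Time-activity curves; y-axis in %IA by default."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    scale = 100.0 if pct_ia else 1.0
    for comp in compartments or tacs.compartments:
        ax.plot(tacs.times, scale * tacs.activity(comp), label=comp)
    ax.set_xlabel("time p.i. [h]")
    ax.set_ylabel("activity [%IA]" if pct_ia else "fraction of administered")
    kind = "decay-corrected" if tacs.decay_corrected else "physical"
    ax.set_title(f"{kind} time-activity curves")
    ax.legend(fontsize="small")
    return ax


def plot_bladder(trajectory: BladderTrajectory, ax=None):
    """Bladder content activity (%IA, physical) with void markers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    tt = np.linspace(0.0, trajectory.config.max_time_h, 2000)
    ax.plot(tt, 100.0 * trajectory.activity(tt), color="C3")
    for ev in trajectory.void_events:
        ax.axvline(ev.time_h, color="0.7", lw=0.6, zorder=0)
    ax.set_xlabel("time p.i. [h]")
    ax.set_ylabel("bladder content [%IA]")
    ax2 = ax.twinx()
    ax2.plot(tt, trajectory.volume_ml(tt), color="C0", alpha=0.5)
    ax2.set_ylabel("urine volume [ml]")
    return ax
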
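"""Static figures: cross-section snapshots and PDMT time courses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless; callers may switch backends beforehand

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Circle

from .state import BondSet, ParticleState

__all__ = ["plot_snapshot", "plot_pdmt_series"]


def plot_snapshot(state: ParticleState, bonds: BondSet | None = None,
                  ax: plt.Axes | None = None) -> plt.Axes:
    """Scatter view of one cross-section: microtubules black, free
    neurofilaments grey, engaged neurofilaments purple, organelles cyan."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    engaged = (bonds.nf_bond >= 0 if bonds is not None
               else np.zeros(state.n_nf, dtype=bool))
    ax.scatter(*state.nf_pos[~engaged].T, s=6, c="0.6", label="NF")
    if engaged.any():
        ax.scatter(*state.nf_pos[engaged].T, s=6, c="purple",
                   label="NF (engaged)")
    ax.scatter(*state.mt_pos.T, s=30, c="k", label="MT")
    for o in state.organelles:
        ax.add_patch(Circle(o.center, max(o.radius, 1.0), fill=False,
                            color="c", lw=1.5))
    if not state.domain.periodic:
        ax.add_patch(Circle((0, 0), state.domain.radius, fill=False,
                            color="k", lw=1.0))
        lim = state.domain.radius * 1.05
        ax.set_xlim(-lim, lim)
        ax.set_ylim(-lim, lim)
    else:
        ax.set_xlim(0, state.domain.side)
        ax.set_ylim(0, state.domain.side)
    ax.set_aspect("equal")
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    ax.legend(loc="upper right", fontsize=7)
    return ax


def plot_pdmt_series(records, labels=None, R0: float | None = None,
                     ax: plt.Axes | None = None) -> plt.Axes:
    """Mean pairwise MT distance over time for one or more trajectories."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    if not isinstance(records, (list, tuple)):
        records = [records]
    for k, rec in enumerate(records):
        t = np.asarray(rec.series["t"], dtype=float) / 3600.0
        m = np.asarray(rec.series["pdmt_mean"], dtype=float)
        if R0:
            m = m / R0
        ax.plot(t, m, lw=1,
                label=None if labels is None else labels[k])
    ax.set_xlabel("time (h)")
    ax.set_ylabel("mean PDMT" + (" (R$_0$)" if R0 else " (nm)"))
    if labels is not None:
        ax.legend(fontsize=8)
    return ax
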
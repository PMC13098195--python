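"""Simple diagnostic plots: activity-versus-time and differential-activity scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .activity import DimaRecord, condition_profiles
from .compendium import SampleTable

__all__ = ["plot_activity_profile", "plot_dima"]


def plot_activity_profile(
    a: pd.DataFrame,
    meta: SampleTable,
    component_id: str,
    conditions: list[str] | None = None,
    ax=None,
):
    """Replicate-averaged activity of one component over the time course."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    md = meta.data
    if conditions is None:
        conditions = sorted(
            md.loc[md["time_min"].notna() & ~md["is_reference"], "condition"].unique()
        )
    for cond in conditions:
        prof = condition_profiles(a, meta, condition=cond)[component_id]
        ax.plot(prof.index, prof.to_numpy(), marker="o", label=cond)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("activity (log-TPM units)")
    ax.set_title(component_id)
    ax.legend(fontsize=8)
    return ax


def plot_dima(records: list[DimaRecord], ax=None):
    """Scatter of condition-mean activities; significant components highlighted."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    xs = np.array([r.mean_b for r in records])
    ys = np.array([r.mean_a for r in records])
    sig = np.array([r.significant for r in records])
    ax.scatter(xs[~sig], ys[~sig], s=12, c="lightgrey", label="n.s.")
    if sig.any():
        ax.scatter(xs[sig], ys[sig], s=18, c="crimson", label="significant")
        for r in records:
            if r.significant:
                ax.annotate(r.component_id, (r.mean_b, r.mean_a), fontsize=7)
    lim = max(1.0, float(np.abs(np.concatenate([xs, ys])).max()) * 1.1)
    ax.plot([-lim, lim], [-lim, lim], color="grey", lw=0.5)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("mean activity, condition B")
    ax.set_ylabel("mean activity, condition A")
    ax.legend(fontsize=8)
    return ax
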
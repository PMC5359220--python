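"""Optional matplotlib views of sweep and block-level results."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_sweep", "plot_block_rt"]


def plot_sweep(table: pd.DataFrame, ax=None):
    """Errors vs RT similarity effect across the share sweep, one trace per
    feedback regime (the strategy-space view)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for mode, sub in table.groupby("mode"):
        sub = sub.sort_values("target_share")
        ax.plot(sub["mean_errors"], sub["rt_effect_ms"], "o-", label=mode)
    ax.set_xlabel("mean classification errors (of 96)")
    ax.set_ylabel("RT similarity effect (ms)")
    ax.legend()
    return ax


def plot_block_rt(per_block_rt: pd.DataFrame, ax=None):
    """Mean correct RT to compliant items per block, by similarity."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for sim in per_block_rt.columns:
        ax.plot(per_block_rt.index, per_block_rt[sim], "o-", label=f"{sim} similarity")
    ax.set_xlabel("block")
    ax.set_ylabel("mean correct RT (ms)")
    ax.set_xticks(list(per_block_rt.index))
    ax.legend()
    return ax
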
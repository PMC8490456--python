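"""Figure helpers for run reports (learning curve, ECRS-alpha scatter)."""

from __future__ import annotations

import pandas as pd


def plot_mraa_curve(curve: pd.DataFrame, ax=None):
    """Group MRAA learning curve with SEM error bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(curve["session"], curve["mraa_mean"],
                yerr=curve["mraa_sem"], fmt="o-", capsize=3)
    ax.set_xlabel("session")
    ax.set_ylabel("MRAA")
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    return ax


def plot_ecrs_scatter(scatter: pd.DataFrame, index: str = "L2", ax=None):
    """ECRS alpha amplitude vs one learning index, one dot per subject."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(scatter["ecrs_alpha_uv"], scatter[index], s=18)
    ax.set_xlabel("ECRS alpha amplitude (uV)")
    ax.set_ylabel(index)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    return ax
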
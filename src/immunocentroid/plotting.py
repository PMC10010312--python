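"""Optional matplotlib rendering of the tidy result tables.

All analysis outputs are plain tables; these helpers draw the standard
views (signature boxplots by response, the Teff/Myeloid quadrant scatter,
Kaplan-Meier steps). matplotlib is imported lazily so the analysis stack
works without it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .outcomes import SurvivalCurve
from .signatures import SignatureScores


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def signature_boxplot(scores: SignatureScores, signature: str,
                      labels, ax=None, out_png: str | None = None):
    """Boxplot of one signature split by a binary responder label."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 4))
    values = scores.row(signature)
    labels = np.asarray(labels, dtype=bool)
    ax.boxplot([values[labels], values[~labels]],
               tick_labels=["responder", "non-responder"])
    ax.set_ylabel("signature score (log2, centered)")
    ax.set_title(signature)
    if out_png:
        ax.figure.savefig(out_png, dpi=150, bbox_inches="tight")
    return ax


def teff_myeloid_plot(scatter_table: pd.DataFrame, ax=None,
                      out_png: str | None = None):
    """Scatter of Teff vs Myeloid scores with median thresholds."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    x = scatter_table["myeloid_score"]
    y = scatter_table["teff_score"]
    ax.scatter(x, y, c="tab:blue", s=20)
    ax.axvline(np.median(x), ls="--", c="grey", lw=0.8)
    ax.axhline(np.median(y), ls="--", c="grey", lw=0.8)
    ax.set_xlabel("Myeloid inflammation score")
    ax.set_ylabel("T-effector score")
    if out_png:
        ax.figure.savefig(out_png, dpi=150, bbox_inches="tight")
    return ax


def km_plot(curves: dict[str, SurvivalCurve], ax=None,
            out_png: str | None = None):
    """Step plot of one or more Kaplan-Meier curves."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for name, curve in curves.items():
        ax.step(curve.event_times, curve.survival_prob, where="post", label=name)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    if out_png:
        ax.figure.savefig(out_png, dpi=150, bbox_inches="tight")
    return ax
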
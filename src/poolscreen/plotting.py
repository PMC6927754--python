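"""Optional RSA-vs-quartile-z scatter for screen QC figures."""

from __future__ import annotations

import pandas as pd

from .rsa import HitThresholds


def rsa_scatter(
    genes: pd.DataFrame,
    direction: str = "down",
    thresholds: HitThresholds = HitThresholds(),
    ax=None,
):
    """Scatter of gene RSA log10 P against Q1 (down) or Q3 (up) z-score.

    Sensitizer calls live in the lower-left of the "down" panel,
    resistance calls in the lower-right of the "up" panel. Returns the
    matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    zcol = "q1_z" if direction == "down" else "q3_z"
    logp = genes[f"logp_{direction}"]
    hit = genes["hit_class"].str.startswith(
        "sensitizer" if direction == "down" else "resistance"
    )
    ax.scatter(genes.loc[~hit, zcol], logp[~hit], s=4, c="0.7", label="none")
    ax.scatter(genes.loc[hit, zcol], logp[hit], s=8, c="crimson", label="hit")
    ax.axhline(thresholds.rsa_stringent, ls="--", lw=0.8, c="k")
    ax.axhline(thresholds.rsa_lenient, ls=":", lw=0.8, c="k")
    ax.axvline(
        thresholds.q1_max if direction == "down" else thresholds.q3_min,
        ls="--", lw=0.8, c="k",
    )
    ax.set_xlabel(f"{'Q1' if direction == 'down' else 'Q3'} z-score")
    ax.set_ylabel(f"RSA {direction} (log10 P)")
    ax.legend(frameon=False, fontsize=8)
    return ax
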
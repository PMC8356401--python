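"""Risk-map plotting (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; must precede pyplot import
import matplotlib.pyplot as plt
import numpy as np

from .scoring import RiskMap

_BAND_COLORS = {"low": "#4575b4", "medium": "#fee090", "high": "#d73027"}


def plot_risk_map(risk_map: RiskMap, ax=None, n: int = 201):
    """Render a banded risk map: colored regions plus iso-risk boundaries."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    s, l, bands = risk_map.band_grid(n)
    codes = np.select([bands == "low", bands == "medium"], [0, 1], default=2)
    ax.contourf(
        s,
        l,
        codes,
        levels=[-0.5, 0.5, 1.5, 2.5],
        colors=[_BAND_COLORS["low"], _BAND_COLORS["medium"], _BAND_COLORS["high"]],
        alpha=0.6,
    )
    for name, (xs, ys) in risk_map.boundaries.items():
        mask = (ys >= risk_map.lp_range[0]) & (ys <= risk_map.lp_range[1])
        ax.plot(xs[mask], ys[mask], "k-", lw=1)
    ax.set_xlim(*risk_map.sdvr_range)
    ax.set_ylim(*risk_map.lp_range)
    ax.set_xlabel("SDVR (PSV/EDV, ICA)")
    ax.set_ylabel("Lp-PLA2 (µg/l)")
    ax.set_title(
        f"Stroke-Stop risk bands, {risk_map.plaque.value} plaque "
        f"(SF={risk_map.plaque.density_coefficient})"
    )
    return ax
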
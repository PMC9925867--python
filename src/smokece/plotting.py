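"""Cost-effectiveness plane and CEAC plots for PSA results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # noqa: E402 — headless backend
import matplotlib.pyplot as plt
import numpy as np

from .uncertainty import PSAResult

__all__ = ["plot_ce_plane", "plot_ceac"]


def plot_ce_plane(psa: PSAResult, ax=None):
    """Scatter of iteration-level (ΔQALY, Δcost) with the threshold line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    dq, dc = psa.delta_qalys, psa.delta_costs
    ax.scatter(dq, dc, s=6, alpha=0.35, edgecolors="none")
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    span = np.linspace(min(dq.min(), 0), max(dq.max(), 0), 10)
    ax.plot(span, psa.threshold * span, "--", color="firebrick",
            label=f"£{psa.threshold:,.0f}/QALY")
    ax.scatter([dq.mean()], [dc.mean()], color="black", zorder=5, label="mean")
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (£)")
    ax.set_title(f"Cost-effectiveness plane: {psa.comparison}")
    ax.legend(frameon=False)
    return ax


def plot_ceac(psa: PSAResult, ax=None):
    """Probability cost-effective across the willingness-to-pay grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ceac = psa.ceac
    ax.plot(ceac["threshold"], ceac["probability"])
    ax.axvline(psa.threshold, color="grey", ls=":", lw=0.8)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("Willingness to pay (£/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_title(f"CEAC: {psa.comparison}")
    return ax
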
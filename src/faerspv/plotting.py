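"""Optional plot output: forest plots of ROR signals and KM cumulative incidence."""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .disproportionality import SignalResult
from .time_to_onset import KMCurve

__all__ = ["plot_forest", "plot_km_curves"]


def plot_forest(results: Sequence[SignalResult], path: str | Path, title: str = "") -> None:
    """Forest plot of ROR point estimates with 95% CIs on a log axis."""
    usable = [r for r in results if np.isfinite(r.ror)]
    if not usable:
        raise ValueError("no calculable ROR results to plot")
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(usable) + 1.5))
    ys = np.arange(len(usable))[::-1]
    for y, r in zip(ys, usable):
        color = "tab:red" if r.significant else "tab:gray"
        ax.plot([r.ci_low, r.ci_high], [y, y], color=color, lw=1.2)
        ax.plot(r.ror, y, "o", color=color, ms=4)
    ax.axvline(1.0, color="k", lw=0.8, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels([f"{r.term} (N={r.n})" for r in usable], fontsize=7)
    ax.set_xscale("log")
    ax.set_xlabel("ROR (95% CI)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_km_curves(curves: Mapping[str, KMCurve], path: str | Path) -> None:
    """Overlayed KM cumulative incidence step curves, one per drug."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        ax.step([0.0, *curve.times], [0.0, *curve.cum_incidence], where="post", label=label)
    ax.set_xlabel("days since therapy start")
    ax.set_ylabel("cumulative incidence of reported AEs")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
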
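"""Figure helpers: state probability and contrast curves faceted by state."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .probabilities import ContrastCurve, StateProbabilityCurve
from .states import STATES


def plot_state_probability_curves(
    curves: Sequence[StateProbabilityCurve], path=None, title: str | None = None
):
    """One panel per state, one step line per curve (exposure group)."""
    fig, axes = plt.subplots(1, len(STATES), figsize=(4 * len(STATES), 3.2), sharex=True)
    for k, (ax, state) in enumerate(zip(axes, STATES)):
        for curve in curves:
            ax.step(curve.times, curve.probabilities[:, k], where="post", label=curve.label)
        ax.set_title(state.replace("_", " "))
        ax.set_xlabel("years since inclusion")
        ax.set_ylim(0, 1)
    axes[0].set_ylabel("state probability")
    axes[0].legend(fontsize="x-small")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_contrast_curves(
    curves: Sequence[ContrastCurve], path=None, title: str | None = None
):
    """Faceted contrast curves (differences or ratios) per state."""
    fig, axes = plt.subplots(1, len(STATES), figsize=(4 * len(STATES), 3.2), sharex=True)
    reference = {"difference": 0.0, "ratio": 1.0, "ratio_of_differences": 1.0}
    for k, (ax, state) in enumerate(zip(axes, STATES)):
        for curve in curves:
            ax.step(curve.times, curve.values[:, k], where="post",
                    label=f"{curve.label} ({curve.kind})")
            ax.axhline(reference.get(curve.kind, 0.0), color="grey", lw=0.5)
        ax.set_title(state.replace("_", " "))
        ax.set_xlabel("years since inclusion")
    axes[0].set_ylabel("contrast")
    axes[0].legend(fontsize="x-small")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
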
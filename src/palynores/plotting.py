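"""Minimal plots for indicator curves and psi drop profiles (matplotlib optional)."""

from __future__ import annotations

from .abundance import CATEGORIES, IndicatorCurveSet
from .slotting import DropResult


def plot_indicator_curves(curves: IndicatorCurveSet, ax=None):
    """Summed indicator percentages vs age, one line per capacity category."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for category in CATEGORIES:
        ax.plot(curves.ages, curves[category], label=category)
    ax.set_xlabel("age (cal yr BP)")
    ax.set_ylabel("% of reference sum")
    ax.set_title(f"anthropogenic indicator curves ({curves.level})")
    ax.invert_xaxis()  # older to the left
    ax.legend()
    return ax


def plot_drop_profile(drops: DropResult, ax=None):
    """Per-bin psi drop percentages (positive bars: bin drives dissimilarity)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(drops.bins, drops.drop_percent.to_numpy(),
           width=0.8 * (drops.bins[1] - drops.bins[0]) if len(drops.bins) > 1 else 400.0)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("bin older edge (cal yr BP)")
    ax.set_ylabel("psi drop (%)")
    ax.invert_xaxis()
    return ax
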
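"""Figures: averaged daily profiles and PCA factorial maps with group ellipses."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.patches import Ellipse  # noqa: E402

from .preprocess import DailyProfile
from .unsupervised import GroupEllipse

__all__ = ["plot_daily_profile", "plot_factorial_map"]


def plot_daily_profile(profile: DailyProfile, ax=None):
    """Mean +/- s.e.m. daily cycle (x axis: hour of day)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    hours = np.arange(profile.mean.size) / 60.0
    ax.plot(hours, profile.mean, color="k", lw=1.2, label=f"mean (n={profile.n})")
    ax.fill_between(hours, profile.mean - profile.sem, profile.mean + profile.sem,
                    color="k", alpha=0.25, lw=0, label="s.e.m.")
    ax.set_xlabel("hour of day")
    ax.set_ylabel("normalized EP")
    ax.set_xlim(0, 24)
    ax.legend(frameon=False)
    return ax


def plot_factorial_map(scores: np.ndarray, groups, ellipses: list[GroupEllipse],
                       explained=None, ax=None):
    """First-two-components scatter coloured by group, with p=0.05 ellipses."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    groups = np.asarray(groups)
    colours = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for i, g in enumerate(np.unique(groups)):
        pts = scores[groups == g]
        ax.scatter(pts[:, 0], pts[:, 1], s=8, alpha=0.6,
                   color=colours[i % len(colours)], label=str(g))
    for i, ell in enumerate(ellipses):
        ax.add_patch(Ellipse(ell.center, 2 * ell.semi_axes[0], 2 * ell.semi_axes[1],
                             angle=np.degrees(ell.angle_rad), fill=False,
                             color=colours[i % len(colours)], lw=1.5))
    labels = ["PC1", "PC2"]
    if explained is not None:
        labels = [f"{l} ({100 * e:.1f}%)" for l, e in zip(labels, explained)]
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    ax.legend(frameon=False)
    return ax
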
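"""Optional matplotlib views of the behavioral summaries."""

from __future__ import annotations

import numpy as np

from . import behavior as bhv


def plot_delta(trials, ax=None):
    """Delta plot: per-decile RT congruency effect vs. decile mean RT."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = bhv.delta_plot(trials)
    ax.plot(pts[:, 0], pts[:, 1] * 1000, "o-")
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("mean RT (s)")
    ax.set_ylabel("RT congruency effect (ms)")
    return ax


def plot_conditional_accuracy(trials, ax=None):
    """Conditional accuracy functions for both congruency classes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    caf = bhv.conditional_accuracy(trials)
    for name, marker in (("congruent", "o"), ("incongruent", "s")):
        pts = caf[name]
        ax.plot(pts[:, 0], pts[:, 1], marker + "-", label=name)
    ax.set_xlabel("mean RT (s)")
    ax.set_ylabel("accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def plot_training(log_frame, ax=None):
    """Training/validation ELBO (or loss) over epochs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    cols = [c for c in ("train_elbo", "val_elbo", "train_loss",
                        "val_accuracy") if c in log_frame]
    for c in cols:
        ax.plot(log_frame["epoch"], log_frame[c], label=c)
    ax.set_xlabel("epoch")
    ax.legend()
    return ax
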
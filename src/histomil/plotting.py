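"""Plot helpers for fitted results (Kaplan-Meier curves, attention maps)."""

from __future__ import annotations

import numpy as np


def plot_km(curves, labels=None, ax=None):
    """Step plot of one or more Kaplan-Meier curves."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    if not isinstance(curves, (list, tuple)):
        curves = [curves]
    labels = labels or [f"group {i}" for i in range(len(curves))]
    for curve, lab in zip(curves, labels):
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=lab)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax


def plot_attention(weights, ax=None, bins=30):
    """Histogram of per-tile attention weights of one slide."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.hist(np.asarray(weights), bins=bins)
    ax.set_xlabel("attention weight")
    ax.set_ylabel("tiles")
    return ax
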
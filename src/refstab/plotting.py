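"""Matplotlib renderings of the stability and validation outputs.

Bar charts order genes least stable (left) to most stable (right), the
convention used throughout the field's stability reports; expression panels
show log10 relative quantity.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt

__all__ = [
    "plot_method_scores",
    "plot_consensus",
    "plot_v_curve",
    "plot_log10_rq",
]


def _bar(ax, names, values, ylabel, title):
    ax.bar(range(len(names)), values, color="#4878a8")
    ax.set_xticks(range(len(names)), names, rotation=60, ha="right", fontsize=8)
    ax.set_ylabel(ylabel)
    ax.set_title(title, fontsize=10)
    return ax


def plot_method_scores(scores, method: str, label: str = "", ax=None):
    """Bar chart of one method's raw scores, least stable on the left."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ascending = method == "bestkeeper"  # high r = stable, so low r leftmost
    s = scores.sort_values(ascending=ascending)
    ylabel = {
        "genorm": "geNorm M",
        "bestkeeper": "Pearson r vs index",
        "deltact": "mean pair SD (Cq)",
        "normfinder": "NormFinder stability",
    }.get(method, method)
    _bar(ax, list(s.index), s.to_numpy(), ylabel, f"{method} — {label}")
    ax.figure.tight_layout()
    return ax


def plot_consensus(consensus, label: str = "", ax=None):
    """Bar chart of aggregate consensus scores (least stable leftmost)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    s = consensus["aggregate"].sort_values(ascending=False)
    _bar(ax, list(s.index), s.to_numpy(), "consensus geometric mean",
         f"consensus — {label}")
    ax.figure.tight_layout()
    return ax


def plot_v_curve(v_curve, label: str = "", ax=None):
    """geNorm V(n/n+1) against panel size, with the 0.2 guideline."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ns = [n for n, _ in v_curve]
    vs = [v for _, v in v_curve]
    ax.plot(ns, vs, marker="o")
    ax.axhline(0.2, linestyle="--", color="grey", linewidth=1)
    ax.set_xticks(ns, [f"{n}/{n+1}" for n in ns])
    ax.set_xlabel("references used (n/n+1)")
    ax.set_ylabel("pairwise variation V")
    ax.set_title(f"geNorm V curve — {label}", fontsize=10)
    ax.figure.tight_layout()
    return ax


def plot_log10_rq(values, annotation, title: str = "", ax=None):
    """Strip plot of log10 RQ per muscle/strain, mirroring expression panels."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    log10 = np.log10(values)
    groups = annotation.loc[values.index].groupby(["muscle", "strain"], sort=False)
    ticks, labels = [], []
    rng = np.random.default_rng(0)  # deterministic jitter, cosmetic only
    for pos, (key, idx) in enumerate(groups.groups.items()):
        y = log10.loc[idx]
        x = pos + rng.uniform(-0.18, 0.18, size=len(y))
        ax.plot(x, y, "o", markersize=3, alpha=0.6)
        ticks.append(pos)
        labels.append("\n".join(map(str, key)))
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_ylabel("log10 RQ")
    ax.set_title(title, fontsize=10)
    ax.figure.tight_layout()
    return ax
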
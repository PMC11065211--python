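"""Static figures: per-group score distributions and pre/post volcano."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .propensity import PropensityScores, score_distribution_summary
from .markers import SetComparison

__all__ = ["plot_score_distribution", "plot_volcano", "plot_set_counts"]

_CATEGORY_COLORS = {
    "shared": "tab:green",
    "pre_only": "tab:blue",
    "post_only": "tab:red",
    "non_significant": "0.7",
}


def plot_score_distribution(scores: PropensityScores, path=None, n_bins: int = 20):
    """Histogram plus density overlay of propensity scores per group."""
    summ = score_distribution_summary(scores, n_bins=n_bins)
    fig, ax = plt.subplots(figsize=(6, 4))
    width = summ.histogram["bin_right"] - summ.histogram["bin_left"]
    for grp, color in (("good", "tab:blue"), ("poor", "tab:orange")):
        ax.bar(
            summ.histogram["bin_left"],
            summ.histogram[f"count_{grp}"],
            width=width,
            align="edge",
            alpha=0.45,
            color=color,
            label=f"{grp} prognosis",
        )
    ax2 = ax.twinx()
    ax2.plot(summ.density["score"], summ.density["density_good"], color="tab:blue")
    ax2.plot(summ.density["score"], summ.density["density_poor"], color="tab:orange")
    ax2.set_ylabel("density")
    ax.set_xlabel("propensity score")
    ax.set_ylabel("cases")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_volcano(comparison: SetComparison, which: str = "post", path=None):
    """Effect vs -log10 p, colored by the shared/pre-only/post-only classes."""
    v = comparison.volcano
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for cat, color in _CATEGORY_COLORS.items():
        sub = v[v["category"] == cat]
        ax.scatter(
            sub[f"effect_{which}"],
            sub[f"minus_log10_p_{which}"],
            s=8,
            color=color,
            label=f"{cat} (n={len(sub)})",
        )
    ax.set_xlabel("effect (log2 fold change, poor - good)")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_set_counts(comparison: SetComparison, path=None):
    """Bar summary of the shared / pre-only / post-only partition."""
    counts = comparison.counts
    keys = ["pre_only", "shared", "post_only"]
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.bar(keys, [counts[k] for k in keys],
           color=[_CATEGORY_COLORS[k] for k in keys])
    ax.set_ylabel("significant markers")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
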
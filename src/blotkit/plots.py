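"""Bar graph of group means with 95% confidence-interval error bars."""

from __future__ import annotations

from pathlib import Path

from .models import SummaryTable

__all__ = ["group_bar_plot"]


def group_bar_plot(summary: SummaryTable, path: str | Path, ylabel: str = "Band density (a.u.)"):
    """Save a per-group bar plot; error bars span the 95% CI where defined."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = [g.group for g in summary.groups]
    means = [g.mean for g in summary.groups]
    lo = [g.mean - g.ci95_low if g.ci95_low is not None else 0.0 for g in summary.groups]
    hi = [g.ci95_high - g.mean if g.ci95_high is not None else 0.0 for g in summary.groups]

    fig, ax = plt.subplots(figsize=(1.2 + len(groups), 3.2))
    ax.bar(groups, means, yerr=[lo, hi], capsize=4, color="#6b8ebf", edgecolor="black")
    ax.set_ylabel(ylabel)
    ax.set_xlabel("Experimental group")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
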
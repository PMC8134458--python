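"""Simple metric-curve plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_metric_curves"]


def plot_metric_curves(curves: dict, path: str | None = None, title: str | None = None):
    """Plot metric-vs-sparsity curves (one panel per metric).

    ``curves`` maps metric name to :class:`~morphconn.topology.MetricCurve`.
    """
    n = len(curves)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.0), squeeze=False)
    for ax, (name, curve) in zip(axes[0], curves.items()):
        ax.plot(curve.s_values, curve.values, marker="o", ms=3)
        ax.set_xlabel("sparsity S")
        ax.set_title(f"{name} (AUC={curve.auc:.3f})")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
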
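"""Line plots of metric value versus perturbation radius, one line per method."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .metrics import EvaluationResult, FAITHFULNESS_METRICS, STABILITY_METRICS

__all__ = ["plot_metric_vs_radius", "plot_all_metrics"]

_COLORS = {"cam": "tab:blue", "gradcam": "tab:orange", "random": "tab:green"}


def plot_metric_vs_radius(results: dict[str, EvaluationResult], metric: str, ax=None):
    """One metric panel: mean ± 95% CI against radius (cm), per method."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    for method, ev in results.items():
        rows = [r for r in ev.results if r.metric == metric]
        rows.sort(key=lambda r: r.radius_m)
        x = [r.radius_m * 100 for r in rows]
        y = [r.mean for r in rows]
        ci = [r.ci95 for r in rows]
        ax.errorbar(
            x, y, yerr=ci, marker="o", capsize=3,
            label=method, color=_COLORS.get(method),
        )
    ax.set_xlabel("perturbation radius (cm)")
    ax.set_ylabel(metric)
    ax.set_xscale("log")
    ax.legend(fontsize=8)
    return ax


def plot_all_metrics(results: dict[str, EvaluationResult], out_path=None):
    """Grid of panels covering PGI/PGU and the five stability metrics."""
    metrics = list(FAITHFULNESS_METRICS + STABILITY_METRICS)
    ncols = 4
    nrows = -(-len(metrics) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.2 * ncols, 3.1 * nrows))
    axes = axes.ravel()
    for ax, metric in zip(axes, metrics):
        plot_metric_vs_radius(results, metric, ax=ax)
    for ax in axes[len(metrics):]:
        ax.set_visible(False)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    return fig
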
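"""Bar and box visualizations of variance-component distributions.

Bars show the interval center (median or pseudo-value mean) as the top
of a shaded bar with error bars spanning the confidence interval; boxes
show the full resampled distribution with 1.5*IQR whiskers and outlier
dots.  Multiple traits can be grouped side by side via labeled inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .decomposition import DERIVED_COMPONENTS
from .errors import PlottingError, ValidationError
from .uncertainty import ComponentMatrix, IntervalSet, percent_rows

__all__ = ["PlotSpec", "bar_plot", "box_plot"]

_LABELS = {"additive": "Additive", "nonadditive": "Nonadditive", "maternal": "Maternal"}


@dataclass
class PlotSpec:
    """Appearance and output options for the plotting functions."""

    path: str = "components.png"
    fmt: str = "png"
    y_unit: float | None = None      # y-axis tick increment
    y_min: float | None = None
    y_max: float | None = None
    label_size: float | None = None
    title: str | None = None

    def __post_init__(self) -> None:
        if self.y_unit is not None and self.y_unit <= 0:
            raise ValidationError("y-axis unit increment must be > 0")
        if (
            self.y_min is not None
            and self.y_max is not None
            and self.y_min >= self.y_max
        ):
            raise ValidationError("y_min must be below y_max")
        if self.fmt not in ("png", "svg"):
            raise ValidationError("fmt must be png or svg")


def _apply_axis(ax, plot: PlotSpec) -> None:
    if plot.y_min is not None or plot.y_max is not None:
        ax.set_ylim(plot.y_min, plot.y_max)
    if plot.y_unit is not None:
        lo, hi = ax.get_ylim()
        ax.set_yticks(np.arange(np.floor(lo / plot.y_unit) * plot.y_unit,
                                hi + plot.y_unit / 2, plot.y_unit))
    if plot.label_size is not None:
        ax.tick_params(labelsize=plot.label_size)
        ax.yaxis.label.set_size(plot.label_size)
    if plot.title:
        ax.set_title(plot.title)


def _as_groups(obj, cls, what: str) -> dict:
    if isinstance(obj, cls):
        return {"": obj}
    if isinstance(obj, dict) and obj and all(
        isinstance(v, cls) for v in obj.values()
    ):
        return obj
    raise PlottingError(f"expected {what} or a label->{what} mapping")


def bar_plot(
    intervals,
    plot: PlotSpec | None = None,
    scale: str = "raw",
    components: tuple[str, ...] = DERIVED_COMPONENTS,
) -> str:
    """Shaded bars at the interval centers with CI error bars.

    ``intervals`` is an :class:`IntervalSet` or a mapping of trait label
    to IntervalSet (grouped clusters).  Returns the output path.
    """
    plot = plot or PlotSpec()
    groups = _as_groups(intervals, IntervalSet, "IntervalSet")
    for label, iv in groups.items():
        values = iv.raw if scale == "raw" else iv.percent
        missing = [c for c in components if c not in values]
        if missing:
            raise PlottingError(
                f"interval set {label or 'input'!r} lacks components {missing}"
            )
    fig, ax = plt.subplots(figsize=(1.2 + 1.6 * len(groups), 4.0))
    width = 0.8 / len(components)
    offsets = (np.arange(len(components)) - (len(components) - 1) / 2) * width
    colors = plt.cm.Greys(np.linspace(0.35, 0.75, len(components)))
    for j, (label, iv) in enumerate(groups.items()):
        values = iv.raw if scale == "raw" else iv.percent
        for i, comp in enumerate(components):
            lo, center, hi = values[comp]
            ax.bar(
                j + offsets[i], center, width=width * 0.95,
                color=colors[i], edgecolor="black", linewidth=0.6,
                label=_LABELS.get(comp, comp) if j == 0 else None,
            )
            ax.errorbar(
                j + offsets[i], center,
                yerr=[[center - lo], [hi - center]],
                fmt="none", ecolor="black", capsize=3, linewidth=1.0,
            )
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels(list(groups))
    ax.set_ylabel("Variance" if scale == "raw" else "% of total variance")
    ax.legend(frameon=False)
    _apply_axis(ax, plot)
    fig.tight_layout()
    fig.savefig(plot.path, format=plot.fmt, dpi=150)
    plt.close(fig)
    return plot.path


def box_plot(
    matrix,
    plot: PlotSpec | None = None,
    scale: str = "raw",
    components: tuple[str, ...] = DERIVED_COMPONENTS,
) -> str:
    """Boxplots of all resampled component values.

    Boxes span the 25th-75th quartiles with a median bar; whiskers
    extend to 1.5*IQR and further points are drawn as outlier dots.
    """
    plot = plot or PlotSpec()
    groups = _as_groups(matrix, ComponentMatrix, "ComponentMatrix")
    data, labels = [], []
    for label, mat in groups.items():
        frame = mat.usable
        if len(frame) < 5:
            raise PlottingError(
                f"matrix {label or 'input'!r} has fewer than 5 usable rows"
            )
        values = frame if scale == "raw" else percent_rows(frame)
        missing = [c for c in components if c not in values.columns]
        if missing:
            raise PlottingError(f"matrix lacks components {missing}")
        for comp in components:
            data.append(values[comp].to_numpy(dtype=float))
            name = _LABELS.get(comp, comp)
            labels.append(f"{label}\n{name}" if label else name)
    fig, ax = plt.subplots(figsize=(1.0 + 0.9 * len(data), 4.0))
    ax.boxplot(
        data, tick_labels=labels, whis=1.5,
        medianprops={"color": "black", "linewidth": 1.6},
        flierprops={"marker": "o", "markersize": 3},
    )
    ax.set_ylabel("Variance" if scale == "raw" else "% of total variance")
    _apply_axis(ax, plot)
    fig.tight_layout()
    fig.savefig(plot.path, format=plot.fmt, dpi=150)
    plt.close(fig)
    return plot.path
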
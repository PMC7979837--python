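"""Per-cell heatmaps and count histograms.

Cell heatmaps draw one dot per cell at its projected centroid; dot area and
colour are both monotone in the plotted value.  Counts and Fano are colour
normalised per gene to [0, population max]; NV and PV use the fixed [0, 1]
scale shared by all genes.  Rendering never mutates its inputs and is
deterministic for fixed inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

__all__ = [
    "HeatmapSpec",
    "RenderResult",
    "dot_sizes",
    "render_cell_heatmap",
    "render_histogram",
    "profile_along_axis",
]

#: value keys drawn on a fixed 0-1 colour scale
_UNIT_SCALE_KEYS = {"nv", "pv_raw", "pv_filtered", "pv"}


@dataclass(slots=True)
class HeatmapSpec:
    value_key: str = "count"
    cmap: str = "viridis"
    dot_size_range: tuple[float, float] = (6.0, 60.0)
    projection: str = "xy"
    out: Path | str | None = None

    def __post_init__(self) -> None:
        lo, hi = self.dot_size_range
        if not (0 < lo < hi):
            raise ValueError("dot_size_range must be positive and increasing")
        if self.projection not in {"xy", "xz"}:
            raise ValueError("projection must be 'xy' or 'xz'")


@dataclass(slots=True)
class RenderResult:
    path: Path | None
    values: np.ndarray
    sizes: np.ndarray = field(default_factory=lambda: np.empty(0))
    heights: list = field(default_factory=list)
    labels: list = field(default_factory=list)


def dot_sizes(values: np.ndarray, size_range: tuple[float, float]) -> np.ndarray:
    """Linear value → marker-area map onto [min, max] of the size range;
    constant values all take the minimum size."""
    v = np.asarray(values, dtype=float)
    lo, hi = size_range
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        return np.full(v.shape, lo)
    return lo + (v - vmin) / (vmax - vmin) * (hi - lo)


def _aligned(values, centroids) -> tuple[pd.Series, pd.DataFrame]:
    values = pd.Series(values) if not isinstance(values, pd.Series) else values
    if isinstance(centroids, Mapping):
        centroids = pd.DataFrame(
            {c: np.asarray(p, dtype=float) for c, p in centroids.items()},
        ).T.rename(columns=dict(enumerate(["centroid_x_um", "centroid_y_um", "centroid_z_um"])))
    values.index = values.index.astype(str)
    centroids.index = centroids.index.astype(str)
    missing = sorted(set(centroids.index) - set(values.index))
    if missing:
        raise ValueError(f"missing value for cell(s): {missing[:10]}")
    return values.loc[centroids.index], centroids


def render_cell_heatmap(values, centroids, spec: HeatmapSpec) -> RenderResult:
    """Render a dot heatmap of per-cell values; returns the drawn geometry
    (sizes and value array) alongside the output path."""
    values, centroids = _aligned(values, centroids)
    v = values.to_numpy(dtype=float)
    x = centroids["centroid_x_um"].to_numpy()
    y = centroids["centroid_y_um" if spec.projection == "xy" else "centroid_z_um"].to_numpy()
    sizes = dot_sizes(v, spec.dot_size_range)
    vmin, vmax = (0.0, 1.0) if spec.value_key in _UNIT_SCALE_KEYS else (0.0, max(v.max(), 1e-12))
    fig, ax = plt.subplots(figsize=(9.0, 3.5))
    sc = ax.scatter(x, y, s=sizes, c=v, cmap=spec.cmap, vmin=vmin, vmax=vmax,
                    linewidths=0, rasterized=True)
    ax.set_aspect("equal")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel(("y" if spec.projection == "xy" else "z") + " (μm)")
    fig.colorbar(sc, ax=ax, label=spec.value_key, shrink=0.8)
    path = None
    if spec.out is not None:
        path = Path(spec.out)
        path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=120, metadata={"Date": None})
    plt.close(fig)
    return RenderResult(path=path, values=v, sizes=sizes)


def render_histogram(histogram: Mapping[str, int], out: Path | str | None,
                     title: str = "") -> RenderResult:
    """Bar chart of a binned count histogram ({"1-5": n, ...}).

    An empty histogram produces an empty-axes figure with a warning rather
    than an error (an all-zero gene is a legitimate outcome).
    """
    labels = list(histogram)
    heights = [int(histogram[k]) for k in labels]
    fig, ax = plt.subplots(figsize=(6.0, 3.5))
    if labels:
        ax.bar(range(len(labels)), heights, color="#5377a8")
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
    else:
        warnings.warn("empty histogram: rendering empty axes", stacklevel=2)
    ax.set_xlabel("mRNA per cell")
    ax.set_ylabel("cells")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = None
    if out is not None:
        path = Path(out)
        path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=120, metadata={"Date": None})
    plt.close(fig)
    return RenderResult(path=path, values=np.asarray(heights, dtype=float),
                        heights=heights, labels=labels)


def profile_along_axis(values, centroids, n_bins: int = 60, axis: str = "x"):
    """Mean plotted value per position bin along one axis — a quick check
    that spatial structure (e.g. stripes) survives into the rendered values.
    Returns (bin centres, binned means); empty bins give NaN."""
    values, centroids = _aligned(values, centroids)
    coord = centroids[f"centroid_{axis}_um"].to_numpy()
    v = values.to_numpy(dtype=float)
    edges = np.linspace(coord.min(), coord.max() + 1e-9, n_bins + 1)
    which = np.digitize(coord, edges) - 1
    means = np.array([v[which == b].mean() if np.any(which == b) else np.nan
                      for b in range(n_bins)])
    return (edges[:-1] + edges[1:]) / 2.0, means
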
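"""Colorized parametric maps for pre/post side-by-side review.

Rendering convention: red always means *increased* perfusion.  For the
timing metrics (AT, TTP, TTD, MTT) low values are good, so the colormap
runs red (low) -> yellow -> blue -> black (high); for the flow metrics
(CBV, CBF) high values are good, so the same lookup table is applied in
reverse.  Pre and post maps of a metric are normalized over identical
bounds (robust pooled percentiles) so their colors are directly
comparable; invalid pixels render black.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .model import FLOW_METRICS, Metric, PerfusionMapSet

__all__ = ["load_lut", "joint_normalize", "render_map", "compose_panel"]

_LUT_CACHE: Optional[np.ndarray] = None


def load_lut() -> np.ndarray:
    """The packaged 256-entry red->yellow->blue->black LUT, floats in [0, 1]."""
    global _LUT_CACHE
    if _LUT_CACHE is None:
        ref = importlib.resources.files("dsaperf.data").joinpath("lut_perfusion.csv")
        table = np.loadtxt(str(ref), delimiter=",", skiprows=1)
        if table.shape != (256, 3):
            raise ValueError("LUT table must be 256 x 3")
        _LUT_CACHE = table
    return _LUT_CACHE


def joint_normalize(
    pre: PerfusionMapSet,
    post: PerfusionMapSet,
    metric: Metric,
    robust_pct: Tuple[float, float] = (2.0, 98.0),
) -> Tuple[float, float]:
    """Shared display bounds: robust percentiles of the pooled valid pixels.

    Percentile (default 2nd/98th) rather than min/max normalization,
    because subtraction noise produces extreme outliers that would crush
    the display range.  The same bounds apply to both studies.
    """
    metric = Metric(metric)
    vals = np.concatenate(
        [pre[metric][pre.validity_mask], post[metric][post.validity_mask]]
    )
    if vals.size == 0:
        raise ValueError(f"no valid pixels to normalize for {metric.value}")
    lo, hi = np.percentile(vals, robust_pct)
    return float(lo), float(hi)


def render_map(
    map2d: np.ndarray,
    bounds: Tuple[float, float],
    metric: Metric,
    lut: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, dict]:
    """Colorize one metric map; returns (H, W, 3) uint8 RGB plus metadata.

    Timing metrics map low->red; flow metrics are reversed so high->red.
    NaN (invalid) pixels are black.  The sidecar metadata records metric,
    bounds and LUT orientation so the rendering is self-describing.
    """
    metric = Metric(metric)
    lut = load_lut() if lut is None else lut
    lo, hi = bounds
    if not hi > lo:
        raise ValueError("bounds must satisfy hi > lo")
    norm = (np.asarray(map2d, dtype=float) - lo) / (hi - lo)
    norm = np.clip(norm, 0.0, 1.0)
    reversed_lut = metric in FLOW_METRICS
    if reversed_lut:
        norm = 1.0 - norm
    invalid = np.isnan(norm)
    idx = np.rint(np.where(invalid, 0.0, norm) * 255).astype(np.intp)
    rgb = (lut[idx] * 255).round().astype(np.uint8)
    rgb[invalid] = 0
    meta = {
        "metric": metric.value,
        "lo": float(lo),
        "hi": float(hi),
        "orientation": "high_is_red" if reversed_lut else "low_is_red",
        "invalid_color": [0, 0, 0],
    }
    return rgb, meta


def unmap_colors(rgb: np.ndarray, metric: Metric, lut: Optional[np.ndarray] = None) -> np.ndarray:
    """Invert a rendered image back to normalized [0, 1] values (nearest LUT entry)."""
    lut = load_lut() if lut is None else lut
    lut8 = (lut * 255).round().astype(np.int32)
    flat = rgb.reshape(-1, 3).astype(np.int32)
    d2 = ((flat[:, None, :] - lut8[None, :, :]) ** 2).sum(axis=2)
    norm = np.argmin(d2, axis=1) / 255.0
    if Metric(metric) in FLOW_METRICS:
        norm = 1.0 - norm
    return norm.reshape(rgb.shape[:2])


def compose_panel(
    pre_ap: Optional[PerfusionMapSet] = None,
    pre_lat: Optional[PerfusionMapSet] = None,
    post_ap: Optional[PerfusionMapSet] = None,
    post_lat: Optional[PerfusionMapSet] = None,
    metric: Metric = Metric.TTP,
    robust_pct: Tuple[float, float] = (2.0, 98.0),
    out_path: Optional[Path] = None,
):
    """2x2 review panel for one metric, clockwise from top-left:
    pre-AP, pre-LAT, post-LAT, post-AP; shared color scale and colorbar.

    Missing views leave their quadrant blank.  Returns the matplotlib
    figure (saved to ``out_path`` when given).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    metric = Metric(metric)
    pairs = [(pre_ap, post_ap), (pre_lat, post_lat)]
    bounds = None
    for pre, post in pairs:
        if pre is not None and post is not None:
            b = joint_normalize(pre, post, metric, robust_pct)
            bounds = b if bounds is None else (min(bounds[0], b[0]), max(bounds[1], b[1]))
    if bounds is None:
        raise ValueError("need at least one pre/post pair of maps")

    # clockwise from top-left: (0,0) pre-AP, (0,1) pre-LAT, (1,1) post-LAT, (1,0) post-AP
    layout = [
        (0, 0, pre_ap, "pre AP"),
        (0, 1, pre_lat, "pre LAT"),
        (1, 1, post_lat, "post LAT"),
        (1, 0, post_ap, "post AP"),
    ]
    fig, axes = plt.subplots(2, 2, figsize=(8, 8))
    for r, c, maps, title in layout:
        ax = axes[r, c]
        ax.set_title(title)
        ax.set_axis_off()
        if maps is not None:
            rgb, _ = render_map(maps[metric], bounds, metric)
            ax.imshow(rgb)
    lut = load_lut()
    cmap_lut = lut[::-1] if metric in FLOW_METRICS else lut
    sm = plt.cm.ScalarMappable(
        cmap=ListedColormap(cmap_lut),
        norm=matplotlib.colors.Normalize(vmin=bounds[0], vmax=bounds[1]),
    )
    fig.colorbar(sm, ax=axes.ravel().tolist(), shrink=0.7, label=metric.value)
    fig.suptitle(f"{metric.value} (red = increased perfusion)")
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    return fig
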
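"""Distribution statistics over vascular-territory ROIs and pre/post deltas.

For each territory (MCA / ACA / PCA / vertebrobasilar) the per-pixel
perfusion metrics form a distribution; treatment effect is the change in
that distribution between the pre- and post-intervention runs.  The
comparison of means uses Welch's unequal-variance two-sample t-test: pre
and post pixel sets are not in spatial correspondence (no registration is
performed), so an unpaired test is the defensible default.  A paired
per-pixel mode exists for registered phantoms.

Caveat documented up front: per-pixel samples inside an ROI are spatially
autocorrelated, so pixel-level p-values are anticonservative.  An
effective-sample-size correction via block subsampling (keep every k-th
pixel) is available and off by default.
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .model import (
    Metric,
    MetricComparison,
    MetricDistributionSummary,
    PerfusionMapSet,
    ROIMask,
    TerritoryComparison,
    View,
)

__all__ = [
    "roi_values",
    "summarize_roi",
    "compare_pre_post",
    "aggregate_cases",
]


def roi_values(maps: PerfusionMapSet, roi: ROIMask, metric: Metric) -> np.ndarray:
    """Valid in-ROI pixel values for one metric, as a flat array."""
    if roi.mask.shape != maps.shape:
        raise ValueError("ROI shape does not match the maps")
    sel = roi.mask & maps.validity_mask
    return maps[metric][sel]


def _moments(x: np.ndarray) -> tuple:
    """mean, median, sample sd, adjusted skew, adjusted excess kurtosis.

    Skew and kurtosis are defined as 0 for zero-variance samples.
    """
    mean = float(np.mean(x))
    median = float(np.median(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if sd == 0 or x.size < 3:
        skew = 0.0
    else:
        skew = float(stats.skew(x, bias=False))
    if sd == 0 or x.size < 4:
        kurt = 0.0
    else:
        kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    return mean, median, sd, skew, kurt


def summarize_roi(
    maps: PerfusionMapSet, roi: ROIMask, metrics: Sequence[Metric] = tuple(Metric)
) -> List[MetricDistributionSummary]:
    """Distribution summary of each metric over valid in-ROI pixels."""
    out = []
    for metric in metrics:
        x = roi_values(maps, roi, metric)
        if x.size == 0:
            raise ValueError(f"ROI '{roi.name}' contains no valid pixels")
        mean, median, sd, skew, kurt = _moments(x)
        out.append(
            MetricDistributionSummary(
                metric=metric,
                n_valid_px=int(x.size),
                mean=mean,
                median=median,
                sd=sd,
                skew=skew,
                kurtosis=kurt,
            )
        )
    return out


def _welch(post: np.ndarray, pre: np.ndarray) -> tuple:
    """Welch delta of means, 95% CI half-width, p-value.

    Degenerate zero-variance pairs: identical constants give p = 1;
    different constants give p = 0.
    """
    delta = float(np.mean(post) - np.mean(pre))
    v1, v2 = np.var(post, ddof=1), np.var(pre, ddof=1)
    n1, n2 = post.size, pre.size
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return delta, 0.0, (1.0 if delta == 0 else 0.0)
    se = math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    tcrit = float(stats.t.ppf(0.975, df))
    p = float(2 * stats.t.sf(abs(delta) / se, df))
    return delta, tcrit * se, p


def compare_pre_post(
    pre_maps: PerfusionMapSet,
    post_maps: PerfusionMapSet,
    roi: ROIMask,
    alpha: float = 0.05,
    metrics: Sequence[Metric] = tuple(Metric),
    paired: bool = False,
    subsample_step: int = 1,
) -> TerritoryComparison:
    """Pre/post change per metric over one ROI.

    ``delta_mean`` is post minus pre.  Unpaired Welch test by default;
    ``paired=True`` runs a paired t-test on pixels valid in both runs
    (registered phantoms only).  ``subsample_step > 1`` keeps every k-th
    in-ROI pixel as a crude effective-sample-size correction for spatial
    autocorrelation.
    """
    comps: Dict[Metric, MetricComparison] = {}
    for metric in metrics:
        if paired:
            sel = roi.mask & pre_maps.validity_mask & post_maps.validity_mask
            a = post_maps[metric][sel]
            b = pre_maps[metric][sel]
            if subsample_step > 1:
                a, b = a[::subsample_step], b[::subsample_step]
            d = a - b
            delta = float(np.mean(d))
            sd = float(np.std(d, ddof=1))
            n = d.size
            if sd == 0:
                hw, p = 0.0, (1.0 if delta == 0 else 0.0)
            else:
                se = sd / math.sqrt(n)
                hw = float(stats.t.ppf(0.975, n - 1)) * se
                p = float(2 * stats.t.sf(abs(delta) / se, n - 1))
            n_pre = n_post = n
        else:
            b = roi_values(pre_maps, roi, metric)
            a = roi_values(post_maps, roi, metric)
            if subsample_step > 1:
                a, b = a[::subsample_step], b[::subsample_step]
            if a.size < 2 or b.size < 2:
                raise ValueError(f"ROI '{roi.name}': too few valid pixels to compare")
            delta, hw, p = _welch(a, b)
            n_pre, n_post = b.size, a.size
        comps[metric] = MetricComparison(
            metric=metric,
            delta_mean=delta,
            ci95_halfwidth=hw,
            p_value=p,
            significant=bool(p < alpha),
            n_pre=n_pre,
            n_post=n_post,
        )
    return TerritoryComparison(
        roi_label=roi.name, view=roi.view, alpha=alpha, metrics=comps
    )


def aggregate_cases(
    comparisons: Sequence[TerritoryComparison],
    roi_label: str,
    view: View,
    metrics: Sequence[Metric] = tuple(Metric),
) -> Dict[Metric, dict]:
    """Across-case mean delta with a t-based 95% CI, per metric.

    Pools the per-case ``delta_mean`` values of all comparisons matching
    ``roi_label`` and ``view``.  With a single case the CI is undefined
    (NaN) and a warning is issued.
    """
    sel = [
        c for c in comparisons if c.roi_label == roi_label and c.view == View(view)
    ]
    if not sel:
        raise ValueError(f"no comparisons for roi={roi_label!r} view={view}")
    out: Dict[Metric, dict] = {}
    for metric in metrics:
        deltas = np.array([c.metrics[metric].delta_mean for c in sel])
        n = deltas.size
        mean = float(deltas.mean())
        if n < 2:
            warnings.warn(
                f"single case for roi={roi_label!r}: across-case CI undefined",
                stacklevel=2,
            )
            hw = float("nan")
        else:
            sd = float(deltas.std(ddof=1))
            hw = float(stats.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
        out[metric] = {"mean_delta": mean, "ci95_halfwidth": hw, "n_cases": n}
    return out
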
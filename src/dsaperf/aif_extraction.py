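"""Arterial input function from a user-drawn line across the injected vessel.

The AIF is the contrast-vs-time curve averaged along a short line segment
spanning the width of the vessel the catheter sits in.  Line placement is
manual by design (accuracy over automation); the extraction itself samples
the segment with bilinear interpolation, since vessel widths are only a
few pixels.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .model import AIFCurve, ContrastSequence, TimeIntensityCurve

__all__ = ["extract_aif"]


def extract_aif(
    cs: ContrastSequence,
    p0: Tuple[float, float],
    p1: Tuple[float, float],
    n_samples: Optional[int] = None,
) -> AIFCurve:
    """Average the contrast stack along the segment ``p0``-``p1`` per frame.

    Points are (row, col), 0-based.  ``n_samples`` defaults to
    ``ceil(segment length in px) + 1`` so sampling is at least pixel-dense.
    Values are bilinearly interpolated, making the result symmetric under
    endpoint exchange and stable in ``n_samples`` on locally uniform
    vessel interiors.

    Raises if the averaged curve has no positive peak (AIF line misplaced).
    """
    H, W = cs.frame_shape
    for name, p in (("p0", p0), ("p1", p1)):
        r, c = float(p[0]), float(p[1])
        if not (0 <= r <= H - 1 and 0 <= c <= W - 1):
            raise ValueError(f"{name}={p} outside the {H}x{W} frame")
    r0, c0 = float(p0[0]), float(p0[1])
    r1, c1 = float(p1[0]), float(p1[1])
    if (r0, c0) == (r1, c1):
        raise ValueError("AIF line endpoints must differ")

    length = math.hypot(r1 - r0, c1 - c0)
    if n_samples is None:
        n_samples = int(math.ceil(length)) + 1
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")

    s = np.linspace(0.0, 1.0, n_samples)
    rows = r0 + s * (r1 - r0)
    cols = c0 + s * (c1 - c0)
    coords = np.vstack([rows, cols])

    T = cs.contrast.shape[0]
    values = np.empty(T)
    for k in range(T):
        values[k] = map_coordinates(
            cs.contrast[k], coords, order=1, mode="nearest"
        ).mean()

    curve = TimeIntensityCurve(times=cs.times, values=np.maximum(values, 0.0))
    if float(curve.values.max()) <= 0:
        raise ValueError("AIF line sees no contrast (zero peak)")
    return AIFCurve(curve=curve, endpoints_px=((r0, c0), (r1, c1)), n_samples=n_samples)
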
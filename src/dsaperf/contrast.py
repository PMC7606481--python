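"""Raw subtracted frames -> nonnegative contrast proxy and integration window.

In standard DSA the subtracted image darkens where iodinated contrast is
present, so the per-pixel contrast proxy is the baseline-referenced
intensity *drop*, clamped at zero.  All downstream curve metrics are
evaluated only inside a single global signal-integration window, found on
the spatial-mean curve: it opens at the initiation of enhancement and
closes at the arrest of signal changes or the end of the run, whichever
comes first.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .model import ContrastSequence, FrameSequence, Polarity

__all__ = ["to_contrast", "detect_window", "mean_curve"]


def to_contrast(
    seq: FrameSequence,
    polarity: Polarity = Polarity.DARK_CONTRAST,
    baseline_frames: int = 2,
) -> ContrastSequence:
    """Convert a frame sequence into the contrast-proxy stack C_{x,y}(t).

    The per-pixel baseline is the mean of the first ``baseline_frames``
    frames (angiographic runs start before injection, so these frames are
    contrast-free).  DARK_CONTRAST: ``C = max(0, baseline - I)``;
    BRIGHT_CONTRAST: ``C = max(0, I - baseline)``.

    The per-pixel standard deviation of the raw intensity over the baseline
    window is carried along as ``baseline_sd`` — the downstream noise floor
    for pixel validity.
    """
    polarity = Polarity(polarity)
    T = seq.n_frames
    if not (1 <= baseline_frames < T):
        raise ValueError(f"baseline_frames must be in [1, {T - 1}], got {baseline_frames}")
    base = seq.frames[:baseline_frames]
    b = base.mean(axis=0)
    sd = base.std(axis=0, ddof=0) if baseline_frames > 1 else np.zeros_like(b)
    if polarity is Polarity.DARK_CONTRAST:
        c = b[None, :, :] - seq.frames
    else:
        c = seq.frames - b[None, :, :]
    np.maximum(c, 0.0, out=c)
    return ContrastSequence(
        contrast=c,
        times=seq.times,
        baseline_frames=baseline_frames,
        polarity=polarity,
        view=seq.view,
        baseline_sd=sd,
    )


def mean_curve(cs: ContrastSequence, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Spatial-mean contrast curve g(t), optionally restricted to a mask."""
    if mask is None:
        return cs.contrast.reshape(cs.contrast.shape[0], -1).mean(axis=1)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cs.frame_shape:
        raise ValueError("mask shape must match the frames")
    return cs.contrast[:, mask].mean(axis=1)


def detect_window(
    cs: ContrastSequence,
    enh_frac: float = 0.05,
    arrest_frac: float = 0.01,
    mask: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Find the global signal-integration window ``(t_start, t_end)``.

    On the spatial-mean curve g(t): ``t_start`` is the first frame time at
    which g exceeds ``enh_frac * max(g)`` (initiation of enhancement);
    ``t_end`` is the first post-peak frame time from which every subsequent
    per-frame change ``|g_k - g_{k-1}|`` stays below
    ``arrest_frac * max(g)`` (arrest of signal changes), else the last
    frame time (conclusion of the study).

    Thresholds are relative, so the window is invariant to global intensity
    scaling.  Raises if the stack shows no enhancement at all.
    """
    g = mean_curve(cs, mask)
    gmax = float(g.max())
    if gmax <= 0:
        raise ValueError("no enhancement detected: mean contrast curve is identically zero")
    t = cs.times

    above = g > enh_frac * gmax
    i_start = int(np.argmax(above))
    t_start = float(t[i_start])

    k_peak = int(np.argmax(g))
    dg = np.abs(np.diff(g))  # dg[k] = |g[k+1] - g[k]|
    thr = arrest_frac * gmax
    t_end = float(t[-1])
    for k in range(k_peak, len(g) - 1):
        if np.all(dg[k:] < thr):
            t_end = float(t[k])
            break
    if t_end <= t_start:
        t_end = float(t[-1])
    return t_start, t_end
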
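"""Bolus-tracking kinetics: AT, TTP, TTD, MTT, CBV, CBF.

Direct (deconvolution-free) bolus tracking on a pixel's contrast curve
C(t):

* **AT** — upward crossing of ``at_frac`` x peak (default 5%) on the
  rising edge leading into the peak, linearly interpolated between the
  bracketing samples.  For a clean single-pass curve this is simply the
  first crossing; anchoring it to the peak keeps it from latching onto
  pre-arrival baseline noise.
* **TTP** — time of the global maximum sample; ties break to the earliest.
* **TTD** — last downward crossing of ``ttd_frac`` x peak after the peak,
  linearly interpolated; a curve that never falls below the threshold
  before the window ends gets TTD = window end and a ``truncated`` flag.
* **MTT** — full width at half maximum: first upward minus last downward
  crossing of peak/2, both interpolated (NOT the deconvolution MTT of
  CT/MR perfusion).
* **CBV** — trapezoid integral of C over the window divided by the same
  integral of the arterial input curve (a relative, dimensionless ratio).
* **CBF** — central volume theorem, CBV / MTT (1/s).

Sub-sample precision matters here: DSA frame intervals (~0.25-1 s) are
coarse relative to clinically relevant effect sizes (a few tenths of a
second), hence the linear interpolation of every crossing.

All crossing searches are vectorized over ``(T, N)`` stacks so whole-frame
maps are a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .model import (
    AIFCurve,
    ContrastSequence,
    Metric,
    PerfusionMapSet,
    PerfusionParams,
    TimeIntensityCurve,
)

__all__ = [
    "KineticsConfig",
    "arrival_time",
    "time_to_peak",
    "time_to_drain",
    "mean_transit_time",
    "cbv",
    "cbf",
    "compute_params",
    "compute_maps",
]


@dataclass
class KineticsConfig:
    """Tunable thresholds of the curve metrics.

    at_frac, ttd_frac
        Relative peak fractions defining "contrast first arrives" and
        "contrast has left" (verbal definitions operationalised as 5%
        threshold crossings).
    noise_floor_k
        A pixel is valid only if its peak exceeds ``noise_floor_k`` times
        its baseline-window intensity SD; suppresses FWHM and division
        artifacts in air/bone regions.
    """

    at_frac: float = 0.05
    ttd_frac: float = 0.05
    noise_floor_k: float = 3.0


# --------------------------------------------------------------------------
# Vectorized crossing primitives on (T, N) stacks
# --------------------------------------------------------------------------


def _first_up_crossing(t: np.ndarray, v: np.ndarray, thr: np.ndarray) -> np.ndarray:
    """First time each column of ``v`` reaches ``thr``, linearly interpolated.

    Columns that never reach their threshold return NaN.  A column already
    at/above threshold at the first sample returns ``t[0]``.
    """
    T, _ = v.shape
    above = v >= thr[None, :]
    k = np.argmax(above, axis=0)
    hit = above.any(axis=0)
    k0 = np.clip(k, 1, T - 1)
    v_prev = np.take_along_axis(v, (k0 - 1)[None, :], axis=0)[0]
    v_next = np.take_along_axis(v, k0[None, :], axis=0)[0]
    denom = v_next - v_prev
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (thr - v_prev) / denom
    frac = np.where(denom > 0, frac, 0.0)
    out = t[k0 - 1] + frac * (t[k0] - t[k0 - 1])
    out = np.where(k == 0, t[0], out)
    return np.where(hit, out, np.nan)


def _up_crossing_into_peak(
    t: np.ndarray, v: np.ndarray, thr: np.ndarray, peak_idx: np.ndarray
) -> np.ndarray:
    """Threshold crossing on the rising edge attached to the peak.

    For each column: the last sample strictly below ``thr`` at or before
    the peak, interpolated to its following sample.  Columns already
    at/above threshold at the first sample return ``t[0]``.
    """
    T, N = v.shape
    idx = np.arange(T)[:, None]
    below = (v < thr[None, :]) & (idx <= peak_idx[None, :])
    anybelow = below.any(axis=0)
    j = T - 1 - np.argmax(below[::-1], axis=0)  # last below-threshold index
    j0 = np.clip(j, 0, T - 2)
    v_prev = np.take_along_axis(v, j0[None, :], axis=0)[0]
    v_next = np.take_along_axis(v, (j0 + 1)[None, :], axis=0)[0]
    denom = v_next - v_prev
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (thr - v_prev) / denom
    frac = np.where(denom > 0, frac, 0.0)
    out = t[j0] + frac * (t[j0 + 1] - t[j0])
    return np.where(anybelow, out, t[0])


def _last_down_crossing(
    t: np.ndarray, v: np.ndarray, thr: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Last time each column falls back through ``thr``; interpolated.

    Returns ``(times, truncated)``.  A column still at/above threshold at
    the final sample is truncated: its time is the window end ``t[-1]``.
    Columns never reaching threshold return NaN.
    """
    T, _ = v.shape
    above = v >= thr[None, :]
    hit = above.any(axis=0)
    j = T - 1 - np.argmax(above[::-1], axis=0)  # last index at/above thr
    truncated = j == T - 1
    j0 = np.clip(j, 0, T - 2)
    v_here = np.take_along_axis(v, j0[None, :], axis=0)[0]
    v_next = np.take_along_axis(v, (j0 + 1)[None, :], axis=0)[0]
    denom = v_here - v_next
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (v_here - thr) / denom
    frac = np.where(denom > 0, frac, 0.0)
    out = t[j0] + frac * (t[j0 + 1] - t[j0])
    out = np.where(truncated, t[-1], out)
    return np.where(hit, out, np.nan), truncated & hit


def _slice_window(
    times: np.ndarray, window: Optional[Tuple[float, float]]
) -> slice:
    if window is None:
        return slice(None)
    t0, t1 = window
    i0 = int(np.searchsorted(times, t0, side="left"))
    i1 = int(np.searchsorted(times, t1, side="right"))
    if i1 - i0 < 3:
        raise ValueError(f"integration window {window} spans fewer than 3 frames")
    return slice(i0, i1)


@dataclass
class _StackMetrics:
    at: np.ndarray
    ttp: np.ndarray
    ttd: np.ndarray
    mtt: np.ndarray
    cbv: np.ndarray
    cbf: np.ndarray
    valid: np.ndarray
    truncated: np.ndarray


def _compute_stack(
    t: np.ndarray,
    v: np.ndarray,
    aif_integral: float,
    noise_floor: np.ndarray,
    cfg: KineticsConfig,
) -> _StackMetrics:
    """All six metrics on a windowed (T, N) stack."""
    peak = v.max(axis=0)
    peak_idx = np.argmax(v, axis=0)  # argmax ties -> earliest
    ttp = t[peak_idx]

    at = _up_crossing_into_peak(t, v, cfg.at_frac * peak, peak_idx)
    ttd, trunc_ttd = _last_down_crossing(t, v, cfg.ttd_frac * peak)
    t_up = _first_up_crossing(t, v, 0.5 * peak)
    t_down, trunc_fwhm = _last_down_crossing(t, v, 0.5 * peak)
    mtt = t_down - t_up

    area = np.trapezoid(v, t, axis=0)
    cbv_v = area / aif_integral
    with np.errstate(divide="ignore", invalid="ignore"):
        cbf_v = cbv_v / mtt

    valid = (peak > noise_floor) & (peak > 0) & (mtt > 0)
    truncated = (trunc_ttd | trunc_fwhm) & valid
    nan = np.nan
    return _StackMetrics(
        at=np.where(valid, at, nan),
        ttp=np.where(valid, ttp, nan),
        ttd=np.where(valid, ttd, nan),
        mtt=np.where(valid, mtt, nan),
        cbv=np.where(valid, cbv_v, nan),
        cbf=np.where(valid, cbf_v, nan),
        valid=valid,
        truncated=truncated,
    )


# --------------------------------------------------------------------------
# Single-curve API
# --------------------------------------------------------------------------


def _curve_cols(c: TimeIntensityCurve, window=None) -> Tuple[np.ndarray, np.ndarray]:
    sl = _slice_window(c.times, window)
    return c.times[sl], c.values[sl][:, None]


def arrival_time(
    c: TimeIntensityCurve, at_frac: float = 0.05, window=None
) -> float:
    """Time contrast first arrives: the ``at_frac`` x peak crossing on the
    rising edge into the peak (the first crossing, for single-pass curves)."""
    t, v = _curve_cols(c, window)
    peak = float(v.max())
    if peak <= 0:
        return float("nan")
    peak_idx = np.argmax(v, axis=0)
    return float(
        _up_crossing_into_peak(t, v, np.array([at_frac * peak]), peak_idx)[0]
    )


def time_to_peak(c: TimeIntensityCurve, window=None) -> float:
    """Time of the curve's global maximum (earliest sample on ties)."""
    t, v = _curve_cols(c, window)
    return float(t[int(np.argmax(v[:, 0]))])


def time_to_drain(
    c: TimeIntensityCurve, ttd_frac: float = 0.05, window=None
) -> Tuple[float, bool]:
    """Time contrast has left: last downward crossing of ``ttd_frac`` x peak.

    Returns ``(ttd, truncated)``; truncated means the curve never fell
    below the threshold before the window end.
    """
    t, v = _curve_cols(c, window)
    peak = float(v.max())
    if peak <= 0:
        return float("nan"), False
    ttd, trunc = _last_down_crossing(t, v, np.array([ttd_frac * peak]))
    return float(ttd[0]), bool(trunc[0])


def mean_transit_time(c: TimeIntensityCurve, window=None) -> Tuple[float, bool]:
    """FWHM of the curve: last-down minus first-up crossing of half peak."""
    t, v = _curve_cols(c, window)
    peak = float(v.max())
    if peak <= 0:
        return float("nan"), False
    t_up = _first_up_crossing(t, v, np.array([0.5 * peak]))[0]
    t_down, trunc = _last_down_crossing(t, v, np.array([0.5 * peak]))
    return float(t_down[0] - t_up), bool(trunc[0])


def cbv(c: TimeIntensityCurve, aif: AIFCurve, window=None) -> float:
    """Relative blood volume: area ratio of pixel curve to AIF curve.

    Both integrals use the trapezoid rule on each curve's own sample grid,
    over the same time window.
    """
    sl_c = _slice_window(c.times, window)
    sl_a = _slice_window(aif.curve.times, window)
    denom = float(np.trapezoid(aif.curve.values[sl_a], aif.curve.times[sl_a]))
    if denom <= 0:
        raise ValueError("AIF integral is zero — AIF line sees no contrast")
    return float(np.trapezoid(c.values[sl_c], c.times[sl_c])) / denom


def cbf(cbv_val: float, mtt_val: float) -> float:
    """Central volume theorem: CBF = CBV / MTT (1/s)."""
    if not mtt_val > 0:
        raise ValueError("CBF requires MTT > 0")
    return cbv_val / mtt_val


def compute_params(
    c: TimeIntensityCurve,
    aif: AIFCurve,
    window: Optional[Tuple[float, float]] = None,
    cfg: Optional[KineticsConfig] = None,
    noise_floor: float = 0.0,
) -> PerfusionParams:
    """All six metrics for one curve; invalid when the peak is in the noise.

    ``noise_floor`` is an absolute contrast threshold the peak must exceed
    (for map computation it is derived per pixel from the baseline SD).
    """
    cfg = cfg or KineticsConfig()
    sl_c = _slice_window(c.times, window)
    sl_a = _slice_window(aif.curve.times, window)
    denom = float(np.trapezoid(aif.curve.values[sl_a], aif.curve.times[sl_a]))
    if denom <= 0:
        raise ValueError("AIF integral is zero — AIF line sees no contrast")
    m = _compute_stack(
        c.times[sl_c],
        c.values[sl_c][:, None],
        denom,
        np.array([noise_floor]),
        cfg,
    )
    return PerfusionParams(
        at_s=float(m.at[0]),
        ttp_s=float(m.ttp[0]),
        ttd_s=float(m.ttd[0]),
        mtt_s=float(m.mtt[0]),
        cbv=float(m.cbv[0]),
        cbf=float(m.cbf[0]),
        valid=bool(m.valid[0]),
        truncated=bool(m.truncated[0]),
    )


def compute_maps(
    cs: ContrastSequence,
    aif: AIFCurve,
    window: Optional[Tuple[float, float]] = None,
    cfg: Optional[KineticsConfig] = None,
) -> PerfusionMapSet:
    """Voxel-wise perfusion maps over the whole frame.

    Applies the single-curve definitions to every pixel in one vectorized
    pass.  A pixel is valid only if its peak contrast exceeds
    ``noise_floor_k`` x its baseline-window SD and its FWHM is positive;
    invalid pixels are NaN in every map.
    """
    cfg = cfg or KineticsConfig()
    T, H, W = cs.contrast.shape
    sl = _slice_window(cs.times, window)
    t = cs.times[sl]
    v = cs.contrast[sl].reshape(len(t), H * W)

    sl_a = _slice_window(aif.curve.times, window)
    denom = float(np.trapezoid(aif.curve.values[sl_a], aif.curve.times[sl_a]))
    if denom <= 0:
        raise ValueError("AIF integral is zero — AIF line sees no contrast")

    if cs.baseline_sd is not None:
        noise_floor = cfg.noise_floor_k * cs.baseline_sd.reshape(-1)
    else:
        noise_floor = np.zeros(H * W)

    m = _compute_stack(t, v, denom, noise_floor, cfg)
    shape = (H, W)
    return PerfusionMapSet(
        maps={
            Metric.AT: m.at.reshape(shape),
            Metric.TTP: m.ttp.reshape(shape),
            Metric.TTD: m.ttd.reshape(shape),
            Metric.MTT: m.mtt.reshape(shape),
            Metric.CBV: m.cbv.reshape(shape),
            Metric.CBF: m.cbf.reshape(shape),
        },
        validity_mask=m.valid.reshape(shape),
        times_window=(float(t[0]), float(t[-1])),
        view=cs.view,
        truncated_mask=m.truncated.reshape(shape),
        meta={
            "at_frac": cfg.at_frac,
            "ttd_frac": cfg.ttd_frac,
            "noise_floor_k": cfg.noise_floor_k,
            "aif_integral": denom,
        },
    )
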
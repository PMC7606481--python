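"""Domain types for DSA perfusion angiography.

The pipeline operates on 2D digital-subtraction-angiography (DSA) cine
sequences: a stack of subtracted X-ray frames with a time axis.  Contrast
transit through each pixel is summarised by six bolus-tracking metrics:

* AT  — arrival time: when contrast first reaches the pixel (s)
* TTP — time to peak of the contrast curve (s)
* TTD — time to drain: when contrast has left the pixel (s)
* MTT — mean transit time, operationalised as the full width at half
  maximum (FWHM) of the contrast curve (s)
* CBV — relative blood volume: area under the pixel curve divided by the
  area under the arterial-input-function (AIF) curve (dimensionless)
* CBF — relative blood flow via the central volume theorem, CBV/MTT (1/s)

All pixel coordinates are 0-based ``(row, col)``; masks and maps share the
frame raster exactly.  Invalid pixels carry NaN (never 0, so an invalid
pixel can never masquerade as "instant arrival").
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "View",
    "Polarity",
    "Metric",
    "TIMING_METRICS",
    "FLOW_METRICS",
    "FrameSequence",
    "ContrastSequence",
    "TimeIntensityCurve",
    "AIFCurve",
    "PerfusionParams",
    "PerfusionMapSet",
    "ROIMask",
    "MetricDistributionSummary",
    "TerritoryComparison",
    "MetricComparison",
    "QCCheck",
    "QCReport",
    "QCTolerances",
    "validate_pair",
]


class View(str, enum.Enum):
    """Biplane angiography projection."""

    AP = "AP"
    LAT = "LAT"
    UNKNOWN = "UNKNOWN"


class Polarity(str, enum.Enum):
    """Whether iodinated contrast renders dark or bright in the frames.

    Standard DSA subtraction renders contrast dark (``DARK_CONTRAST``);
    exported stacks may be inverted.
    """

    DARK_CONTRAST = "DARK_CONTRAST"
    BRIGHT_CONTRAST = "BRIGHT_CONTRAST"


class Metric(str, enum.Enum):
    AT = "AT"
    TTP = "TTP"
    TTD = "TTD"
    MTT = "MTT"
    CBV = "CBV"
    CBF = "CBF"


#: Metrics measured in seconds, where *lower* means better perfusion.
TIMING_METRICS: Tuple[Metric, ...] = (Metric.AT, Metric.TTP, Metric.TTD, Metric.MTT)
#: Metrics where *higher* means better perfusion.
FLOW_METRICS: Tuple[Metric, ...] = (Metric.CBV, Metric.CBF)


class TerritoryLabel(str, enum.Enum):
    MCA = "MCA"
    ACA = "ACA"
    PCA = "PCA"
    VERTEBROBASILAR = "VERTEBROBASILAR"
    CUSTOM = "CUSTOM"


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-D, got shape {arr.shape}")
    return arr


def _check_times(times: np.ndarray) -> None:
    if times.ndim != 1:
        raise ValueError("times must be a 1-D vector")
    if np.any(~np.isfinite(times)):
        raise ValueError("times must be finite")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")


@dataclass
class FrameSequence:
    """A raw DSA intensity stack with a time axis.

    Parameters
    ----------
    frames
        ``(T, H, W)`` scalar array, frame-major, arbitrary intensity units.
    times
        Length-T vector of frame midpoint times in seconds, strictly
        increasing.  Acquisition-relative: the first entry may be nonzero.
    view
        Projection (AP / LAT / UNKNOWN).
    pixel_spacing_mm
        Optional (row, col) physical pixel spacing; used as a magnification
        proxy in pre/post QC.
    source_id
        Free-text provenance.
    """

    frames: np.ndarray
    times: np.ndarray
    view: View = View.UNKNOWN
    pixel_spacing_mm: Optional[Tuple[float, float]] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = _as_float_array(self.frames, "frames", 3)
        self.times = np.asarray(self.times, dtype=np.float64)
        _check_times(self.times)
        if self.frames.shape[0] < 3:
            raise ValueError("a frame sequence needs at least 3 frames")
        if self.frames.shape[0] != self.times.shape[0]:
            raise ValueError(
                f"{self.frames.shape[0]} frames but {self.times.shape[0]} times"
            )
        self.view = View(self.view)
        if self.pixel_spacing_mm is not None:
            ps = tuple(float(v) for v in self.pixel_spacing_mm)
            if len(ps) != 2 or any(v <= 0 for v in ps):
                raise ValueError("pixel_spacing_mm must be a positive pair")
            self.pixel_spacing_mm = ps

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]


@dataclass
class ContrastSequence:
    """Baseline-corrected, polarity-resolved contrast-proxy stack C_{x,y}(t).

    ``contrast`` is clamped nonnegative after baseline subtraction.
    ``baseline_sd`` holds the per-pixel standard deviation of the *raw*
    intensity over the baseline window, used downstream as a noise floor.
    """

    contrast: np.ndarray
    times: np.ndarray
    baseline_frames: int
    polarity: Polarity = Polarity.DARK_CONTRAST
    view: View = View.UNKNOWN
    baseline_sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.contrast = _as_float_array(self.contrast, "contrast", 3)
        self.times = np.asarray(self.times, dtype=np.float64)
        _check_times(self.times)
        T = self.contrast.shape[0]
        if self.times.shape[0] != T:
            raise ValueError("times length must match number of frames")
        if np.any(self.contrast < 0):
            raise ValueError("contrast must be nonnegative (clamp on construction)")
        if not (1 <= int(self.baseline_frames) < T):
            raise ValueError("baseline_frames must satisfy 1 <= n < T")
        self.baseline_frames = int(self.baseline_frames)
        self.polarity = Polarity(self.polarity)
        self.view = View(self.view)
        if self.baseline_sd is not None:
            self.baseline_sd = _as_float_array(self.baseline_sd, "baseline_sd", 2)
            if self.baseline_sd.shape != self.contrast.shape[1:]:
                raise ValueError("baseline_sd shape must match frame shape")

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.contrast.shape[1:]  # type: ignore[return-value]


@dataclass
class TimeIntensityCurve:
    """A single pixel's (or ROI-averaged) contrast-vs-time curve."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_times(self.times)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("curve values must be nonnegative")


@dataclass
class AIFCurve:
    """Arterial input function C_AIF(t) with line-ROI provenance.

    The AIF is the averaged contrast curve along a user-drawn line spanning
    the width of the injected vessel.
    """

    curve: TimeIntensityCurve
    endpoints_px: Tuple[Tuple[float, float], Tuple[float, float]]
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if float(np.max(self.curve.values)) <= 0:
            raise ValueError("AIF curve must have a strictly positive peak")


@dataclass
class PerfusionParams:
    """Bolus-tracking metrics for a single curve.

    When ``valid`` is False every numeric field is NaN.
    """

    at_s: float
    ttp_s: float
    ttd_s: float
    mtt_s: float
    cbv: float
    cbf: float
    valid: bool
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.valid:
            if not (self.at_s <= self.ttp_s <= self.ttd_s):
                raise ValueError("valid params require AT <= TTP <= TTD")
            if not self.mtt_s > 0:
                raise ValueError("valid params require MTT > 0")
            if self.cbv < 0:
                raise ValueError("valid params require CBV >= 0")
        else:
            for name in ("at_s", "ttp_s", "ttd_s", "mtt_s", "cbv", "cbf"):
                if not math.isnan(getattr(self, name)):
                    raise ValueError("invalid params must carry NaN fields")


@dataclass
class PerfusionMapSet:
    """Six co-registered scalar maps plus a validity mask.

    Invalid pixels are NaN in every metric map; ``validity_mask`` is False
    wherever any metric is NaN.  ``times_window`` records the global signal
    integration interval used for every pixel.
    """

    maps: dict  # Metric -> (H, W) float array
    validity_mask: np.ndarray
    times_window: Tuple[float, float]
    view: View = View.UNKNOWN
    truncated_mask: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.maps = {Metric(k): _as_float_array(v, str(k), 2) for k, v in self.maps.items()}
        if set(self.maps) != set(Metric):
            raise ValueError("maps must contain exactly the six perfusion metrics")
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) != 1:
            raise ValueError("all metric maps must share one shape")
        self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
        if self.validity_mask.shape != next(iter(shapes)):
            raise ValueError("validity_mask shape must match the maps")
        self.view = View(self.view)
        for m, arr in self.maps.items():
            if np.any(np.isnan(arr[self.validity_mask])):
                raise ValueError(f"{m.value} map has NaN on pixels marked valid")
            if np.any(~np.isnan(arr[~self.validity_mask])):
                raise ValueError(f"{m.value} map has finite values on invalid pixels")

    def __getitem__(self, metric) -> np.ndarray:
        return self.maps[Metric(metric)]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.validity_mask.shape  # type: ignore[return-value]


@dataclass
class ROIMask:
    """A vascular-territory region of interest on the frame raster."""

    mask: np.ndarray
    label: TerritoryLabel = TerritoryLabel.CUSTOM
    view: View = View.UNKNOWN
    name: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI mask must contain at least one pixel")
        self.label = TerritoryLabel(self.label)
        self.view = View(self.view)
        if not self.name:
            self.name = self.label.value


@dataclass
class MetricDistributionSummary:
    """Distribution of one metric over the valid pixels of one ROI.

    ``sd`` uses the sample (n-1) convention; ``skew`` and ``kurtosis`` are
    the adjusted Fisher-Pearson estimators, with kurtosis reported as
    *excess* kurtosis (normal = 0).  Conventions are recorded in
    serialised metadata because they are not universal.
    """

    metric: Metric
    n_valid_px: int
    mean: float
    median: float
    sd: float
    skew: float
    kurtosis: float
    kurtosis_convention: str = "excess (Fisher, normal=0), adjusted estimator"

    def __post_init__(self) -> None:
        self.metric = Metric(self.metric)
        if self.n_valid_px < 1:
            raise ValueError("summary requires >= 1 valid pixel")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass
class MetricComparison:
    """Pre/post change for one metric over one ROI."""

    metric: Metric
    delta_mean: float
    ci95_halfwidth: float
    p_value: float
    significant: bool
    n_pre: int
    n_post: int

    def __post_init__(self) -> None:
        self.metric = Metric(self.metric)
        if not math.isnan(self.ci95_halfwidth) and self.ci95_halfwidth < 0:
            raise ValueError("ci95_halfwidth must be >= 0")


@dataclass
class TerritoryComparison:
    """Pre/post deltas for every metric over one ROI / view."""

    roi_label: str
    view: View
    alpha: float
    metrics: dict  # Metric -> MetricComparison

    def __post_init__(self) -> None:
        self.view = View(self.view)
        self.metrics = {Metric(k): v for k, v in self.metrics.items()}
        for mc in self.metrics.values():
            want = bool(mc.p_value < self.alpha) if math.isfinite(mc.p_value) else False
            if mc.significant != want:
                raise ValueError("significant flag inconsistent with p < alpha")


# --------------------------------------------------------------------------
# Pre/post quality control
# --------------------------------------------------------------------------


@dataclass
class QCTolerances:
    """Thresholds for the pre/post pairing checks.

    motion_px
        Maximum acceptable median per-frame rigid translation (pixels)
        estimated by phase correlation on the contrast-free baseline
        frames.  The source study excluded "significant motion" without
        quantifying it; 2 px is the configurable default.
    spacing_rtol
        Relative tolerance for pixel-spacing agreement (magnification
        proxy).
    washout_frac
        The territory-mean contrast curve must fall back below this
        fraction of its peak before the last frame for the run to count as
        having captured the full arterial/capillary/venous transit.
    """

    motion_px: float = 2.0
    spacing_rtol: float = 0.01
    washout_frac: float = 0.5
    baseline_frames: int = 2


@dataclass
class QCCheck:
    name: str
    passed: bool
    score: float
    detail: str = ""


@dataclass
class QCReport:
    checks: dict  # name -> QCCheck

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks.values())

    def failures(self) -> list:
        return [c.name for c in self.checks.values() if not c.passed]

    def to_json(self) -> str:
        payload = {
            name: {"passed": bool(c.passed), "score": float(c.score), "detail": c.detail}
            for name, c in self.checks.items()
        }
        payload["all_passed"] = self.passed
        return json.dumps(payload, indent=2)


def _motion_score(frames: np.ndarray, n_baseline: int) -> float:
    """Median rigid-translation magnitude between consecutive baseline frames.

    Uses cross-correlation (unwhitened, mean-subtracted, Hann-windowed) at
    10x subpixel upsampling.  Spectral whitening is avoided because
    subtraction residue is low-frequency; whitening amplifies numerical
    noise there and loses the peak.  The baseline (pre-contrast) window is
    used deliberately: contrast arrival changes frame intensity and would
    confound whole-sequence registration.  Featureless (near-constant)
    frame pairs contribute zero shift.
    """
    from scipy.signal.windows import hann
    from skimage.registration import phase_cross_correlation

    n = max(2, int(n_baseline))
    n = min(n, frames.shape[0])
    H, W = frames.shape[1:]
    win = np.outer(hann(H), hann(W))
    mags = []
    for i in range(n - 1):
        a, b = frames[i], frames[i + 1]
        if np.std(a) < 1e-12 or np.std(b) < 1e-12:
            mags.append(0.0)
            continue
        shift, _, _ = phase_cross_correlation(
            (a - a.mean()) * win,
            (b - b.mean()) * win,
            upsample_factor=10,
            normalization=None,
        )
        mags.append(float(np.hypot(*shift)))
    return float(np.median(mags)) if mags else 0.0


def _washout_ok(seq: FrameSequence, frac: float, baseline_frames: int) -> Tuple[bool, float]:
    """Check that the mean contrast curve returns below ``frac`` x peak."""
    from . import contrast as _contrast

    cs = _contrast.to_contrast(seq, baseline_frames=baseline_frames)
    g = cs.contrast.reshape(cs.contrast.shape[0], -1).mean(axis=1)
    peak = float(g.max())
    if peak <= 0:
        return False, float("inf")
    tail = float(g[-1]) / peak
    return tail < frac, tail


def validate_pair(
    pre: FrameSequence,
    post: FrameSequence,
    tol: Optional[QCTolerances] = None,
) -> QCReport:
    """Automated pre/post pairing QC, mirroring the study exclusion rules.

    Checks: (a) same projection view; (b) same frame shape and, when
    recorded, pixel spacing within ``spacing_rtol`` (magnification proxy);
    (c) motion score below ``motion_px`` in both sequences; (d) each run
    captures the full contrast transit (mean curve falls back below
    ``washout_frac`` of its peak).

    Mismatched frame *counts* are not an error: the two runs are analysed
    on their own time axes.
    """
    tol = tol or QCTolerances()
    checks = {}

    checks["view_match"] = QCCheck(
        name="view_match",
        passed=pre.view == post.view,
        score=float(pre.view == post.view),
        detail=f"pre={pre.view.value} post={post.view.value}",
    )

    shape_ok = pre.frame_shape == post.frame_shape
    spacing_ok = True
    detail = f"pre={pre.frame_shape} post={post.frame_shape}"
    if pre.pixel_spacing_mm is not None and post.pixel_spacing_mm is not None:
        a = np.asarray(pre.pixel_spacing_mm)
        b = np.asarray(post.pixel_spacing_mm)
        spacing_ok = bool(np.all(np.abs(a - b) <= tol.spacing_rtol * np.abs(a)))
        detail += f" spacing pre={tuple(a)} post={tuple(b)}"
    checks["magnification_match"] = QCCheck(
        name="magnification_match",
        passed=shape_ok and spacing_ok,
        score=float(shape_ok and spacing_ok),
        detail=detail,
    )

    for tag, seq in (("pre", pre), ("post", post)):
        score = _motion_score(seq.frames, tol.baseline_frames)
        checks[f"motion_{tag}"] = QCCheck(
            name=f"motion_{tag}",
            passed=score <= tol.motion_px,
            score=score,
            detail=f"median baseline-frame translation {score:.3f} px "
            f"(threshold {tol.motion_px} px)",
        )

    for tag, seq in (("pre", pre), ("post", post)):
        ok, tail = _washout_ok(seq, tol.washout_frac, tol.baseline_frames)
        checks[f"full_transit_{tag}"] = QCCheck(
            name=f"full_transit_{tag}",
            passed=ok,
            score=tail,
            detail=f"final mean contrast = {tail:.3f} x peak "
            f"(threshold {tol.washout_frac})",
        )

    return QCReport(checks=checks)
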
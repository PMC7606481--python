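"""Reading and writing the formats the pipeline touches.

Sequences come in as DICOM multi-frame files, directories of single-frame
DICOMs, or directories of ordered TIFF/PNG frames; they go out as 32-bit
float TIFF stacks with a JSON timing sidecar.  ROI masks come in as
rasters (nonzero = in-ROI) or as polygons in a small JSON dialect::

    {"label": "MCA", "view": "AP", "rings": [[[r, c], ...], ...]}

Polygon rings are closed pixel-coordinate loops; rasterization uses
even-odd fill with center-inclusive boundaries (a pixel is in-ROI when its
integer center lies inside or on the polygon).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np

from .model import (
    FrameSequence,
    Metric,
    MetricDistributionSummary,
    PerfusionMapSet,
    ROIMask,
    TerritoryComparison,
    TerritoryLabel,
    View,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_sequence",
    "write_sequence",
    "read_mask",
    "read_mask_file",
    "rasterize_polygons",
    "write_maps",
    "read_maps",
    "write_tables",
]

_IMAGE_EXTS = {".png", ".tif", ".tiff"}


def _times_from_override(T: int, override) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(override, dtype=float))
    if arr.size == 1:  # scalar dt
        return float(arr[0]) * np.arange(T)
    if arr.size != T:
        raise ValueError(f"times override has {arr.size} entries for {T} frames")
    return arr


def _default_times(T: int) -> np.ndarray:
    logger.warning("no frame timing available; assuming uniform 1 s spacing")
    warnings.warn("no frame timing available; assuming uniform 1 s spacing", stacklevel=3)
    return np.arange(T, dtype=float)


def _view_from_dicom(ds) -> View:
    vp = str(getattr(ds, "ViewPosition", "") or "").upper()
    if vp in ("AP", "PA"):
        return View.AP
    if vp in ("LAT", "LL", "RL", "LATERAL"):
        return View.LAT
    return View.UNKNOWN


def _maybe_invert(ds, frames: np.ndarray) -> np.ndarray:
    # MONOCHROME1: low pixel value = bright; flip to the MONOCHROME2 convention.
    if str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2")) == "MONOCHROME1":
        return frames.max() - frames
    return frames


def _read_dicom_multiframe(path: Path, times_override) -> FrameSequence:
    import pydicom

    ds = pydicom.dcmread(str(path))
    frames = np.asarray(ds.pixel_array, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    frames = _maybe_invert(ds, frames)
    T = frames.shape[0]
    if times_override is not None:
        times = _times_from_override(T, times_override)
    elif getattr(ds, "FrameTimeVector", None) is not None:
        ftv = np.asarray(ds.FrameTimeVector, dtype=float)
        if ftv.size != T:
            raise ValueError("FrameTimeVector length does not match frame count")
        times = np.cumsum(ftv) / 1000.0  # ms increments -> cumulative s
    elif getattr(ds, "FrameTime", None):
        times = float(ds.FrameTime) / 1000.0 * np.arange(T)
    else:
        times = _default_times(T)
    spacing = getattr(ds, "PixelSpacing", None) or getattr(
        ds, "ImagerPixelSpacing", None
    )
    return FrameSequence(
        frames=frames,
        times=times,
        view=_view_from_dicom(ds),
        pixel_spacing_mm=tuple(float(v) for v in spacing) if spacing else None,
        source_id=str(path),
    )


def _read_dicom_series(paths: List[Path], times_override) -> FrameSequence:
    import pydicom

    dss = [pydicom.dcmread(str(p)) for p in paths]
    dss.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    frames = [
        _maybe_invert(d, np.asarray(d.pixel_array, dtype=float)) for d in dss
    ]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"heterogeneous frame shapes in series: {sorted(shapes)}")
    stack = np.stack(frames)
    T = stack.shape[0]
    if times_override is not None:
        times = _times_from_override(T, times_override)
    else:
        ft = getattr(dss[0], "FrameTime", None)
        times = float(ft) / 1000.0 * np.arange(T) if ft else _default_times(T)
    spacing = getattr(dss[0], "PixelSpacing", None)
    return FrameSequence(
        frames=stack,
        times=times,
        view=_view_from_dicom(dss[0]),
        pixel_spacing_mm=tuple(float(v) for v in spacing) if spacing else None,
        source_id=str(paths[0].parent),
    )


def _read_image_dir(paths: List[Path], times_override) -> FrameSequence:
    import imageio.v3 as iio

    paths = sorted(paths, key=lambda p: p.name)
    frames = []
    for p in paths:
        img = np.asarray(iio.imread(p), dtype=float)
        if img.ndim == 3:  # collapse RGB(A) to luminance
            img = img[..., :3].mean(axis=-1)
        frames.append(img)
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"heterogeneous frame shapes: {sorted(shapes)}")
    stack = np.stack(frames)
    T = stack.shape[0]
    times = (
        _times_from_override(T, times_override)
        if times_override is not None
        else _default_times(T)
    )
    return FrameSequence(frames=stack, times=times, source_id=str(paths[0].parent))


def read_sequence(
    path: Union[str, Path],
    times_override=None,
    view: Optional[View] = None,
) -> FrameSequence:
    """Load a DSA frame sequence from disk.

    ``path`` may be a DICOM multi-frame file, a directory of single-frame
    DICOMs (ordered by InstanceNumber), a directory of TIFF/PNG frames
    (ordered lexicographically), or a TIFF stack written by
    :func:`write_sequence` (whose JSON sidecar restores exact timing).
    ``times_override`` may be a scalar frame interval in seconds or a full
    length-T vector; it wins over file metadata.  Missing timing falls back
    to a uniform 1 s spacing with a warning, never silently.
    """
    path = Path(path)
    if path.is_dir():
        dicoms = sorted(path.glob("*.dcm"))
        if dicoms:
            seq = _read_dicom_series(dicoms, times_override)
        else:
            imgs = [p for p in sorted(path.iterdir()) if p.suffix.lower() in _IMAGE_EXTS]
            if not imgs:
                raise FileNotFoundError(f"no DICOM or image frames in {path}")
            seq = _read_image_dir(imgs, times_override)
    elif path.suffix.lower() in (".tif", ".tiff"):
        seq = _read_tiff_stack(path, times_override)
    else:
        seq = _read_dicom_multiframe(path, times_override)
    if view is not None:
        seq.view = View(view)
    return seq


def _read_tiff_stack(path: Path, times_override) -> FrameSequence:
    import tifffile

    frames = np.asarray(tifffile.imread(str(path)), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    T = frames.shape[0]
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if times_override is not None:
        times = _times_from_override(T, times_override)
    elif "times_s" in meta:
        times = np.asarray(meta["times_s"], dtype=float)
    else:
        times = _default_times(T)
    return FrameSequence(
        frames=frames,
        times=times,
        view=View(meta.get("view", "UNKNOWN")),
        pixel_spacing_mm=tuple(meta["pixel_spacing_mm"]) if meta.get("pixel_spacing_mm") else None,
        source_id=str(path),
    )


def write_sequence(seq: FrameSequence, path: Union[str, Path]) -> Path:
    """Write a sequence as a float32 TIFF stack plus a JSON timing sidecar."""
    import tifffile

    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        path = path.with_suffix(".tif")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), seq.frames.astype(np.float32))
    meta = {
        "times_s": seq.times.tolist(),
        "view": seq.view.value,
        "pixel_spacing_mm": list(seq.pixel_spacing_mm) if seq.pixel_spacing_mm else None,
        "source_id": seq.source_id,
    }
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


# --------------------------------------------------------------------------
# ROI masks
# --------------------------------------------------------------------------


def rasterize_polygons(rings: Sequence[Sequence[Sequence[float]]], shape) -> np.ndarray:
    """Even-odd rasterization of closed (row, col) rings on ``shape``.

    A pixel is in-ROI when its center lies inside (or on the boundary of)
    an odd number of rings.  Zero-area rings are rejected.
    """
    import shapely

    H, W = shape
    mask = np.zeros((H, W), dtype=bool)
    for ring in rings:
        pts = np.asarray(ring, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
            raise ValueError("each ring needs >= 3 (row, col) points")
        poly = shapely.Polygon([(c, r) for r, c in pts])  # shapely is (x, y)
        if poly.area == 0:
            raise ValueError("degenerate polygon ring with zero area")
        minx, miny, maxx, maxy = poly.bounds
        c0, c1 = max(0, int(np.floor(minx))), min(W - 1, int(np.ceil(maxx)))
        r0, r1 = max(0, int(np.floor(miny))), min(H - 1, int(np.ceil(maxy)))
        if c1 < c0 or r1 < r0:
            continue
        rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        pts_xy = shapely.points(cc.ravel().astype(float), rr.ravel().astype(float))
        inside = shapely.covers(poly, pts_xy).reshape(rr.shape)
        mask[r0 : r1 + 1, c0 : c1 + 1] ^= inside  # even-odd across rings
    if not mask.any():
        raise ValueError("polygon rasterization produced an empty mask")
    return mask


def read_mask(spec: dict, shape) -> ROIMask:
    """Build an ROIMask from an in-memory polygon spec (the JSON dialect)."""
    rings = spec["rings"]
    mask = rasterize_polygons(rings, shape)
    label_txt = str(spec.get("label", "CUSTOM")).upper()
    try:
        label = TerritoryLabel(label_txt)
    except ValueError:
        label = TerritoryLabel.CUSTOM
    return ROIMask(
        mask=mask,
        label=label,
        view=View(spec.get("view", "UNKNOWN")),
        name=spec.get("label", label.value),
    )


def read_mask_file(path: Union[str, Path], shape) -> ROIMask:
    """Load an ROI from a polygon JSON file or a raster image (nonzero=in)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_mask(json.loads(path.read_text()), shape)
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3].max(axis=-1)
    if img.shape != tuple(shape):
        raise ValueError(f"raster mask shape {img.shape} != frame shape {tuple(shape)}")
    return ROIMask(mask=img > 0, name=path.stem)


# --------------------------------------------------------------------------
# Maps and tables
# --------------------------------------------------------------------------


def write_maps(maps: PerfusionMapSet, out_dir: Union[str, Path], prefix: str = "") -> Path:
    """One float32 TIFF per metric + validity-mask PNG + JSON metadata."""
    import imageio.v3 as iio
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for metric, arr in maps.maps.items():
        tifffile.imwrite(
            str(out_dir / f"{prefix}{metric.value}.tif"), arr.astype(np.float32)
        )
    iio.imwrite(
        out_dir / f"{prefix}validity.png",
        (maps.validity_mask.astype(np.uint8) * 255),
    )
    meta = {
        "times_window_s": list(maps.times_window),
        "view": maps.view.value,
        **{k: v for k, v in maps.meta.items()},
    }
    (out_dir / f"{prefix}maps_meta.json").write_text(json.dumps(meta, indent=2))
    return out_dir


def read_maps(out_dir: Union[str, Path], prefix: str = "") -> PerfusionMapSet:
    """Inverse of :func:`write_maps`."""
    import imageio.v3 as iio
    import tifffile

    out_dir = Path(out_dir)
    maps = {
        m: np.asarray(tifffile.imread(str(out_dir / f"{prefix}{m.value}.tif")), dtype=float)
        for m in Metric
    }
    validity = np.asarray(iio.imread(out_dir / f"{prefix}validity.png")) > 0
    meta = json.loads((out_dir / f"{prefix}maps_meta.json").read_text())
    return PerfusionMapSet(
        maps=maps,
        validity_mask=validity,
        times_window=tuple(meta["times_window_s"]),
        view=View(meta.get("view", "UNKNOWN")),
        meta={k: v for k, v in meta.items() if k not in ("times_window_s", "view")},
    )


def write_tables(
    summaries: dict,
    comparisons: Sequence[TerritoryComparison],
    out_dir: Union[str, Path],
) -> Path:
    """CSV + JSON outputs of the territory statistics.

    ``summaries`` maps (study, roi_name) -> list of summaries.  The
    comparison CSV has one row per (roi, view, metric) with delta_mean,
    ci95_halfwidth, p_value and significance, mirroring a pre/post
    treatment-effect table.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for (study, roi_name), summs in summaries.items():
        for s in summs:
            rows.append(
                {
                    "study": study,
                    "roi": roi_name,
                    "metric": s.metric.value,
                    "n_valid_px": s.n_valid_px,
                    "mean": s.mean,
                    "median": s.median,
                    "sd": s.sd,
                    "skew": s.skew,
                    "kurtosis": s.kurtosis,
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "roi_summaries.csv", index=False)

    comp_rows = []
    for comp in comparisons:
        for metric, mc in comp.metrics.items():
            comp_rows.append(
                {
                    "roi": comp.roi_label,
                    "view": comp.view.value,
                    "metric": metric.value,
                    "delta_mean": mc.delta_mean,
                    "ci95_halfwidth": mc.ci95_halfwidth,
                    "p_value": mc.p_value,
                    "significant": mc.significant,
                    "n_pre": mc.n_pre,
                    "n_post": mc.n_post,
                }
            )
    pd.DataFrame(comp_rows).to_csv(out_dir / "pre_post_comparison.csv", index=False)

    meta = {
        "sd_convention": "sample (ddof=1)",
        "kurtosis_convention": "excess (Fisher, normal=0), adjusted estimator",
        "skew_convention": "adjusted Fisher-Pearson",
        "test": "Welch unequal-variance two-sample t-test",
    }
    (out_dir / "tables_meta.json").write_text(json.dumps(meta, indent=2))
    return out_dir
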
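"""End-to-end orchestration: QC -> contrast -> window -> AIF -> maps -> stats.

These functions are the programmatic counterpart of the CLI commands; they
take in-memory domain objects so the CLI stays a thin shell over them.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import bolus_kinetics, contrast, aif_extraction, territory_analysis
from .model import (
    AIFCurve,
    FrameSequence,
    Metric,
    PerfusionMapSet,
    Polarity,
    QCReport,
    QCTolerances,
    ROIMask,
    TerritoryComparison,
    validate_pair,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "StudyResult", "PairResult", "analyze_single", "analyze_pair"]


@dataclass
class AnalysisConfig:
    """Every tunable of the pipeline in one place (YAML-mappable)."""

    polarity: Polarity = Polarity.DARK_CONTRAST
    baseline_frames: int = 2
    enh_frac: float = 0.05
    arrest_frac: float = 0.01
    kinetics: bolus_kinetics.KineticsConfig = field(
        default_factory=bolus_kinetics.KineticsConfig
    )
    qc: QCTolerances = field(default_factory=QCTolerances)
    alpha: float = 0.05
    paired: bool = False
    subsample_step: int = 1


@dataclass
class StudyResult:
    maps: PerfusionMapSet
    aif: AIFCurve
    window: Tuple[float, float]
    summaries: Dict[str, list]  # roi name -> list of MetricDistributionSummary
    timings_s: Dict[str, float]


@dataclass
class PairResult:
    qc: QCReport
    pre: StudyResult
    post: StudyResult
    comparisons: List[TerritoryComparison]


class QCFailure(RuntimeError):
    """Raised when pre/post QC fails and the run is not forced."""

    def __init__(self, report: QCReport):
        super().__init__(f"QC failed: {', '.join(report.failures())}")
        self.report = report


def analyze_single(
    seq: FrameSequence,
    aif_line: Tuple[Tuple[float, float], Tuple[float, float]],
    rois: Sequence[ROIMask] = (),
    cfg: Optional[AnalysisConfig] = None,
) -> StudyResult:
    """Maps and ROI summaries for one study."""
    cfg = cfg or AnalysisConfig()
    timings: Dict[str, float] = {}

    t0 = time.perf_counter()
    cs = contrast.to_contrast(seq, cfg.polarity, cfg.baseline_frames)
    timings["contrast"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    window = contrast.detect_window(cs, cfg.enh_frac, cfg.arrest_frac)
    timings["window"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    aif = aif_extraction.extract_aif(cs, aif_line[0], aif_line[1])
    timings["aif"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    maps = bolus_kinetics.compute_maps(cs, aif, window, cfg.kinetics)
    timings["maps"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    summaries = {
        roi.name: territory_analysis.summarize_roi(maps, roi) for roi in rois
    }
    timings["summaries"] = time.perf_counter() - t0

    for stage, dt in timings.items():
        logger.info("stage %-10s %.3f s", stage, dt)
    return StudyResult(maps=maps, aif=aif, window=window, summaries=summaries, timings_s=timings)


def analyze_pair(
    pre: FrameSequence,
    post: FrameSequence,
    aif_line: Tuple[Tuple[float, float], Tuple[float, float]],
    rois: Sequence[ROIMask] = (),
    cfg: Optional[AnalysisConfig] = None,
    force: bool = False,
) -> PairResult:
    """Full pre/post comparison.

    Runs pairing QC first; a failed check aborts with :class:`QCFailure`
    unless ``force`` is set, in which case the failures are logged and the
    analysis proceeds.
    """
    cfg = cfg or AnalysisConfig()
    report = validate_pair(pre, post, cfg.qc)
    if not report.passed:
        if not force:
            raise QCFailure(report)
        logger.warning("QC failures overridden by --force: %s", report.failures())

    pre_res = analyze_single(pre, aif_line, rois, cfg)
    post_res = analyze_single(post, aif_line, rois, cfg)

    comparisons = [
        territory_analysis.compare_pre_post(
            pre_res.maps,
            post_res.maps,
            roi,
            alpha=cfg.alpha,
            paired=cfg.paired,
            subsample_step=cfg.subsample_step,
        )
        for roi in rois
    ]
    return PairResult(qc=report, pre=pre_res, post=post_res, comparisons=comparisons)
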
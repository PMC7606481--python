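"""Digital flow phantom: DSA-like sequences with known ground-truth kinetics.

Each territory is a polygon whose pixels share a gamma-variate contrast
curve — the canonical single-pass indicator-dilution transit shape.  The
peak-normalized parameterization

    C(t) = A * ((t - t0) / (alpha*beta))**alpha * exp(alpha - (t - t0)/beta)

for t > t0 peaks at exactly ``A`` at ``t = t0 + alpha*beta``, so amplitude
and timing are independently controllable.  Frames are rendered in the
DARK_CONTRAST convention around a baseline of 100 intensity units, with a
static smooth background texture (emulating the bone/soft-tissue residue
of real subtraction imaging — this is what motion QC registers on),
additive Gaussian noise, and optional rigid per-frame shifts.

Ground truth carries the analytic TTP plus AT/TTD/MTT/CBV/CBF computed by
a dense-grid (dt = 1e-4 s) brute-force scan of the analytic curves — an
oracle deliberately independent of the :mod:`dsaperf.bolus_kinetics`
implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import FrameSequence, View
from .dsa_io import rasterize_polygons

__all__ = [
    "GammaVariate",
    "TerritorySpec",
    "VesselSpec",
    "PhantomSpec",
    "GroundTruth",
    "gamma_variate",
    "oracle_metrics",
    "generate",
    "make_pre_post",
    "default_pre_post_spec",
]

BASELINE = 100.0


@dataclass
class GammaVariate:
    """Peak-normalized gamma-variate bolus: peak A at t0 + alpha*beta."""

    amplitude: float = 30.0
    alpha: float = 2.0
    beta: float = 1.0  # seconds
    t0: float = 2.0  # seconds

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0 or self.amplitude <= 0 or self.t0 < 0:
            raise ValueError("gamma-variate requires alpha, beta, A > 0 and t0 >= 0")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return gamma_variate(t, self.amplitude, self.alpha, self.beta, self.t0)

    def shifted(self, dt0=0.0, dalpha=0.0, dbeta=0.0, damplitude=0.0) -> "GammaVariate":
        return GammaVariate(
            amplitude=self.amplitude + damplitude,
            alpha=self.alpha + dalpha,
            beta=self.beta + dbeta,
            t0=self.t0 + dt0,
        )


def gamma_variate(t, A: float, alpha: float, beta: float, t0: float) -> np.ndarray:
    """Evaluate the peak-normalized gamma-variate at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    tau = t - t0
    out = np.zeros_like(tau)
    pos = tau > 0
    x = tau[pos] / (alpha * beta)
    out[pos] = A * np.power(x, alpha) * np.exp(alpha - tau[pos] / beta)
    return out


@dataclass
class TerritorySpec:
    label: str
    rings: List  # closed (row, col) rings
    bolus: GammaVariate


@dataclass
class VesselSpec:
    """The injected vessel: a thick line segment carrying the AIF bolus."""

    p0: Tuple[float, float]
    p1: Tuple[float, float]
    bolus: GammaVariate
    width_px: float = 5.0


@dataclass
class PhantomSpec:
    """Study conditions of the synthetic acquisition.

    Defaults: 128x128 frames, 40 frames at dt = 0.25 s, baseline 100,
    noise SD 2 intensity units, static background texture of amplitude 3.
    """

    height: int = 128
    width: int = 128
    n_frames: int = 40
    dt_s: float = 0.25
    territories: List[TerritorySpec] = field(default_factory=list)
    vessel: Optional[VesselSpec] = None
    noise_sd: float = 2.0
    background_amp: float = 3.0
    motion_px_per_frame: Optional[Tuple[float, float]] = None
    view: View = View.AP
    seed: int = 0


@dataclass
class GroundTruth:
    """Analytic / dense-grid oracle metrics per territory plus masks."""

    territory_masks: Dict[str, np.ndarray]
    territory_metrics: Dict[str, Dict[str, float]]
    vessel_mask: Optional[np.ndarray]
    aif_line: Optional[Tuple[Tuple[float, float], Tuple[float, float]]]
    times: np.ndarray


# --------------------------------------------------------------------------
# Dense-grid brute-force oracle (independent of bolus_kinetics)
# --------------------------------------------------------------------------


def oracle_metrics(
    bolus: GammaVariate,
    aif_bolus: Optional[GammaVariate],
    t_end: float,
    dt: float = 1e-4,
    at_frac: float = 0.05,
    ttd_frac: float = 0.05,
) -> Dict[str, float]:
    """Brute-force AT/TTP/TTD/MTT/CBV/CBF on a dense grid.

    Scans the analytic curve sampled at ``dt`` over [0, t_end]: AT is the
    first sample at/above at_frac*peak, TTD the last, FWHM likewise at
    half peak; CBV is the rectangle-rule area ratio against the AIF curve.
    Kept deliberately simple (index scans, no interpolation) so it is an
    independent check on the production implementation.
    """
    t = np.arange(0.0, t_end + dt / 2, dt)
    c = bolus(t)
    peak = c.max()
    ttp = float(t[int(np.argmax(c))])
    above_at = np.nonzero(c >= at_frac * peak)[0]
    at = float(t[above_at[0]])
    ttd = float(t[above_at[-1]]) if ttd_frac == at_frac else float(
        t[np.nonzero(c >= ttd_frac * peak)[0][-1]]
    )
    above_half = np.nonzero(c >= 0.5 * peak)[0]
    mtt = float(t[above_half[-1]] - t[above_half[0]])
    out = {"AT": at, "TTP": ttp, "TTD": ttd, "MTT": mtt}
    if aif_bolus is not None:
        a = aif_bolus(t)
        cbv = float(c.sum() / a.sum())
        out["CBV"] = cbv
        out["CBF"] = cbv / mtt
    return out


def analytic_ttp(bolus: GammaVariate) -> float:
    return bolus.t0 + bolus.alpha * bolus.beta


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------


def _vessel_mask(spec: VesselSpec, shape) -> np.ndarray:
    """Pixels within width/2 of the segment (piecewise-constant interior)."""
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    r0, c0 = spec.p0
    r1, c1 = spec.p1
    dr, dc = r1 - r0, c1 - c0
    L2 = dr * dr + dc * dc
    if L2 == 0:
        raise ValueError("vessel segment endpoints must differ")
    s = np.clip(((rr - r0) * dr + (cc - c0) * dc) / L2, 0.0, 1.0)
    dist = np.hypot(rr - (r0 + s * dr), cc - (c0 + s * dc))
    return dist <= spec.width_px / 2.0


def generate(spec: PhantomSpec) -> Tuple[FrameSequence, GroundTruth]:
    """Render the phantom sequence and its ground truth.

    Territory polygons must be non-overlapping and inside the frame; the
    vessel band overrides any territory it crosses.  Seeded runs are
    bit-reproducible.
    """
    H, W, T = spec.height, spec.width, spec.n_frames
    times = spec.dt_s * np.arange(T)
    rng = np.random.default_rng(spec.seed)

    occupancy = np.zeros((H, W), dtype=bool)
    masks: Dict[str, np.ndarray] = {}
    for terr in spec.territories:
        pts = np.concatenate([np.asarray(r, float) for r in terr.rings])
        if pts.min() < 0 or pts[:, 0].max() > H - 1 or pts[:, 1].max() > W - 1:
            raise ValueError(f"territory {terr.label!r} polygon outside the frame")
        m = rasterize_polygons(terr.rings, (H, W))
        if (m & occupancy).any():
            raise ValueError(f"territory {terr.label!r} overlaps another territory")
        occupancy |= m
        masks[terr.label] = m

    contrast = np.zeros((T, H, W))
    for terr in spec.territories:
        contrast[:, masks[terr.label]] = terr.bolus(times)[:, None]

    vmask = None
    aif_line = None
    if spec.vessel is not None:
        vmask = _vessel_mask(spec.vessel, (H, W))
        contrast[:, vmask] = spec.vessel.bolus(times)[:, None]
        aif_line = (spec.vessel.p0, spec.vessel.p1)

    background = np.zeros((H, W))
    if spec.background_amp > 0:
        from scipy.ndimage import gaussian_filter

        field_ = gaussian_filter(rng.standard_normal((H, W)), sigma=2.0)
        sd = field_.std()
        if sd > 0:
            background = spec.background_amp * field_ / sd

    frames = BASELINE + background[None, :, :] - contrast

    if spec.motion_px_per_frame is not None:
        from scipy.ndimage import shift as nd_shift

        dy, dx = spec.motion_px_per_frame
        for k in range(1, T):
            frames[k] = nd_shift(
                frames[k], (dy * k, dx * k), order=1, mode="nearest"
            )

    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, size=frames.shape)

    t_end = float(times[-1])
    metrics: Dict[str, Dict[str, float]] = {}
    for terr in spec.territories:
        m = oracle_metrics(
            terr.bolus,
            spec.vessel.bolus if spec.vessel is not None else None,
            t_end,
        )
        m["TTP_analytic"] = analytic_ttp(terr.bolus)
        metrics[terr.label] = m

    seq = FrameSequence(
        frames=frames,
        times=times,
        view=spec.view,
        source_id=f"phantom(seed={spec.seed})",
    )
    truth = GroundTruth(
        territory_masks=masks,
        territory_metrics=metrics,
        vessel_mask=vmask,
        aif_line=aif_line,
        times=times,
    )
    return seq, truth


def make_pre_post(
    spec: PhantomSpec,
    deltas: Dict[str, dict],
    post_seed_offset: int = 1,
) -> Tuple[FrameSequence, FrameSequence, GroundTruth, GroundTruth, Dict[str, Dict[str, float]]]:
    """Generate a pre/post pair with per-territory kinetic changes.

    ``deltas`` maps territory label -> keyword changes for
    :meth:`GammaVariate.shifted` (dt0, dalpha, dbeta, damplitude),
    emulating the vasodilation effect of an intra-arterial treatment.
    Returns (pre_seq, post_seq, pre_truth, post_truth, truth_deltas) where
    ``truth_deltas[label][metric]`` is the oracle post-minus-pre change.
    """
    pre_seq, pre_truth = generate(spec)

    post_terrs = [
        TerritorySpec(
            label=t.label,
            rings=t.rings,
            bolus=t.bolus.shifted(**deltas.get(t.label, {})),
        )
        for t in spec.territories
    ]
    post_spec = PhantomSpec(
        height=spec.height,
        width=spec.width,
        n_frames=spec.n_frames,
        dt_s=spec.dt_s,
        territories=post_terrs,
        vessel=spec.vessel,
        noise_sd=spec.noise_sd,
        background_amp=spec.background_amp,
        motion_px_per_frame=spec.motion_px_per_frame,
        view=spec.view,
        seed=spec.seed + post_seed_offset,
    )
    post_seq, post_truth = generate(post_spec)

    truth_deltas = {
        label: {
            k: post_truth.territory_metrics[label][k] - pre_truth.territory_metrics[label][k]
            for k in pre_truth.territory_metrics[label]
        }
        for label in pre_truth.territory_metrics
    }
    return pre_seq, post_seq, pre_truth, post_truth, truth_deltas


# --------------------------------------------------------------------------
# Default study conditions
# --------------------------------------------------------------------------


def fwhm_coefficient(alpha: float) -> float:
    """FWHM of the unit gamma-variate in units of beta (root-finding)."""
    from scipy.optimize import brentq

    def g(u):
        return (u / alpha) ** alpha * math.exp(alpha - u) - 0.5

    u_up = brentq(g, 1e-9, alpha)
    u_dn = brentq(g, alpha, 60.0)
    return u_dn - u_up


def default_pre_post_spec(
    seed: int = 0,
    noise_sd: float = 2.0,
    motion_px_per_frame: Optional[Tuple[float, float]] = None,
) -> Tuple[PhantomSpec, Dict[str, dict]]:
    """The canonical two-territory verapamil-like phantom pair.

    Territory "MCA" gets a clinically scaled treatment effect —
    dTTP = -1.2 s exactly and dMTT = -1.1 s exactly (both solved from the
    gamma-variate geometry), with the implied dAT of about -0.6 s.
    Territory "ACA" is an untreated control (no kinetic change).  The
    vessel band along the left edge carries a taller, earlier AIF bolus.
    """
    mca = TerritorySpec(
        label="MCA",
        rings=[[[20, 30], [20, 120], [60, 120], [60, 30]]],
        bolus=GammaVariate(amplitude=30.0, alpha=2.0, beta=1.0, t0=2.0),
    )
    aca = TerritorySpec(
        label="ACA",
        rings=[[[70, 30], [70, 120], [110, 120], [110, 30]]],
        bolus=GammaVariate(amplitude=25.0, alpha=2.0, beta=1.1, t0=2.2),
    )
    vessel = VesselSpec(
        p0=(10.0, 8.0),
        p1=(118.0, 8.0),
        bolus=GammaVariate(amplitude=60.0, alpha=3.0, beta=0.5, t0=1.0),
        width_px=7.0,
    )
    spec = PhantomSpec(
        territories=[mca, aca],
        vessel=vessel,
        noise_sd=noise_sd,
        motion_px_per_frame=motion_px_per_frame,
        seed=seed,
    )
    # Solve the kinetic changes so the oracle deltas land on the clinical
    # scale: dMTT = -1.1 s via beta (FWHM is linear in beta at fixed alpha),
    # then dt0 so dTTP = d t0 + alpha*dbeta = -1.2 s.
    k = fwhm_coefficient(mca.bolus.alpha)
    dbeta = -1.1 / k
    dt0 = -1.2 - mca.bolus.alpha * dbeta
    deltas = {"MCA": {"dt0": dt0, "dbeta": dbeta}}
    return spec, deltas
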
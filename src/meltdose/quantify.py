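"""Melting-peak detection and batch peak normalization.

Copy number is quantified by target melting-peak heights on the −dF/dT
curve, after every curve in the batch has its reference peak normalized
both vertically — to the geometric mean reference-peak amplitude across
the batch — and horizontally — an affine temperature map sending each
sample's peak temperatures to the batch-mean temperature of each peak.
The target/reference height ratio of a sample divided by that of a
two-copy control is then the relative dosage, ≈ copies/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .models import MeltdoseError, NegDerivCurve, Peak, PeakWindow

log = logging.getLogger(__name__)

DEFAULT_REFERENCE_FLOOR = 0.1  # fraction of batch median reference height
AFFINE_SCALE_BAND = (0.95, 1.05)


def detect_peaks(
    curve: NegDerivCurve,
    windows: Sequence[PeakWindow],
    reference: Optional[str] = None,
    absent_frac: float = 0.05,
) -> List[Peak]:
    """Highest local maximum per window, with sub-grid quadratic refinement.

    A window without an interior local maximum yields a height-0 peak at
    the window center flagged ``absent`` (no product melted there).
    Ties between equal-height maxima break toward the window center.
    When ``reference`` names one of the windows, target-window maxima
    whose topographic prominence is below ``absent_frac`` × the reference
    peak height are treated as absent too: a melting transition rises
    with prominence comparable to its height, whereas noise wiggles on a
    neighbouring peak's flank do not.
    """
    for i, w in enumerate(windows):
        for other in windows[i + 1:]:
            if w.overlaps(other):
                raise MeltdoseError(
                    f"peak windows {w.amplicon} and {other.amplicon} overlap"
                )
    grid = curve.temperatures
    vals = curve.values
    all_max, _ = signal.find_peaks(vals)
    prominences = (
        signal.peak_prominences(vals, all_max)[0]
        if all_max.size
        else np.zeros(0)
    )

    def window_candidates(w: PeakWindow) -> Tuple[np.ndarray, np.ndarray]:
        if w.low < grid[0] or w.high > grid[-1]:
            raise MeltdoseError(
                f"window {w.amplicon} [{w.low}, {w.high}] outside curve grid"
            )
        sel = (grid[all_max] >= w.low) & (grid[all_max] <= w.high)
        return all_max[sel], prominences[sel]

    def pick(cand: np.ndarray, w: PeakWindow) -> Peak:
        heights = vals[cand]
        ties = cand[heights == heights.max()]
        i0 = int(ties[np.argmin(np.abs(grid[ties] - w.center))])
        t, h = _refine_quadratic(grid, vals, i0)
        return Peak(t, h, w.amplicon, curve.sample_id)

    ordered = sorted(windows, key=lambda w: w.amplicon != reference)
    ref_height = 0.0
    peaks: List[Peak] = []
    for w in ordered:
        cand, prom = window_candidates(w)
        if w.amplicon != reference and reference is not None:
            keep = prom >= absent_frac * ref_height
            cand, prom = cand[keep], prom[keep]
        if cand.size == 0:
            peaks.append(Peak(w.center, 0.0, w.amplicon, curve.sample_id, absent=True))
            continue
        peak = pick(cand, w)
        if w.amplicon == reference:
            ref_height = peak.height
        peaks.append(peak)
    # preserve the caller's window order
    order = {w.amplicon: i for i, w in enumerate(windows)}
    peaks.sort(key=lambda p: order[p.amplicon])
    return peaks


def _refine_quadratic(grid: np.ndarray, vals: np.ndarray, i: int) -> Tuple[float, float]:
    vm, v0, vp = vals[i - 1], vals[i], vals[i + 1]
    denom = vm - 2 * v0 + vp
    if denom >= 0:  # degenerate curvature; keep the grid point
        return float(grid[i]), float(v0)
    delta = 0.5 * (vm - vp) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    step = grid[1] - grid[0]
    height = v0 - 0.25 * (vm - vp) * delta
    return float(grid[i] + delta * step), float(height)


@dataclass
class NormalizedBatch:
    """Output of :func:`normalize_peaks_batch`."""

    curves: List[NegDerivCurve]
    peaks: List[List[Peak]]
    excluded: List[str]          # sample_ids with a failed reference peak
    geometric_mean: float
    scale_warnings: List[str]


def normalize_peaks_batch(
    curves: Sequence[NegDerivCurve],
    peaks: Sequence[Sequence[Peak]],
    reference: str,
    floor: float = DEFAULT_REFERENCE_FLOOR,
) -> NormalizedBatch:
    """Two-sided reference-peak normalization across a batch.

    Vertically, each curve is multiplied by G/h_ref where G is the
    geometric mean of the (non-failed) reference peak heights.
    Horizontally, each sample's detected peak temperatures are mapped by
    an affine transform onto the batch-mean temperature of each peak
    (exact with two anchors, least-squares with three) and the curve is
    re-interpolated.  Samples whose reference peak is absent or below
    ``floor`` × the batch median reference height are excluded and
    reported — never silently dropped.
    """
    ref_heights = {}
    for sample_peaks in peaks:
        p = _find(sample_peaks, reference)
        ref_heights[p.sample_id] = 0.0 if p.absent else p.height
    finite = np.array([h for h in ref_heights.values() if h > 0], float)
    if finite.size == 0:
        raise MeltdoseError("no sample in the batch amplified the reference")
    median = float(np.median(finite))
    excluded = [
        sid for sid, h in ref_heights.items() if h < floor * median or h <= 0
    ]
    kept = [
        (c, list(ps)) for c, ps in zip(curves, peaks)
        if c.sample_id not in excluded
    ]
    if not kept:
        raise MeltdoseError("every sample failed the reference floor")

    g = float(np.exp(np.mean([np.log(ref_heights[c.sample_id]) for c, _ in kept])))

    # Vertical: scale curves and peak heights to the geometric mean.
    scaled: List[Tuple[NegDerivCurve, List[Peak]]] = []
    for c, ps in kept:
        f = g / ref_heights[c.sample_id]
        new_curve = NegDerivCurve(c.temperatures.copy(), c.values * f, c.sample_id)
        new_peaks = [
            Peak(p.temperature, p.height * f, p.amplicon, p.sample_id, p.absent)
            for p in ps
        ]
        scaled.append((new_curve, new_peaks))

    # Horizontal: affine map to the batch-mean temperature of each peak.
    amplicon_names = [p.amplicon for p in scaled[0][1]]
    mean_temp = {}
    for name in amplicon_names:
        temps = [
            _find(ps, name).temperature
            for _, ps in scaled
            if not _find(ps, name).absent
        ]
        if temps:
            mean_temp[name] = float(np.mean(temps))

    out_curves: List[NegDerivCurve] = []
    out_peaks: List[List[Peak]] = []
    warnings: List[str] = []
    for c, ps in scaled:
        anchors = [
            (p.temperature, mean_temp[p.amplicon])
            for p in ps
            if not p.absent and p.amplicon in mean_temp
        ]
        alpha, beta = _fit_affine(anchors)
        if not AFFINE_SCALE_BAND[0] <= alpha <= AFFINE_SCALE_BAND[1]:
            msg = (
                f"{c.sample_id}: horizontal scale {alpha:.3f} outside "
                f"{AFFINE_SCALE_BAND}"
            )
            warnings.append(msg)
            log.warning("normalize_peaks_batch: %s", msg)
        grid = c.temperatures
        spline = CubicSpline(grid, c.values)
        # value at T comes from the pre-map temperature (T - beta)/alpha
        src = np.clip((grid - beta) / alpha, grid[0], grid[-1])
        out_curves.append(NegDerivCurve(grid.copy(), spline(src), c.sample_id))
        out_peaks.append(
            [
                Peak(
                    alpha * p.temperature + beta if not p.absent else p.temperature,
                    p.height,
                    p.amplicon,
                    p.sample_id,
                    p.absent,
                )
                for p in ps
            ]
        )
    if excluded:
        log.warning(
            "normalize_peaks_batch: excluded (failed reference): %s",
            ", ".join(excluded),
        )
    return NormalizedBatch(out_curves, out_peaks, excluded, g, warnings)


def _fit_affine(anchors: List[Tuple[float, float]]) -> Tuple[float, float]:
    """Affine map x → αx + β through source/destination anchor pairs."""
    if len(anchors) == 0:
        return 1.0, 0.0
    if len(anchors) == 1:
        (x, y), = anchors
        return 1.0, y - x
    xs = np.array([a[0] for a in anchors])
    ys = np.array([a[1] for a in anchors])
    alpha, beta = np.polyfit(xs, ys, 1)
    return float(alpha), float(beta)


def relative_dosage(
    sample_peaks: Sequence[Peak],
    baseline_peaks: Sequence[Peak],
    targets: Sequence[str],
) -> Dict[str, float]:
    """Target peak heights relative to a normalized two-copy control.

    An absent sample peak yields dosage 0; an absent or zero-height
    baseline target is an invalid baseline and is rejected.
    """
    out: Dict[str, float] = {}
    for name in targets:
        base = _find(baseline_peaks, name)
        if base.absent or base.height <= 0:
            raise MeltdoseError(
                f"invalid baseline: control has no {name} peak"
            )
        p = _find(sample_peaks, name)
        out[name] = 0.0 if p.absent else p.height / base.height
    return out


def _find(peaks: Sequence[Peak], amplicon: str) -> Peak:
    for p in peaks:
        if p.amplicon == amplicon:
            return p
    raise MeltdoseError(f"no peak record for amplicon {amplicon!r}")
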
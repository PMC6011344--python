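"""Raw melt curves → overlaid, normalized negative-derivative curves.

The chain follows standard high-resolution-melting practice:

1. **Exponential background subtraction.**  Saturating-dye fluorescence
   rides on a decaying exponential background.  Two cursors flank the melt
   region; the (negative) smoothed slopes there determine the decay rate
   ``a = ln(s_R/s_L)/(T_R−T_L)`` and amplitude of ``B(T) = C·e^{aT}``,
   whose cumulative contribution is removed so the corrected curve is flat
   at both cursors and ≈ 0 beyond the right cursor.
2. **Helicity normalization.**  Affine rescale to 100% helicity at the
   left cursor and 0% at the right, removing per-well fluorescence gain.
3. **Temperature shifting.**  Each curve is translated by the δ that best
   overlays it (in the sup metric) with the batch's first curve over a
   low-helicity band, removing well-to-well temperature offsets.
4. **Savitzky–Golay differentiation.**  Degree-2 local-polynomial first
   derivative, negated, so melting transitions appear as peaks.

Two numerical details in step 1 go beyond the textbook recipe.  A
Savitzky–Golay slope estimate of an exponential carries the multiplicative
bias ρ(a) = Σ cᵢ e^{a·i·h}; because the two cursor slopes share that bias,
``a`` is recovered exactly from their ratio, and dividing the anchor slope
by ρ(a) makes the subtraction exact (to rounding) on pure-exponential
input.  Second, the melting transitions' tails leak a little slope into
the cursors; a few fixed-point iterations re-estimate the cursor slopes
after removing the current signal estimate, which matters most for the
triplex assay whose highest-melting product sits near the top of the
acquisition range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, savgol_coeffs, savgol_filter

from .models import (
    CursorPair,
    MeltCurve,
    MeltdoseError,
    NegDerivCurve,
    ReactionSpec,
)

log = logging.getLogger(__name__)

DEFAULT_SG_WINDOW = 1.0     # °C, derivative filter
DEFAULT_SG_DEGREE = 2
DEFAULT_SLOPE_WINDOW = 2.0  # °C, cursor slope estimation
DEFAULT_SHIFT_BAND = (5.0, 10.0)   # % helicity
DEFAULT_MAX_SHIFT = 1.0     # °C
CURSOR_MARGIN_WIDTHS = 5.0  # melt widths between extreme Tm and cursor
CURSOR_MARGIN_EXTRA = 1.5   # °C on top of the width margin


def _odd_points(window: float, step: float, degree: int) -> int:
    """Window length in grid points, forced odd; rejects degenerate windows."""
    n = max(int(round(window / step)), 1)
    if n % 2 == 0:
        n += 1
    if n < degree + 2:
        raise MeltdoseError(
            f"window of {window} °C is {n} points at step {step}; "
            f"needs at least degree+2 = {degree + 2}"
        )
    return n


def default_cursors(
    reaction: ReactionSpec,
    grid: np.ndarray,
    margin_widths: float = CURSOR_MARGIN_WIDTHS,
    margin_extra: float = CURSOR_MARGIN_EXTRA,
    edge_clearance: float = DEFAULT_SLOPE_WINDOW / 2,
) -> CursorPair:
    """Cursors flanking all expected transitions of ``reaction``.

    Placed ``margin_widths`` melt widths plus ``margin_extra`` °C outside
    the extreme Tms, clipped so each keeps half a slope-estimation window
    inside the grid (the triplex's highest Tm leaves little headroom
    before the top of the acquisition range).
    """
    lo_amp = min(reaction.amplicons, key=lambda a: a.tm)
    hi_amp = max(reaction.amplicons, key=lambda a: a.tm)
    left = lo_amp.tm - margin_widths * lo_amp.melt_width - margin_extra
    right = hi_amp.tm + margin_widths * hi_amp.melt_width + margin_extra
    left = max(left, float(grid[0]) + edge_clearance)
    right = min(right, float(grid[-1]) - edge_clearance)
    return CursorPair(left, right)


def _sg_slope(values: np.ndarray, step: float, window: float, degree: int) -> np.ndarray:
    n = _odd_points(window, step, degree)
    return savgol_filter(values, n, degree, deriv=1, delta=step)


def _filter_response(a: float, step: float, window: float, degree: int) -> float:
    """Response ρ(a) of the derivative filter to e^{aT}: ŝ = ρ(a)·e^{aT}."""
    n = _odd_points(window, step, degree)
    c = savgol_coeffs(n, degree, deriv=1, delta=step, use="dot")
    m = n // 2
    offsets = (np.arange(n) - m) * step
    return float(np.dot(c, np.exp(a * offsets)))


def _window_mean(curve_vals: np.ndarray, grid: np.ndarray, center: float,
                 width: float) -> float:
    mask = np.abs(grid - center) <= width / 2
    return float(curve_vals[mask].mean())


def subtract_exponential_background(
    curve: MeltCurve,
    cursors: CursorPair,
    slope_window: float = DEFAULT_SLOPE_WINDOW,
    degree: int = DEFAULT_SG_DEGREE,
    refine: int = 3,
) -> MeltCurve:
    """Remove the exponential dye background anchored at the cursors.

    The fluorescence must be strictly decreasing (smoothed slope < 0) at
    both cursors — i.e. the cursors sit on background decay, not on a
    plateau or rise.  ``refine`` fixed-point iterations subtract the
    estimated melt signal's own tail slope from the cursor slopes before
    re-fitting the exponential.
    """
    grid = curve.temperatures
    step = curve.step
    if not (grid[0] <= cursors.left < cursors.right <= grid[-1]):
        raise MeltdoseError("cursors outside the curve's temperature range")

    i_left = int(np.argmin(np.abs(grid - cursors.left)))
    i_right = int(np.argmin(np.abs(grid - cursors.right)))

    raw_slopes = _sg_slope(curve.fluorescence, step, slope_window, degree)
    s_left, s_right = raw_slopes[i_left], raw_slopes[i_right]
    # Tolerate slope ≈ 0 (already-flat input, e.g. re-processing) but
    # reject genuinely rising fluorescence at a cursor.
    tol = 1e-9 * max(
        float(np.ptp(curve.fluorescence)) / (cursors.right - cursors.left),
        1e-30,
    )
    for name, s in (("left", s_left), ("right", s_right)):
        if s > tol:
            raise MeltdoseError(
                f"no fluorescence decay at the {name} cursor "
                f"(slope {s:.3g} >= 0); cannot fit an exponential background"
            )
    s_left = min(s_left, -tol)
    s_right = min(s_right, -tol)

    # The raw cursor slopes mix background decay with the melt
    # transitions' tails.  Fixed-point decontamination: fit the
    # background, model the corrected curve's transitions as logistics
    # (position and height from the derivative peaks, width from the
    # peak curvature), and strip the model's *filtered* tail slope from
    # the raw cursor slopes before refitting.  A stripped slope driven
    # to ~0 means no measurable decay on that side; flooring it keeps
    # the fit defined.
    slope_floor = -1e-4 * max(abs(s_left), abs(s_right))
    model = np.zeros_like(curve.fluorescence)
    corrected = curve.fluorescence.copy()
    for iteration in range(max(refine, 1)):
        if iteration > 0:
            model = _transition_model(grid, corrected, step)
        model_slopes = _sg_slope(model, step, slope_window, degree)
        bg_left = min(s_left - model_slopes[i_left], slope_floor)
        bg_right = min(s_right - model_slopes[i_right], slope_floor)
        a = float(np.log(bg_right / bg_left) / (cursors.right - cursors.left))
        rho = _filter_response(a, step, slope_window, degree)
        # True background slope at the left cursor, bias-corrected.
        bprime_left = bg_left * (a / rho if abs(a) > 1e-12 else 1.0)
        background = _integrated_exponential(grid, cursors, a, bprime_left)
        corrected = curve.fluorescence - background

    # Anchor the corrected curve to ≈ 0 over the right-cursor window.
    corrected = corrected - _window_mean(corrected, grid, cursors.right, slope_window)
    return curve.with_values(corrected, stage="background_subtracted")


def _transition_model(
    grid: np.ndarray, corrected: np.ndarray, step: float,
    deriv_window: float = 1.0, min_width: float = 0.2, max_width: float = 1.5,
) -> np.ndarray:
    """Sum-of-logistics model of the melt transitions in ``corrected``.

    Each −dF/dT peak of prominence ≥ 5% of the tallest becomes a
    two-state transition: Tm at the peak, width from the peak curvature
    (a logistic derivative peak of height h has curvature −h/(2w²)),
    amplitude 4wh.  Used only to predict transition tail slopes at the
    background cursors; widths are clamped to a plausible melt range.
    """
    n = _odd_points(deriv_window, step, 2)
    deriv = -savgol_filter(corrected, n, 2, deriv=1, delta=step)
    d2 = np.gradient(np.gradient(deriv, step), step)
    idx, _ = find_peaks(deriv, prominence=0.05 * max(deriv.max(), 1e-30))
    model = np.zeros_like(grid)
    for i in idx:
        h = deriv[i]
        g2 = d2[i]
        if h <= 0 or g2 >= 0:
            continue
        w = float(np.clip(np.sqrt(h / (2.0 * -g2)), min_width, max_width))
        amplitude = 4.0 * w * h
        model += amplitude / (1.0 + np.exp(-(grid[i] - grid) / w))
    return model


def _integrated_exponential(
    grid: np.ndarray, cursors: CursorPair, a: float, bprime_left: float
) -> np.ndarray:
    """∫ background slope dT with B(right cursor) = 0."""
    if abs(a) > 1e-12:
        return (bprime_left / a) * (
            np.exp(a * (grid - cursors.left))
            - np.exp(a * (cursors.right - cursors.left))
        )
    return bprime_left * (grid - cursors.right)


def normalize_helicity(
    curve: MeltCurve,
    cursors: CursorPair,
    window: float = 1.0,
) -> MeltCurve:
    """Affine rescale: mean 100 at the left cursor window, 0 at the right."""
    if curve.stage == "raw":
        raise MeltdoseError("normalize_helicity expects a background-subtracted curve")
    grid = curve.temperatures
    top = _window_mean(curve.fluorescence, grid, cursors.left, window)
    bottom = _window_mean(curve.fluorescence, grid, cursors.right, window)
    if abs(top - bottom) < 1e-12:
        raise MeltdoseError(
            f"curve {curve.sample_id}: no dynamic range between cursors"
        )
    values = 100.0 * (curve.fluorescence - bottom) / (top - bottom)
    return curve.with_values(values, stage="normalized")


@dataclass
class ShiftResult:
    """Temperature-shifted batch plus the per-curve translations applied."""

    curves: List[MeltCurve]
    deltas: np.ndarray
    flagged: List[str]


def temperature_shift(
    curves: Sequence[MeltCurve],
    band: Tuple[float, float] = DEFAULT_SHIFT_BAND,
    max_shift: float = DEFAULT_MAX_SHIFT,
    delta_step: float = 0.01,
) -> ShiftResult:
    """Overlay curves on the batch's first curve over a helicity band.

    Each curve is translated by the δ (|δ| ≤ ``max_shift``) minimizing the
    sup distance to the first curve restricted to temperatures where the
    first curve's helicity lies in ``band`` (default the 5–10% tail, which
    every genotype shares through the reference amplicon's melt).  Curves
    whose own values never cross the band are flagged and left unshifted.
    """
    if not curves:
        return ShiftResult([], np.zeros(0), [])
    for c in curves:
        if c.stage not in ("normalized", "background_subtracted"):
            raise MeltdoseError(f"curve {c.sample_id}: shift expects normalized curves")
        if not np.array_equal(c.temperatures, curves[0].temperatures):
            raise MeltdoseError("temperature_shift requires a common grid")

    low, high = band
    ref = curves[0]
    grid = ref.temperatures
    step = ref.step
    smooth_n = _odd_points(1.0, step, 2)
    ref_smooth = savgol_filter(ref.fluorescence, smooth_n, 2)
    in_band = (ref_smooth >= low) & (ref_smooth <= high)
    # Use the high-temperature band crossing: points past the last
    # above-band sample of the reference curve.
    above = np.nonzero(ref_smooth > high)[0]
    if above.size:
        in_band[: above[-1] + 1] = False
    band_idx = np.nonzero(in_band)[0]

    shifted: List[MeltCurve] = []
    deltas = np.zeros(len(curves))
    flagged: List[str] = []
    candidates = np.arange(-max_shift, max_shift + delta_step / 2, delta_step)
    for k, c in enumerate(curves):
        c_smooth = savgol_filter(c.fluorescence, smooth_n, 2)
        crosses = band_idx.size > 0 and (
            c_smooth.min() <= high and c_smooth.max() >= low
        )
        if not crosses:
            flagged.append(c.sample_id)
            delta = 0.0
        elif k == 0:
            delta = 0.0
        else:
            spline = CubicSpline(grid, c.fluorescence)
            band_T = grid[band_idx]
            ref_vals = ref.fluorescence[band_idx]
            costs = [
                np.max(np.abs(spline(np.clip(band_T + d, grid[0], grid[-1]))
                              - ref_vals))
                for d in candidates
            ]
            delta = float(candidates[int(np.argmin(costs))])
        spline = CubicSpline(grid, c.fluorescence)
        values = spline(np.clip(grid + delta, grid[0], grid[-1]))
        deltas[k] = delta
        shifted.append(MeltCurve(grid.copy(), values, c.sample_id, stage="shifted"))
    if flagged:
        log.warning("temperature_shift: band not crossed by %s", ", ".join(flagged))
    return ShiftResult(shifted, deltas, flagged)


def savitzky_golay_negderiv(
    curve: MeltCurve,
    window: float = DEFAULT_SG_WINDOW,
    degree: int = DEFAULT_SG_DEGREE,
) -> NegDerivCurve:
    """Negative first derivative by local least-squares polynomial fit.

    The filter is linear-phase (no temperature lag); half a window is
    trimmed at each end rather than padded with fabricated values.
    """
    step = curve.step
    n = _odd_points(window, step, degree)
    deriv = savgol_filter(curve.fluorescence, n, degree, deriv=1, delta=step)
    half = n // 2
    return NegDerivCurve(
        curve.temperatures[half:-half].copy(),
        -deriv[half:-half],
        curve.sample_id,
    )


def preprocess_curve(
    curve: MeltCurve,
    cursors: CursorPair,
    slope_window: float = DEFAULT_SLOPE_WINDOW,
    degree: int = DEFAULT_SG_DEGREE,
) -> MeltCurve:
    """Background subtraction followed by helicity normalization."""
    sub = subtract_exponential_background(
        curve, cursors, slope_window=slope_window, degree=degree
    )
    return normalize_helicity(sub, cursors)
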
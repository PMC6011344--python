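"""Signal chain: background subtraction, normalization, shifting, derivative."""

import numpy as np
import pytest

from meltdose import preprocess as pp
from meltdose import synthetic
from meltdose.models import CursorPair, GenotypeTruth, MeltCurve, MeltdoseError
from meltdose.pcr import simulate_competitive_pcr
from meltdose.synthetic import transition_sum

from conftest import noiseless_curve


def _logistic(grid, A, tm, w=0.7):
    return A / (1 + np.exp(-(tm - grid) / w))


class TestBackgroundSubtraction:
    def test_pure_exponential_removed_to_machine_precision(self, grid, sma_cursors):
        background = 40.0 * np.exp(-0.09 * (grid - 65.0))
        curve = MeltCurve(grid, background, "bg")
        out = pp.subtract_exponential_background(curve, sma_cursors)
        assert np.abs(out.fluorescence).max() < 1e-6 * background.max()

    def test_zero_background_passthrough(self, grid, sma_cursors):
        signal = _logistic(grid, 10.0, 77.5) + _logistic(grid, 7.0, 73.5)
        curve = MeltCurve(grid, signal, "s")
        out = pp.subtract_exponential_background(curve, sma_cursors)
        # nothing to subtract: output tracks the input transition sum
        assert np.abs(out.fluorescence - signal).max() < 0.025 * signal.max()

    def test_known_background_recovers_transitions(self, grid, sma_cursors,
                                                   sma_reaction):
        """Forward-model oracle: corrected curve ≈ noiseless transition sum."""
        gt = GenotypeTruth({"SMN1": 1}, "Carrier")
        products = simulate_competitive_pcr(sma_reaction, gt)
        signal = transition_sum(products, sma_reaction.amplicons, grid)
        curve = synthetic.synthesize_melt_curve(
            products, sma_reaction.amplicons, grid,
            background=(0.6 * signal.max(), 0.12), sample_id="c",
        )
        out = pp.subtract_exponential_background(curve, sma_cursors)
        rms = np.sqrt(np.mean((out.fluorescence - signal) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(signal**2))

    def test_rising_fluorescence_at_cursor_rejected(self, grid, sma_cursors):
        curve = MeltCurve(grid, np.linspace(1.0, 2.0, grid.size), "rise")
        with pytest.raises(MeltdoseError, match="cursor"):
            pp.subtract_exponential_background(curve, sma_cursors)


class TestHelicityNormalization:
    def test_anchors_at_100_and_0(self, grid, sma_cursors):
        vals = _logistic(grid, 30.0, 75.0) + 3.0
        curve = MeltCurve(grid, vals, "x", stage="background_subtracted")
        out = pp.normalize_helicity(curve, sma_cursors)
        left = np.abs(grid - sma_cursors.left) <= 0.5
        right = np.abs(grid - sma_cursors.right) <= 0.5
        assert out.fluorescence[left].mean() == pytest.approx(100.0, abs=1e-9)
        assert out.fluorescence[right].mean() == pytest.approx(0.0, abs=1e-9)

    def test_scale_invariance(self, grid, sma_cursors):
        vals = _logistic(grid, 12.0, 76.0)
        a = pp.normalize_helicity(
            MeltCurve(grid, vals, "a", stage="background_subtracted"), sma_cursors)
        b = pp.normalize_helicity(
            MeltCurve(grid, 3 * vals, "b", stage="background_subtracted"), sma_cursors)
        np.testing.assert_allclose(a.fluorescence, b.fluorescence, atol=1e-9)

    def test_interpeak_plateau_equals_reference_share(self, grid, sma_cursors,
                                                      sma_reaction):
        """Between the transitions the curve sits at the CFTR signal share."""
        gt = GenotypeTruth({"SMN1": 2}, "Normal")
        products = simulate_competitive_pcr(sma_reaction, gt)
        curve = noiseless_curve(sma_reaction, gt, grid, background=("auto", 0.1))
        out = pp.normalize_helicity(
            pp.subtract_exponential_background(curve, sma_cursors), sma_cursors)
        amp = {a.name: products[a.name] * a.length for a in sma_reaction.amplicons}
        share = 100.0 * amp["CFTR"] / (amp["CFTR"] + amp["SMN1"])
        i_mid = int(np.argmin(np.abs(grid - 75.5)))
        assert out.fluorescence[i_mid] == pytest.approx(share, abs=2.0)

    def test_zero_dynamic_range_rejected(self, grid, sma_cursors):
        curve = MeltCurve(grid, np.ones(grid.size), "flat",
                          stage="background_subtracted")
        with pytest.raises(MeltdoseError, match="dynamic range"):
            pp.normalize_helicity(curve, sma_cursors)


class TestTemperatureShift:
    def _normalized(self, grid, tm_shift=0.0, sample_id="s"):
        vals = (
            57.6 * 1 / (1 + np.exp(-(77.5 + tm_shift - grid) / 0.7))
            + 42.4 * 1 / (1 + np.exp(-(73.5 + tm_shift - grid) / 0.7))
        )
        return MeltCurve(grid, vals, sample_id, stage="normalized")

    def test_recovers_known_translation(self, grid):
        """A +0.3 °C translate f(T+0.3) needs δ = −0.3 to overlay f."""
        ref = self._normalized(grid, 0.0, "ref")
        moved = self._normalized(grid, -0.3, "moved")  # g(T) = f(T + 0.3)
        result = pp.temperature_shift([ref, moved])
        assert result.deltas[1] == pytest.approx(-0.3, abs=0.05)

    def test_identical_curves_zero_shift(self, grid):
        curves = [self._normalized(grid, 0.0, f"s{i}") for i in range(4)]
        result = pp.temperature_shift(curves)
        np.testing.assert_allclose(result.deltas, 0.0, atol=1e-12)

    def test_jittered_batch_tightens_in_band(self, grid):
        """Random ±0.4 °C jitter: shifting reduces sup distance in the band."""
        rng = np.random.default_rng(3)
        jitters = rng.uniform(-0.4, 0.4, size=10)
        curves = [self._normalized(grid, j, f"s{i}") for i, j in enumerate(jitters)]
        result = pp.temperature_shift(curves)
        ref_smooth = curves[0].fluorescence
        band = (ref_smooth >= 5.0) & (ref_smooth <= 10.0)
        improved = 0
        total = 0
        for i in range(len(curves)):
            for j in range(i + 1, len(curves)):
                before = np.max(np.abs(
                    curves[i].fluorescence[band] - curves[j].fluorescence[band]))
                after = np.max(np.abs(
                    result.curves[i].fluorescence[band]
                    - result.curves[j].fluorescence[band]))
                total += 1
                improved += after <= before + 1e-9
        assert improved / total >= 0.95

    def test_band_not_crossed_flags_curve(self, grid):
        ref = self._normalized(grid, 0.0, "ref")
        flat = MeltCurve(grid, np.full(grid.size, 50.0), "flat", stage="normalized")
        result = pp.temperature_shift([ref, flat])
        assert "flat" in result.flagged
        assert result.deltas[1] == 0.0


class TestSavitzkyGolayDerivative:
    def test_exact_on_linear_ramp(self, grid):
        curve = MeltCurve(grid, -3.0 * grid + 250.0, "lin", stage="normalized")
        out = pp.savitzky_golay_negderiv(curve)
        np.testing.assert_allclose(out.values, 3.0, atol=1e-9)

    def test_exact_on_quadratic(self, grid):
        curve = MeltCurve(grid, 0.5 * (grid - 80) ** 2, "quad", stage="normalized")
        out = pp.savitzky_golay_negderiv(curve)
        np.testing.assert_allclose(out.values, -(out.temperatures - 80), atol=1e-8)

    def test_logistic_peak_matches_closed_form(self, grid):
        """−d/dT of A·σ((tm−T)/w) peaks at tm with height A/(4w)."""
        A, tm, w = 10.0, 77.5, 0.7
        curve = MeltCurve(grid, _logistic(grid, A, tm, w), "log", stage="normalized")
        out = pp.savitzky_golay_negderiv(curve, window=0.5)
        i = int(np.argmax(out.values))
        assert abs(out.temperatures[i] - tm) <= curve.step
        assert out.values[i] == pytest.approx(A / (4 * w), rel=0.01)

    def test_noise_suppressed_relative_to_finite_difference(self, grid):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 1.0, grid.size)
        curve = MeltCurve(grid, noise, "n", stage="normalized")
        sg = pp.savitzky_golay_negderiv(curve)
        fd = -np.gradient(noise, grid)
        assert sg.values.var() < fd.var()

    def test_window_too_small_rejected(self, grid):
        curve = MeltCurve(grid, grid * 0.0, "x", stage="normalized")
        with pytest.raises(MeltdoseError, match="window"):
            pp.savitzky_golay_negderiv(curve, window=0.05, degree=2)


class TestPipelineInvariants:
    def test_translation_equivariance(self, grid, sma_reaction):
        """Translating a raw curve translates its −dF/dT identically."""
        gt = GenotypeTruth({"SMN1": 2}, "Normal")
        shift_steps = 8  # 0.4 °C on the default grid
        base = noiseless_curve(sma_reaction, gt, grid, background=("auto", 0.1))
        moved = noiseless_curve(
            sma_reaction, gt, grid, background=("auto", 0.1),
            tm_shift=shift_steps * base.step,
        )
        # translate cursors along with the curve; background referenced to
        # grid start differs, so compare the transition part only
        c0 = CursorPair(68.5, 82.5)
        c1 = CursorPair(68.5 + shift_steps * base.step,
                        82.5 + shift_steps * base.step)
        d0 = pp.savitzky_golay_negderiv(pp.preprocess_curve(base, c0))
        d1 = pp.savitzky_golay_negderiv(pp.preprocess_curve(moved, c1))
        a = d0.values[50:-50]
        b = d1.values[50 + shift_steps:grid.size - 100 + shift_steps - 10]
        b = d1.values[50 + shift_steps: 50 + shift_steps + a.size]
        assert np.abs(a - b).max() < 0.02 * d0.values.max()

    def test_background_plus_helicity_idempotent(self, grid, sma_cursors,
                                                 sma_reaction):
        gt = GenotypeTruth({"SMN1": 1}, "Carrier")
        curve = noiseless_curve(sma_reaction, gt, grid, background=("auto", 0.1))
        once = pp.preprocess_curve(curve, sma_cursors)
        again_input = MeltCurve(grid, once.fluorescence, once.sample_id, stage="raw")
        twice = pp.preprocess_curve(again_input, sma_cursors)
        assert np.abs(twice.fluorescence - once.fluorescence).max() < 2.0
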
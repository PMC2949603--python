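"""Background subtraction, normalization, overlay, Tm and difference curves."""

import dataclasses

import numpy as np
import pytest

from meltscan.errors import CurveAnalysisError
from meltscan.preprocess import (
    MODEL_CLASS_RTOL,
    RECOVERY_RMS_TOL,
    CursorPair,
    auto_cursors,
    difference_curve,
    exponential_background_subtract,
    mean_reference,
    normalize_curve,
    preprocess_curves,
    temperature_overlay,
    tm_from_curve,
)
from meltscan.simulate import MeltCurve, MeltModelParams, simulate_curve

from conftest import build_plate


GRID = 65.0 + 0.1 * np.arange(331)
CURSORS = CursorPair((65.5, 69.5), (93.0, 97.0))


def _exp_curve(amplitude=120.0, decay=0.025, well="W0"):
    values = amplitude * np.exp(-decay * (GRID - GRID[0]))
    return MeltCurve(well, well, "raw", GRID.copy(), values)


def _quiet_norm(wt_duplexes, default_params, **over):
    p = dataclasses.replace(
        default_params, noise_sd=0.0, well_temp_jitter_sd=0.0, **over
    )
    raw = simulate_curve(wt_duplexes, p, np.random.default_rng(0))
    cursors = auto_cursors(raw)
    return normalize_curve(
        exponential_background_subtract(raw, cursors), cursors
    ), cursors


class TestBackgroundSubtraction:
    def test_pure_exponential_leaves_zero_residual(self):
        curve = _exp_curve()
        corrected = exponential_background_subtract(curve, CURSORS)
        assert np.max(np.abs(corrected.values)) < MODEL_CLASS_RTOL * 120.0

    def test_known_melt_component_recovered(self, wt_duplexes, default_params):
        """Additive sigmoid + exponential: the sigmoid survives EBS intact."""
        p = dataclasses.replace(default_params, noise_sd=0.0, well_temp_jitter_sd=0.0)
        from meltscan.thermo import helicity

        theta = sum(
            d.weight * helicity(d, GRID, p.vant_hoff_fraction) for d in wt_duplexes
        )
        signal = 80.0 * theta
        background = 40.0 * np.exp(-0.02 * (GRID - GRID[0]))
        curve = MeltCurve("W0", "S0", "raw", GRID.copy(), signal + background)
        corrected = exponential_background_subtract(curve, CURSORS)
        rms = np.sqrt(np.mean((corrected.values - signal) ** 2))
        assert rms < RECOVERY_RMS_TOL * 80.0

    def test_rising_premelt_fluorescence_rejected(self):
        values = 100.0 + (GRID - GRID[0])  # increasing: no dye decay to fit
        curve = MeltCurve("W0", "S0", "raw", GRID.copy(), values)
        with pytest.raises(CurveAnalysisError, match="negative"):
            exponential_background_subtract(curve, CURSORS)

    def test_auto_cursors_sit_in_flat_regions(self, wt_duplexes, default_params):
        p = dataclasses.replace(default_params, noise_sd=0.0, well_temp_jitter_sd=0.0)
        raw = simulate_curve(wt_duplexes, p, np.random.default_rng(0))
        cursors = auto_cursors(raw)
        tm = wt_duplexes[0].tm
        assert cursors.lower_window[1] < tm - 2
        assert cursors.upper_window[0] > tm + 2

    def test_cursor_ordering_enforced(self):
        with pytest.raises(CurveAnalysisError, match="ordered"):
            CursorPair((70.0, 68.0), (90.0, 95.0))


class TestNormalization:
    def test_window_means_pin_100_and_0(self, wt_duplexes, default_params):
        norm, cursors = _quiet_norm(wt_duplexes, default_params)
        t, v = norm.temperatures, norm.values
        lo = (t >= cursors.lower_window[0]) & (t <= cursors.lower_window[1])
        hi = (t >= cursors.upper_window[0]) & (t <= cursors.upper_window[1])
        assert 99.0 <= v[lo].mean() <= 101.0
        assert -1.0 <= v[hi].mean() <= 1.0

    def test_affine_input_invariance(self, wt_duplexes, default_params):
        """Scaling/offsetting raw fluorescence does not change the result."""
        p = dataclasses.replace(default_params, noise_sd=0.0, well_temp_jitter_sd=0.0)
        raw = simulate_curve(wt_duplexes, p, np.random.default_rng(0))
        cursors = auto_cursors(raw)
        scaled = raw.with_values(3.7 * raw.values + 55.0, "raw")
        n1 = normalize_curve(exponential_background_subtract(raw, cursors), cursors)
        n2 = normalize_curve(exponential_background_subtract(scaled, cursors), cursors)
        assert np.allclose(n1.values, n2.values, atol=1e-8)

    def test_monotone_input_stays_monotone(self):
        values = 80.0 / (1.0 + np.exp((GRID - 80.0) / 1.5)) + 5.0
        curve = MeltCurve("W0", "S0", "bg_corrected", GRID.copy(), values)
        norm = normalize_curve(curve, CURSORS)
        assert np.all(np.diff(norm.values) <= 1e-9)

    def test_idempotent_on_normalized_curve(self, wt_duplexes, default_params):
        norm, cursors = _quiet_norm(wt_duplexes, default_params)
        again = normalize_curve(norm, cursors)
        assert np.allclose(again.values, norm.values, atol=1e-9)

    def test_degenerate_dynamic_range_rejected(self):
        flat = MeltCurve("W0", "S0", "bg_corrected", GRID.copy(), np.ones_like(GRID))
        with pytest.raises(CurveAnalysisError, match="[Dd]egenerate"):
            normalize_curve(flat, CURSORS)


class TestOverlay:
    def _translated_pair(self, wt_duplexes, default_params, shift_steps=3):
        norm, _ = _quiet_norm(wt_duplexes, default_params)
        shifted_vals = np.roll(norm.values, shift_steps)
        shifted_vals[:shift_steps] = norm.values[0]
        shifted = MeltCurve("W1", "S1", "normalized", GRID.copy(), shifted_vals)
        return norm, shifted

    def test_exact_translations_coincide(self, wt_duplexes, default_params):
        base, shifted = self._translated_pair(wt_duplexes, default_params)
        overlaid, shifts, flagged = temperature_overlay(
            [base, shifted], reference_wells=[base.well_id]
        )
        assert not flagged
        interior = slice(20, 311)
        assert np.allclose(
            overlaid[0].values[interior], overlaid[1].values[interior], atol=0.05
        )
        assert shifts[base.well_id] == pytest.approx(0.0, abs=1e-9)
        assert shifts["W1"] == pytest.approx(-0.3, abs=0.02)

    def test_jitter_shifts_recovered(self, toy_amplicon, wt_duplexes):
        """Injected 0.2 °C well jitter is recovered to within the grid step."""
        params = MeltModelParams(well_temp_jitter_sd=0.2)

        class TapRng:
            def __init__(self, inner):
                self.inner, self.jitters = inner, []

            def normal(self, loc, scale, size=None):
                v = self.inner.normal(loc, scale, size)
                if size is None:
                    self.jitters.append(v)
                return v

        rng = TapRng(np.random.default_rng(12))
        curves = [
            simulate_curve(wt_duplexes, params, rng, f"W{i:02d}", f"S{i:02d}")
            for i in range(48)
        ]
        overlaid, shifts, flagged = preprocess_curves(curves)
        assert not flagged
        injected = np.array(rng.jitters)
        recovered = np.array([shifts[f"W{i:02d}"] for i in range(48)])
        # the overlay can only recover jitter up to the plate mean
        err = (recovered - injected) - np.mean(recovered - injected)
        assert np.corrcoef(recovered, injected)[0, 1] > 0.99
        assert np.sqrt(np.mean(err**2)) < 0.1

    def test_overlay_reduces_between_well_variance(
        self, toy_amplicon, wt_duplexes, default_params
    ):
        params = dataclasses.replace(default_params, well_temp_jitter_sd=0.15)
        rng = np.random.default_rng(5)
        curves = [
            simulate_curve(wt_duplexes, params, rng, f"W{i:02d}", f"S{i:02d}")
            for i in range(48)
        ]
        cursors = auto_cursors(curves[0])
        norm = [
            normalize_curve(exponential_background_subtract(c, cursors), cursors)
            for c in curves
        ]
        overlaid, _, _ = temperature_overlay(norm, threshold_pct=10.0)
        var_before = np.var(np.vstack([c.values for c in norm]), axis=0).max()
        var_after = np.var(np.vstack([c.values for c in overlaid]), axis=0).max()
        assert var_after <= var_before

    def test_flat_curve_flagged_not_fatal(self, wt_duplexes, default_params):
        norm, _ = _quiet_norm(wt_duplexes, default_params)
        flat = MeltCurve("FLAT", "S", "normalized", GRID.copy(), np.full_like(GRID, 50.0))
        overlaid, shifts, flagged = temperature_overlay([norm, flat])
        assert flagged == ["FLAT"]
        assert norm.well_id in shifts


class TestTmEstimation:
    def test_recovers_model_tm(self, wt_duplexes, default_params):
        norm, _ = _quiet_norm(wt_duplexes, default_params)
        est = tm_from_curve(norm)
        assert est == pytest.approx(wt_duplexes[0].tm, abs=0.1)

    def test_mirror_symmetry_of_grid_convention(self, wt_duplexes, default_params):
        norm, _ = _quiet_norm(wt_duplexes, default_params)
        mirrored = MeltCurve(
            "M", "S", "normalized",
            -norm.temperatures[::-1].copy(), norm.values[::-1].copy(),
        )
        assert tm_from_curve(mirrored) == pytest.approx(-tm_from_curve(norm), abs=1e-6)

    def test_homozygote_tm_shift_matches_nn_sign(
        self, toy_amplicon, default_params
    ):
        """hom-alt vs hom-ref curve Tm difference has the NN-predicted sign."""
        from meltscan.amplicons import SequenceVariant
        from meltscan.simulate import duplexes_for_sample

        p = dataclasses.replace(default_params, noise_sd=0.0, well_temp_jitter_sd=0.0)
        pos = 150
        ref = toy_amplicon.sequence[pos]
        alt = "G" if ref != "G" else "C"
        var = SequenceVariant(pos, ref, alt, zygosity="hom_alt")
        rng = np.random.default_rng(0)
        hom_alt = duplexes_for_sample(toy_amplicon, [var], p, rng)
        hom_ref = duplexes_for_sample(toy_amplicon, [dataclasses.replace(var, zygosity="hom_ref")], p, rng)
        predicted = hom_alt[0].tm - hom_ref[0].tm
        est = []
        for species in (hom_alt, hom_ref):
            raw = simulate_curve(species, p, np.random.default_rng(0))
            cursors = auto_cursors(raw)
            norm = normalize_curve(
                exponential_background_subtract(raw, cursors), cursors
            )
            est.append(tm_from_curve(norm))
        assert np.sign(est[0] - est[1]) == np.sign(predicted)

    def test_flat_curve_rejected(self):
        flat = MeltCurve("W", "S", "normalized", GRID.copy(), np.zeros_like(GRID))
        with pytest.raises(CurveAnalysisError, match="flat|transition"):
            tm_from_curve(flat)


class TestDifferenceCurves:
    def test_reference_of_itself_is_zero(self, wt_duplexes, default_params):
        norm, _ = _quiet_norm(wt_duplexes, default_params)
        ref = mean_reference([norm])
        delta = difference_curve(norm, ref)
        assert np.allclose(delta.delta_percent, 0.0, atol=1e-12)

    def test_deltas_sum_to_zero_over_reference_wells(
        self, toy_amplicon, wt_duplexes, default_params
    ):
        rng = np.random.default_rng(9)
        curves = [
            simulate_curve(wt_duplexes, default_params, rng, f"W{i}", f"S{i}")
            for i in range(12)
        ]
        overlaid, _, _ = preprocess_curves(curves)
        ref = mean_reference(overlaid)
        deltas = [difference_curve(c, ref).delta_percent for c in overlaid]
        assert np.allclose(np.sum(deltas, axis=0), 0.0, atol=1e-9)

    def test_grid_mismatch_rejected(self, wt_duplexes, default_params):
        norm, _ = _quiet_norm(wt_duplexes, default_params)
        other = MeltCurve("X", "S", "normalized", GRID[:-1].copy() + 0.05,
                          norm.values[:-1].copy())
        ref = mean_reference([norm])
        with pytest.raises(CurveAnalysisError, match="grid"):
            difference_curve(other, ref)
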
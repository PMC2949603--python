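"""The melt-curve analysis chain.

Raw fluorescence is dominated by the temperature-dependent decay of the
saturating dye.  Scanning analysis therefore proceeds:

1. exponential background subtraction (EBS) anchored on a pre-melt and a
   post-melt cursor window,
2. normalization of the corrected curve to 0-100%,
3. temperature overlay — shifting each curve along T so its low-fluorescence
   threshold crossing coincides with the reference crossing, removing
   well-to-well calibration offsets so only shape differences remain,
4. difference ("subtraction-plot") curves against the mean wild-type curve.

Tolerances used for model-class identities and recovery checks are module
constants rather than scattered literals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import CurveAnalysisError
from .simulate import MeltCurve

#: relative tolerance for identities that hold exactly on the model class
MODEL_CLASS_RTOL = 1e-6
#: RMS tolerance (fraction of signal) for component-recovery checks
RECOVERY_RMS_TOL = 0.01
#: default width (°C) of the least-squares smoothing window
SMOOTH_WINDOW_C = 1.0
#: default cursor-window width (°C); wide windows condition the slope
#: estimates of the background fit against instrument noise
CURSOR_WIDTH_C = 4.0
#: default overlay threshold for the bare overlay operation (%)
OVERLAY_THRESHOLD_PCT = 5.0
#: overlay threshold used by the analysis pipeline: 10% sits on the steep
#: flank of the transition, where the crossing is least perturbed by residual
#: background-fit curvature
PIPELINE_OVERLAY_THRESHOLD_PCT = 10.0


@dataclass(frozen=True)
class CursorPair:
    """Pre-melt and post-melt cursor windows, [T_a, T_b] and [T_c, T_d] °C."""

    lower_window: tuple[float, float]
    upper_window: tuple[float, float]

    def __post_init__(self) -> None:
        t_a, t_b = self.lower_window
        t_c, t_d = self.upper_window
        if not t_a < t_b < t_c < t_d:
            raise CurveAnalysisError(
                f"cursor windows must be ordered: {t_a} < {t_b} < {t_c} < {t_d}"
            )


@dataclass
class DifferenceCurve:
    """A sample's overlaid curve minus the mean wild-type curve (% points)."""

    well_id: str
    sample_id: str
    temperatures: np.ndarray
    delta_percent: np.ndarray
    reference_id: str

    @property
    def max_abs(self) -> float:
        return float(np.max(np.abs(self.delta_percent)))

    def max_abs_in(self, window: tuple[float, float] | None) -> float:
        """Max |Δ| restricted to a temperature window (full range if None).

        Calling metrics are evaluated between the cursor windows: outside
        them the background fit is extrapolated and edge artifacts dominate.
        """
        if window is None:
            return self.max_abs
        mask = (self.temperatures >= window[0]) & (self.temperatures <= window[1])
        if not mask.any():
            return self.max_abs
        return float(np.max(np.abs(self.delta_percent[mask])))

    @property
    def signed_area(self) -> float:
        return float(np.trapezoid(self.delta_percent, self.temperatures))


def _window_mask(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < 3:
        raise CurveAnalysisError(f"cursor window {window} covers < 3 grid points")
    return mask


def _ls_slope(t: np.ndarray, y: np.ndarray) -> float:
    """Least-squares line slope over a window (the smoothed slope estimate)."""
    t_c = t - t.mean()
    return float(np.dot(t_c, y - y.mean()) / np.dot(t_c, t_c))


def auto_cursors(
    curve: MeltCurve, width: float = CURSOR_WIDTH_C
) -> CursorPair:
    """Place cursor windows at the flattest spans of the first and last thirds.

    'Flattest' means the span where the local log-slope of the fluorescence is
    most nearly constant (minimum variance of d log F / dT), i.e. the region
    best described by a pure exponential.
    """
    t, f = curve.temperatures, curve.values
    if np.any(f <= 0):
        # log-slope undefined; fall back to the outermost spans
        return CursorPair(
            (t[0], t[0] + width), (t[-1] - width, t[-1])
        )
    logf = np.log(f)
    step = float(np.median(np.diff(t)))
    k = max(2, int(round(width / step)))
    dlog = np.diff(logf) / np.diff(t)

    def flattest(lo: int, hi: int) -> tuple[float, float]:
        best, best_var = lo, np.inf
        for i in range(lo, max(lo + 1, hi - k)):
            var = float(np.var(dlog[i : i + k]))
            if var < best_var:
                best, best_var = i, var
        return float(t[best]), float(t[best] + width)

    third = len(t) // 3
    lower = flattest(0, third)
    upper = flattest(len(t) - third, len(t) - 1)
    return CursorPair(lower, upper)


def exponential_background_subtract(
    curve: MeltCurve, cursors: CursorPair | None = None
) -> MeltCurve:
    """Subtract an exponential dye background B(T) = a·exp(c·T).

    The decay constant comes from the ratio of the smoothed (least-squares
    line) fluorescence slopes in the two cursor windows,
    c = ln(s_U/s_L)/(T_U − T_L); the amplitude a is fixed so that the same
    least-squares slope estimator applied to B over the lower window
    reproduces s_L.  On a pure exponential input the residual is zero to
    rounding.
    """
    if curve.stage != "raw":
        raise CurveAnalysisError(f"expected a raw curve, got stage {curve.stage!r}")
    if cursors is None:
        cursors = auto_cursors(curve)
    t, f = curve.temperatures, curve.values
    lo = _window_mask(t, cursors.lower_window)
    hi = _window_mask(t, cursors.upper_window)
    if np.any(f[lo] <= 0) or np.any(f[hi] <= 0):
        raise CurveAnalysisError("fluorescence must be positive in cursor windows")
    s_l = _ls_slope(t[lo], f[lo])
    s_u = _ls_slope(t[hi], f[hi])
    if s_l >= 0 or s_u >= 0:
        raise CurveAnalysisError(
            f"cursor-window slopes must be negative (decaying dye); got "
            f"{s_l:.4g} / {s_u:.4g}"
        )
    ratio = s_u / s_l
    if ratio <= 0:
        raise CurveAnalysisError("slope ratio must be positive")
    t_l = float(t[lo].mean())
    t_u = float(t[hi].mean())
    c = np.log(ratio) / (t_u - t_l)
    # scale a so the discrete slope estimator is self-consistent with s_L
    model_slope = _ls_slope(t[lo], np.exp(c * t[lo]))
    a = s_l / model_slope
    background = a * np.exp(c * t)
    return curve.with_values(f - background, "bg_corrected")


def normalize_curve(curve: MeltCurve, cursors: CursorPair) -> MeltCurve:
    """Scale a background-corrected curve to 0-100%.

    100% is the mean corrected fluorescence over the pre-melt window, 0% the
    mean over the post-melt window.
    """
    if curve.stage not in ("bg_corrected", "normalized"):
        raise CurveAnalysisError(
            f"expected a bg_corrected curve, got stage {curve.stage!r}"
        )
    t, f = curve.temperatures, curve.values
    f_pre = float(f[_window_mask(t, cursors.lower_window)].mean())
    f_post = float(f[_window_mask(t, cursors.upper_window)].mean())
    if f_pre <= f_post:
        raise CurveAnalysisError(
            f"degenerate dynamic range: pre-melt mean {f_pre:.4g} <= "
            f"post-melt mean {f_post:.4g}"
        )
    return curve.with_values(100.0 * (f - f_post) / (f_pre - f_post), "normalized")


def _smooth(values: np.ndarray, t: np.ndarray, window_c: float) -> np.ndarray:
    step = float(np.median(np.diff(t)))
    w = max(5, int(round(window_c / step)) | 1)  # odd, >= 5
    w = min(w, len(values) if len(values) % 2 else len(values) - 1)
    return savgol_filter(values, w, polyorder=2)


def _threshold_crossings(
    t: np.ndarray, values: np.ndarray, threshold: float
) -> list[float]:
    """Interpolated temperatures of downward crossings of the threshold."""
    above = values > threshold
    crossings = []
    for i in range(len(t) - 1):
        if above[i] and not above[i + 1]:
            frac = (values[i] - threshold) / (values[i] - values[i + 1])
            crossings.append(float(t[i] + frac * (t[i + 1] - t[i])))
    return crossings


def overlay_shift(
    curve: MeltCurve,
    threshold_pct: float = OVERLAY_THRESHOLD_PCT,
    smooth_window: float = SMOOTH_WINDOW_C,
) -> float:
    """Temperature of the curve's single threshold crossing in its upper tail.

    Raises
    ------
    CurveAnalysisError
        If the smoothed curve crosses the threshold zero times or more than
        once (un-overlayable well).
    """
    smoothed = _smooth(curve.values, curve.temperatures, smooth_window)
    crossings = _threshold_crossings(curve.temperatures, smoothed, threshold_pct)
    if len(crossings) != 1:
        raise CurveAnalysisError(
            f"well {curve.well_id}: {len(crossings)} threshold crossings "
            f"at {threshold_pct}% (need exactly 1)"
        )
    return crossings[0]


def temperature_overlay(
    curves: list[MeltCurve],
    threshold_pct: float = OVERLAY_THRESHOLD_PCT,
    reference_wells: list[str] | None = None,
    smooth_window: float = SMOOTH_WINDOW_C,
) -> tuple[list[MeltCurve], dict[str, float], list[str]]:
    """Shift curves along T so their threshold crossings coincide.

    The reference crossing is the mean crossing of ``reference_wells`` (all
    wells if None).  Returns the overlaid curves (re-interpolated onto the
    common grid), the per-well shift applied, and the well ids flagged
    un-overlayable (returned unshifted and excluded from the reference).
    """
    crossings: dict[str, float] = {}
    flagged: list[str] = []
    for c in curves:
        try:
            crossings[c.well_id] = overlay_shift(c, threshold_pct, smooth_window)
        except CurveAnalysisError:
            flagged.append(c.well_id)
    ref_ids = reference_wells or [w for w in crossings]
    ref_vals = [crossings[w] for w in ref_ids if w in crossings]
    if not ref_vals:
        raise CurveAnalysisError("no overlayable reference wells")
    ref_crossing = float(np.mean(ref_vals))
    overlaid, shifts = [], {}
    for c in curves:
        if c.well_id not in crossings:
            overlaid.append(c.with_values(c.values.copy(), "overlaid"))
            continue
        shift = ref_crossing - crossings[c.well_id]
        shifts[c.well_id] = shift
        shifted = np.interp(
            c.temperatures,
            c.temperatures + shift,
            c.values,
            left=c.values[0],
            right=c.values[-1],
        )
        overlaid.append(c.with_values(shifted, "overlaid"))
    return overlaid, shifts, flagged


def tm_from_curve(
    curve: MeltCurve, smooth_window: float = SMOOTH_WINDOW_C
) -> float:
    """Melt temperature as the extremum of |dM/dT|, quadratically interpolated.

    The derivative is estimated with a Savitzky-Golay filter (window
    ``smooth_window`` °C, quadratic), which is a windowed least-squares slope
    and robust to grid-level noise.
    """
    t, values = curve.temperatures, curve.values
    if float(np.ptp(values)) < 1e-9:
        raise CurveAnalysisError("flat curve: no melt transition to locate")
    step = float(np.median(np.diff(t)))
    w = max(5, int(round(smooth_window / step)) | 1)
    w = min(w, len(values) if len(values) % 2 else len(values) - 1)
    neg_deriv = np.abs(savgol_filter(values, w, polyorder=2, deriv=1, delta=step))
    i = int(np.argmax(neg_deriv))
    if 0 < i < len(t) - 1:
        y0, y1, y2 = neg_deriv[i - 1 : i + 2]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-12:
            offset = 0.5 * (y0 - y2) / denom
            return float(t[i] + np.clip(offset, -1, 1) * step)
    return float(t[i])


def mean_reference(
    curves: list[MeltCurve], well_ids: list[str] | None = None
) -> MeltCurve:
    """Pointwise mean curve over the given wells (all wells if None)."""
    selected = [
        c for c in curves if well_ids is None or c.well_id in set(well_ids)
    ]
    if not selected:
        raise CurveAnalysisError("no wells selected for the reference curve")
    grid = selected[0].temperatures
    for c in selected[1:]:
        if not np.array_equal(c.temperatures, grid):
            raise CurveAnalysisError("reference wells must share a grid")
    values = np.mean([c.values for c in selected], axis=0)
    return MeltCurve("REF", "REF", selected[0].stage, grid.copy(), values)


def difference_curve(curve: MeltCurve, reference: MeltCurve) -> DifferenceCurve:
    """Subtraction-plot curve: sample minus mean wild-type, percentage points."""
    if not np.array_equal(curve.temperatures, reference.temperatures):
        raise CurveAnalysisError(
            f"grid mismatch between {curve.well_id} and reference"
        )
    return DifferenceCurve(
        well_id=curve.well_id,
        sample_id=curve.sample_id,
        temperatures=curve.temperatures.copy(),
        delta_percent=curve.values - reference.values,
        reference_id=reference.well_id,
    )


def preprocess_curves(
    curves: list[MeltCurve],
    cursors: CursorPair | None = None,
    threshold_pct: float = PIPELINE_OVERLAY_THRESHOLD_PCT,
) -> tuple[list[MeltCurve], dict[str, float], list[str]]:
    """EBS → normalize → overlay for a set of raw curves sharing a grid.

    Cursors are auto-placed on the first curve when not supplied; the same
    cursors are used for every well so the stages are comparable.
    """
    if not curves:
        raise CurveAnalysisError("no curves to preprocess")
    if cursors is None:
        cursors = auto_cursors(curves[0])
    normalized, failed = [], []
    for c in curves:
        try:
            normalized.append(
                normalize_curve(exponential_background_subtract(c, cursors), cursors)
            )
        except CurveAnalysisError:
            # a well whose background cannot be fit (e.g. noise swamping the
            # post-melt decay) is flagged un-analyzable, not fatal to the plate
            failed.append(c.well_id)
    if not normalized:
        raise CurveAnalysisError("no analyzable curves on this plate")
    overlaid, shifts, flagged = temperature_overlay(normalized, threshold_pct)
    return overlaid, shifts, failed + flagged
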
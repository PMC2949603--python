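"""Positive calling on subtraction plots, the two-step screen, SNP filtering.

A well is called positive when its difference curve departs from the plate's
wild-type cluster by more than a robust threshold (median + k·MAD of the
per-well max |Δ| metric).  Screening runs in two passes: every sample is
assayed once, first positives are re-assayed (fresh instrument noise, same
genotype) and only wells positive twice go to sequencing.  Sequencing is an
oracle lookup in the simulation's ground truth.  Recurrent identical base
changes are strain polymorphisms, not induced mutations: any exact change
confirmed at least ``snp_min_count`` times (default 3, i.e. "more than two")
is reclassified as an SNP, either across the whole screen or within each
plate independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .amplicons import AmpliconDef, SequenceVariant
from .errors import CallingError
from .preprocess import (
    DifferenceCurve,
    auto_cursors,
    difference_curve,
    mean_reference,
    preprocess_curves,
)
from .simulate import (
    GroundTruth,
    MeltCurve,
    MeltModelParams,
    Plate,
    TillingLibrarySpec,
    resimulate_wells,
)

#: k multipliers for the named caller sensitivities
SENSITIVITY_K = {"high": 2.5, "normal": 4.0}
#: absolute floor (percentage points) below which no well is called positive
ABS_FLOOR_PCT = 0.5
#: MAD -> sigma scale for a normal distribution
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class WellCall:
    well_id: str
    sample_id: str
    metric_max_abs: float  # percentage points
    metric_signed_area: float  # % * degC
    label: str  # wildtype | positive
    step: str  # first | second
    plate_id: str = ""
    threshold: float = float("nan")


@dataclass
class ConfirmedVariant:
    sample_id: str
    amplicon: str
    variant: SequenceVariant
    plate_id: str
    classification: str | None = None  # mutation | snp
    occurrence_count: int = 0

    def change_key(self) -> tuple[str, int, str, str]:
        v = self.variant
        return (self.amplicon, v.position, v.ref_base, v.alt_base)


@dataclass
class ScreenResult:
    first_calls: list[WellCall] = field(default_factory=list)
    second_calls: list[WellCall] = field(default_factory=list)
    confirmed: list[ConfirmedVariant] = field(default_factory=list)

    @property
    def first_positive_samples(self) -> set[str]:
        return {c.sample_id for c in self.first_calls if c.label == "positive"}

    @property
    def second_positive_samples(self) -> set[str]:
        return {c.sample_id for c in self.second_calls if c.label == "positive"}


def _resolve_k(sensitivity) -> float:
    if isinstance(sensitivity, str):
        try:
            return SENSITIVITY_K[sensitivity]
        except KeyError:
            raise CallingError(
                f"sensitivity must be one of {sorted(SENSITIVITY_K)} or a number"
            ) from None
    k = float(sensitivity)
    if k <= 0:
        raise CallingError("numeric sensitivity k must be positive")
    return k


def plate_difference_curves(
    curves: list[MeltCurve],
    abs_floor: float = ABS_FLOOR_PCT,
    metric_window: tuple[float, float] | None = None,
) -> tuple[list[DifferenceCurve], list[str]]:
    """Difference curves of a plate against its most-common-genotype reference.

    The wild type is taken as the largest cluster: wells whose maximum
    deviation from the pointwise median curve (within ``metric_window``) stays
    below the absolute floor.  Their pointwise mean is the reference every
    well is subtracted from.
    """
    if len(curves) < 8:
        raise CallingError("need >= 8 wells per plate to estimate the wild type")
    grid = curves[0].temperatures
    matrix = np.vstack([c.values for c in curves])
    median_curve = np.median(matrix, axis=0)
    if metric_window is not None:
        sel = (grid >= metric_window[0]) & (grid <= metric_window[1])
        if not sel.any():
            sel = np.ones_like(grid, dtype=bool)
    else:
        sel = np.ones_like(grid, dtype=bool)
    dev = np.max(np.abs(matrix[:, sel] - median_curve[sel]), axis=1)
    wt_ids = [c.well_id for c, d in zip(curves, dev) if d <= abs_floor]
    if not wt_ids:  # fall back: the closest half of the plate
        order = np.argsort(dev)
        wt_ids = [curves[i].well_id for i in order[: max(4, len(curves) // 2)]]
    reference = mean_reference(curves, wt_ids)
    assert np.array_equal(reference.temperatures, grid)
    return [difference_curve(c, reference) for c in curves], wt_ids


def call_positives(
    diff_curves: list[DifferenceCurve],
    sensitivity="high",
    abs_floor: float = ABS_FLOOR_PCT,
    step: str = "first",
    plate_id: str = "",
    metric_window: tuple[float, float] | None = None,
) -> list[WellCall]:
    """Flag wells whose max |Δ| exceeds the plate's robust threshold.

    The threshold is median + k·MAD (MAD normal-scaled) of the metric over
    all wells, never below ``abs_floor``; k = 2.5 for 'high' sensitivity,
    4 for 'normal', or any positive number.  The metric is evaluated inside
    ``metric_window`` (between the cursors) when given.
    """
    if len(diff_curves) < 8:
        raise CallingError("need >= 8 wells per plate to estimate the spread")
    k = _resolve_k(sensitivity)
    metrics = np.array([d.max_abs_in(metric_window) for d in diff_curves])
    med = float(np.median(metrics))
    mad = MAD_SCALE * float(np.median(np.abs(metrics - med)))
    threshold = max(med + k * mad, abs_floor) if mad > 0 else max(med, abs_floor)
    calls = []
    for d, m in zip(diff_curves, metrics):
        calls.append(
            WellCall(
                well_id=d.well_id,
                sample_id=d.sample_id,
                metric_max_abs=float(m),
                metric_signed_area=d.signed_area,
                label="positive" if m > threshold else "wildtype",
                step=step,
                plate_id=plate_id,
                threshold=threshold,
            )
        )
    return calls


def cluster_wells(
    diff_curves: list[DifferenceCurve], cut: float
) -> dict[str, int]:
    """Agglomerative (complete-linkage) grouping on max |Δdelta| distance.

    An optional subtraction-plot-style cluster view; the pipeline itself uses
    the threshold caller.  Returns well_id -> cluster label, with the largest
    cluster labeled 1.
    """
    if len(diff_curves) < 2:
        return {d.well_id: 1 for d in diff_curves}
    matrix = np.vstack([d.delta_percent for d in diff_curves])
    dist = pdist(matrix, metric="chebyshev")
    labels = fcluster(linkage(dist, method="complete"), t=cut, criterion="distance")
    sizes = {lab: int(np.sum(labels == lab)) for lab in set(labels)}
    order = sorted(sizes, key=lambda lab: -sizes[lab])
    relabel = {lab: i + 1 for i, lab in enumerate(order)}
    return {
        d.well_id: relabel[lab] for d, lab in zip(diff_curves, labels)
    }


def screen_plate(
    plate: Plate,
    sensitivity="high",
    abs_floor: float = ABS_FLOOR_PCT,
    step: str = "first",
) -> list[WellCall]:
    """Preprocess one plate's raw curves and call positives.

    The calling metric is restricted to the span between the two cursor
    windows, where the background model is interpolated rather than
    extrapolated.
    """
    cursors = auto_cursors(plate.curves[0])
    window = (cursors.lower_window[1], cursors.upper_window[0])
    overlaid, _, flagged = preprocess_curves(plate.curves, cursors)
    good = [c for c in overlaid if c.well_id not in set(flagged)]
    diffs, _ = plate_difference_curves(good, abs_floor, window)
    return call_positives(diffs, sensitivity, abs_floor, step, plate.plate_id, window)


def two_step_screen(
    plates: list[Plate],
    truth: GroundTruth | None,
    spec: TillingLibrarySpec,
    params: MeltModelParams,
    rng: np.random.Generator | int | None = None,
    sensitivity="high",
    abs_floor: float = ABS_FLOOR_PCT,
) -> ScreenResult:
    """Run the full two-step screen over a simulated library.

    Step 1 calls every well on every plate.  Step 2 re-assays the first
    positives per amplicon (fresh noise, same genotypes) on plates padded with
    the lowest-metric step-1 wells so the wild-type cluster stays defined, and
    re-calls.  Second positives are "sequenced" against the ground truth,
    which is the simulation's stand-in for Sanger confirmation.
    """
    if not plates:
        raise CallingError("need at least one plate")
    if truth is None:
        raise CallingError("ground truth required to confirm second positives")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    amp_by_name = {a.name: a for a in spec.amplicons}
    result = ScreenResult()
    first_by_amp: dict[str, list[WellCall]] = {}
    plate_of_sample: dict[tuple[str, str], str] = {}
    for plate in plates:
        calls = screen_plate(plate, sensitivity, abs_floor, "first")
        result.first_calls.extend(calls)
        first_by_amp.setdefault(plate.amplicon, []).extend(calls)
        for c in calls:
            plate_of_sample[(c.sample_id, plate.amplicon)] = plate.plate_id
    for amp_name, calls in first_by_amp.items():
        positives = [c for c in calls if c.label == "positive"]
        if not positives:
            continue
        amplicon = amp_by_name[amp_name]
        pos_ids = [c.sample_id for c in positives]
        fillers = sorted(
            (c for c in calls if c.label == "wildtype"),
            key=lambda c: c.metric_max_abs,
        )
        n_fill = max(0, min(spec.plate_size - len(pos_ids), len(fillers)))
        fill_ids = [c.sample_id for c in fillers[:n_fill]]
        rescreen = resimulate_wells(
            plates,
            truth,
            spec,
            params,
            pos_ids + fill_ids,
            amplicon,
            rng,
            plate_id=f"{amp_name}-R1",
        )
        calls2 = screen_plate(rescreen, sensitivity, abs_floor, "second")
        candidate = set(pos_ids)
        calls2 = [
            replace(c, label="wildtype") if c.sample_id not in candidate else c
            for c in calls2
        ]
        result.second_calls.extend(calls2)
        for c in calls2:
            if c.label != "positive":
                continue
            for v in truth.variants_for(c.sample_id, amp_name):
                if v.zygosity == "hom_ref":
                    continue
                result.confirmed.append(
                    ConfirmedVariant(
                        sample_id=c.sample_id,
                        amplicon=amp_name,
                        variant=v,
                        plate_id=plate_of_sample[(c.sample_id, amp_name)],
                    )
                )
    return result


def snp_filter(
    confirmed: list[ConfirmedVariant],
    scope: str = "global",
    snp_min_count: int = 3,
) -> list[ConfirmedVariant]:
    """Classify confirmed variants as induced mutations or strain SNPs.

    The same exact base change (amplicon, position, ref>alt) confirmed at
    least ``snp_min_count`` times is an SNP.  ``scope='global'`` counts across
    the whole screen; ``scope='per_plate'`` counts within each assay plate
    independently, which reproduces the misclassification of an SNP that
    happens to appear only once on a given plate.
    """
    if scope not in ("global", "per_plate"):
        raise CallingError(f"scope must be 'global' or 'per_plate', got {scope!r}")
    if snp_min_count < 1:
        raise CallingError("snp_min_count must be >= 1")
    counts: dict[tuple, int] = {}
    for cv in confirmed:
        key = cv.change_key() if scope == "global" else (cv.plate_id, *cv.change_key())
        counts[key] = counts.get(key, 0) + 1
    out = []
    for cv in confirmed:
        key = cv.change_key() if scope == "global" else (cv.plate_id, *cv.change_key())
        n = counts[key]
        out.append(
            replace(
                cv,
                occurrence_count=n,
                classification="snp" if n >= snp_min_count else "mutation",
            )
        )
    return out
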
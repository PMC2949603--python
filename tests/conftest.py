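"""Shared fixtures: a deterministic toy amplicon and plate builders."""

import numpy as np
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("deterministic", derandomize=True, deadline=None)
_hsettings.load_profile("deterministic")

from meltscan.amplicons import AmpliconDef, SequenceVariant
from meltscan.calling import screen_plate
from meltscan.simulate import (
    MeltModelParams,
    Plate,
    duplexes_for_sample,
    melt_domain,
    simulate_curve,
)
from meltscan.thermo import duplexes_for_alleles, fill_thermo

#: fixed 300-bp random sequence used as the standard toy amplicon
TOY_SEQ = "".join(np.random.default_rng(42).choice(list("ACGT"), 300))


@pytest.fixture(scope="session")
def toy_amplicon() -> AmpliconDef:
    """300-bp amplicon, scanned window [20, 280) (20-bp primer masks)."""
    return AmpliconDef(
        name="amp1",
        sequence=TOY_SEQ,
        scanned_window=(20, 280),
        primer_len_left=20,
        primer_len_right=20,
    )


@pytest.fixture(scope="session")
def default_params() -> MeltModelParams:
    return MeltModelParams()


@pytest.fixture(scope="session")
def wt_duplexes(toy_amplicon, default_params):
    """Thermo-filled wild-type duplex (the central melting domain)."""
    lo, hi = melt_domain(toy_amplicon, default_params)
    seq = toy_amplicon.sequence[lo:hi]
    return fill_thermo(duplexes_for_alleles(seq, seq))


def build_plate(
    amplicon,
    wt_duplexes,
    params,
    seed,
    mutants=(),
    n_wells=96,
    plate_id="P1",
):
    """A plate of wild-type wells with het mutants planted at given indices.

    ``mutants`` is a list of (well_index, SequenceVariant).
    """
    rng = np.random.default_rng(seed)
    curves = [
        simulate_curve(wt_duplexes, params, rng, f"W{i:02d}", f"S{i:02d}")
        for i in range(n_wells)
    ]
    for idx, variant in mutants:
        dup = duplexes_for_sample(amplicon, [variant], params, rng)
        curves[idx] = simulate_curve(dup, params, rng, f"W{idx:02d}", f"S{idx:02d}")
    layout = {c.well_id: c.sample_id for c in curves}
    return Plate(plate_id, amplicon.name, curves, layout)


def measure_power(
    amplicon, wt_duplexes, params, variant, n_plates=4, per_plate=8, seed0=900
):
    """Fraction of planted mutant wells called positive over replicate plates."""
    hits = total = 0
    for p in range(n_plates):
        mut_idx = list(range(0, 96, 12))[:per_plate]
        plate = build_plate(
            amplicon,
            wt_duplexes,
            params,
            seed0 + p,
            mutants=[(i, variant) for i in mut_idx],
        )
        calls = screen_plate(plate)
        positive = {c.well_id for c in calls if c.label == "positive"}
        hits += len(positive & {f"W{i:02d}" for i in mut_idx})
        total += per_plate
    return hits / total


def variant_at(amplicon, position, alt) -> SequenceVariant:
    return SequenceVariant(position, amplicon.sequence[position], alt)
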
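"""Synthetic plate-organized melting curves with ground truth.

This module stands in for the melting instrument and the real mutagenized
library: it draws heterozygous induced point mutations (Poisson per scanned
base) and strain SNP genotypes (Hardy-Weinberg at catalog allele frequencies)
for every F1 sample, organizes samples onto 96-well plates per amplicon, and
renders each well's fluorescence-vs-temperature curve as an exponential dye
background multiplying a weighted mixture of two-state duplex transitions,
plus per-well temperature jitter and additive Gaussian noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .amplicons import AmpliconDef, SequenceVariant, apply_variants
from .errors import ConfigError, MeltScanError
from .thermo import (
    DuplexSpecies,
    attenuate_towards,
    duplexes_for_alleles,
    fill_thermo,
    helicity,
)

STAGES = ("raw", "bg_corrected", "normalized", "overlaid", "difference")

#: Per-class substitution weights, keyed by (ref pair, alt pair).  ENU acts
#: mainly on A:T pairs; the biased preset reflects the A/T-targeted changes
#: dominating observed TILLING spectra, the uniform preset is the neutral
#: default.
SUBSTITUTION_SPECTRA: dict[str, dict[tuple[str, str], float]] = {
    "uniform": {
        ("AT", "TA"): 1.0,
        ("AT", "GC"): 1.0,
        ("AT", "CG"): 1.0,
        ("GC", "AT"): 1.0,
        ("GC", "TA"): 1.0,
        ("GC", "CG"): 1.0,
    },
    "enu_at_biased": {
        ("AT", "TA"): 0.42,
        ("AT", "GC"): 0.38,
        ("AT", "CG"): 0.06,
        ("GC", "AT"): 0.08,
        ("GC", "TA"): 0.04,
        ("GC", "CG"): 0.02,
    },
}

# alt base for a given ref base under a (ref-pair, alt-pair) class
_CLASS_ALT = {
    ("A", ("AT", "TA")): "T",
    ("A", ("AT", "GC")): "G",
    ("A", ("AT", "CG")): "C",
    ("T", ("AT", "TA")): "A",
    ("T", ("AT", "GC")): "C",
    ("T", ("AT", "CG")): "G",
    ("G", ("GC", "AT")): "A",
    ("G", ("GC", "TA")): "T",
    ("G", ("GC", "CG")): "C",
    ("C", ("GC", "AT")): "T",
    ("C", ("GC", "TA")): "A",
    ("C", ("GC", "CG")): "G",
}


@dataclass(frozen=True)
class MeltModelParams:
    """Instrument and melt-model parameters.

    Temperatures in °C.  The fluorescence model for one well is
    ``F(T) = bg_amplitude·exp(−bg_decay·(T−T₀)) ·
    [ss_floor + (ds_gain−ss_floor)·Σ_d w_d·θ_d(T+δT)] + ε(T)``
    with per-well temperature offset δT ~ N(0, well_temp_jitter_sd) and
    i.i.d. Gaussian noise ε.
    """

    t_start: float = 65.0
    t_stop: float = 98.0
    t_step: float = 0.1
    ramp_rate: float = 0.3  # °C/s, metadata only
    bg_amplitude: float = 100.0
    bg_decay: float = 0.02  # 1/°C
    ds_gain: float = 1.0
    ss_floor: float = 0.15
    noise_sd: float = 0.02
    well_temp_jitter_sd: float = 0.03
    end_attenuation: float = 0.3
    end_window_bp: int = 50
    salt_mM: float = 50.0
    strand_conc_nM: float = 50.0
    melt_domain_bp: int = 100
    vant_hoff_fraction: float = 1.0
    heteroduplex_fraction: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.t_start < self.t_stop and self.t_step > 0):
            raise ConfigError("temperature grid must be increasing")
        if self.noise_sd < 0 or self.well_temp_jitter_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if not 0.0 <= self.end_attenuation <= 1.0:
            raise ConfigError("end_attenuation must lie in [0, 1]")
        if self.ds_gain <= self.ss_floor:
            raise ConfigError("ds_gain must exceed ss_floor")
        if self.melt_domain_bp < 10:
            raise ConfigError("melt_domain_bp must be at least 10")

    @property
    def t_grid(self) -> np.ndarray:
        n = int(round((self.t_stop - self.t_start) / self.t_step)) + 1
        return self.t_start + self.t_step * np.arange(n)


@dataclass
class MeltCurve:
    """One well's temperature/fluorescence series at a given analysis stage."""

    well_id: str
    sample_id: str
    stage: str
    temperatures: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in STAGES:
            raise MeltScanError(f"unknown stage {self.stage!r}")
        if self.temperatures.ndim != 1 or len(self.temperatures) < 2:
            raise MeltScanError("need a 1-D temperature grid of length >= 2")
        if np.any(np.diff(self.temperatures) <= 0):
            raise MeltScanError("temperatures must be strictly increasing")
        if self.values.shape != self.temperatures.shape:
            raise MeltScanError("values and temperatures must align")

    def with_values(self, values: np.ndarray, stage: str) -> "MeltCurve":
        return MeltCurve(
            self.well_id, self.sample_id, stage, self.temperatures.copy(), values
        )


@dataclass(frozen=True)
class SNPCatalogEntry:
    variant: SequenceVariant
    allele_frequency: float

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_frequency < 1.0:
            raise ConfigError("allele frequency must lie in (0, 1)")


@dataclass(frozen=True)
class TillingLibrarySpec:
    """Composition of the synthetic mutagenized F1 library."""

    n_samples: int
    amplicons: tuple[AmpliconDef, ...]
    mutation_rate_per_bp: float = 1.0 / 314206.0
    snp_catalog: tuple[tuple[str, SNPCatalogEntry], ...] = ()
    plate_size: int = 96
    substitution_spectrum: str = "uniform"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("need at least one sample")
        if not self.amplicons:
            raise ConfigError("need at least one amplicon")
        if not 0.0 <= self.mutation_rate_per_bp < 0.01:
            raise ConfigError("mutation_rate_per_bp must be small and >= 0")
        if self.plate_size < 8:
            raise ConfigError("plate_size must be at least 8")
        if self.substitution_spectrum not in SUBSTITUTION_SPECTRA:
            raise ConfigError(
                f"unknown substitution spectrum {self.substitution_spectrum!r}"
            )


@dataclass(frozen=True)
class GroundTruthRecord:
    sample_id: str
    amplicon: str
    variant: SequenceVariant
    distance_to_end: int


@dataclass
class GroundTruth:
    """Variants actually planted per (sample, amplicon), for oracle lookup."""

    records: list[GroundTruthRecord] = field(default_factory=list)

    def variants_for(self, sample_id: str, amplicon: str) -> list[SequenceVariant]:
        return [
            r.variant
            for r in self.records
            if r.sample_id == sample_id and r.amplicon == amplicon
        ]

    def samples_with_variants(self, amplicon: str | None = None) -> set[str]:
        return {
            r.sample_id
            for r in self.records
            if amplicon is None or r.amplicon == amplicon
        }

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class Plate:
    """One assay plate: the amplicon scanned, its wells, and the layout."""

    plate_id: str
    amplicon: str
    curves: list[MeltCurve]
    layout: dict[str, str]  # well_id -> sample_id


def simulate_curve(
    duplexes: list[DuplexSpecies],
    params: MeltModelParams,
    rng: np.random.Generator,
    well_id: str = "A01",
    sample_id: str = "S0001",
) -> MeltCurve:
    """Render one well's raw fluorescence curve from its duplex mixture."""
    if not duplexes:
        raise MeltScanError("empty duplex list")
    weights = np.array([d.weight for d in duplexes])
    if abs(weights.sum() - 1.0) > 1e-9:
        raise MeltScanError(f"duplex weights sum to {weights.sum():.6f}, not 1")
    t = params.t_grid
    delta_t = (
        rng.normal(0.0, params.well_temp_jitter_sd)
        if params.well_temp_jitter_sd > 0
        else 0.0
    )
    theta_mix = np.zeros_like(t)
    for d in duplexes:
        theta_mix += d.weight * helicity(d, t + delta_t, params.vant_hoff_fraction)
    background = params.bg_amplitude * np.exp(-params.bg_decay * (t - t[0]))
    signal = params.ss_floor + (params.ds_gain - params.ss_floor) * theta_mix
    values = background * signal
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=t.shape)
    return MeltCurve(well_id, sample_id, "raw", t, values)


def _draw_alt_base(ref: str, weights: dict[tuple[str, str], float], rng) -> str:
    classes = [c for c in weights if _CLASS_ALT.get((ref, c)) is not None]
    w = np.array([weights[c] for c in classes], dtype=float)
    w = w / w.sum()
    choice = classes[rng.choice(len(classes), p=w)]
    return _CLASS_ALT[(ref, choice)]


def draw_sample_variants(
    spec: TillingLibrarySpec, amplicon: AmpliconDef, rng: np.random.Generator
) -> list[SequenceVariant]:
    """Induced mutations (Poisson) plus SNP genotypes for one sample/amplicon.

    Only variant-carrying genotypes are returned: an SNP drawn hom_ref is
    absent, one drawn het/hom_alt is included with that zygosity.
    """
    start, end = amplicon.scanned_window
    weights = SUBSTITUTION_SPECTRA[spec.substitution_spectrum]
    variants: list[SequenceVariant] = []
    n_mut = rng.poisson(spec.mutation_rate_per_bp * amplicon.scanned_length)
    taken: set[int] = set()
    for _ in range(n_mut):
        pos = int(rng.integers(start, end))
        if pos in taken:
            continue
        taken.add(pos)
        ref = amplicon.sequence[pos]
        alt = _draw_alt_base(ref, weights, rng)
        variants.append(
            SequenceVariant(pos, ref, alt, origin="induced_mutation", zygosity="het")
        )
    for amp_name, entry in spec.snp_catalog:
        if amp_name != amplicon.name or entry.variant.position in taken:
            continue
        p = entry.allele_frequency
        u = rng.random()
        if u < p * p:
            zyg = "hom_alt"
        elif u < p * p + 2 * p * (1 - p):
            zyg = "het"
        else:
            continue
        taken.add(entry.variant.position)
        variants.append(dataclasses.replace(entry.variant, origin="snp", zygosity=zyg))
    return variants


def melt_domain(
    amplicon: AmpliconDef, params: MeltModelParams, center: int | None = None
) -> tuple[int, int]:
    """Bounds of the cooperative melting domain rendered for one well.

    Long amplicons do not melt as a single two-state unit: the observable
    transition is dominated by a local cooperative domain, and a mismatch
    perturbs that domain rather than the average of the whole product.  The
    simulated transition therefore uses a ``melt_domain_bp`` window centered
    on the variant (or on the scanned window for wild type), clipped to the
    amplicon.
    """
    n = len(amplicon.sequence)
    width = min(params.melt_domain_bp, n)
    if center is None:
        center = (amplicon.scanned_window[0] + amplicon.scanned_window[1]) // 2
    lo = int(np.clip(center - width // 2, 0, n - width))
    return lo, lo + width


def duplexes_for_sample(
    amplicon: AmpliconDef,
    variants: list[SequenceVariant],
    params: MeltModelParams,
    rng: np.random.Generator,
) -> list[DuplexSpecies]:
    """Thermo-filled duplex mixture for a sample's genotype on one amplicon.

    Heterozygous variants are phased onto the two alleles at random (each het
    variant flips a fair coin); homozygous alt variants go on both.  The
    mixture is evaluated over the melting domain containing the variants
    (variants outside one domain width of each other are only partially
    modeled).  Variants within ``end_window_bp`` of a scanned-window edge
    have every species' Tm deviation from the wild-type Tm multiplied by
    ``end_attenuation``, emulating the reduced sensitivity of the assay near
    amplicon ends.
    """
    allele_a: list[SequenceVariant] = []
    allele_b: list[SequenceVariant] = []
    for v in variants:
        if v.zygosity == "hom_alt":
            allele_a.append(v)
            allele_b.append(v)
        elif v.zygosity == "het":
            (allele_a if rng.random() < 0.5 else allele_b).append(v)
        # hom_ref carries nothing
    carried = allele_a + allele_b
    center = (
        int(round(np.mean([v.position for v in carried]))) if carried else None
    )
    lo, hi = melt_domain(amplicon, params, center)
    seq_a = apply_variants(amplicon.sequence, allele_a)[lo:hi]
    seq_b = apply_variants(amplicon.sequence, allele_b)[lo:hi]
    species = fill_thermo(
        duplexes_for_alleles(seq_a, seq_b, params.heteroduplex_fraction),
        params.salt_mM,
        params.strand_conc_nM,
    )
    near_end = [
        v
        for v in variants
        if v.zygosity != "hom_ref"
        and amplicon.distance_to_window_end(v.position) < params.end_window_bp
    ]
    if near_end and params.end_attenuation < 1.0 and len(species) > 1:
        tm_ref = fill_thermo(
            duplexes_for_alleles(
                amplicon.sequence[lo:hi], amplicon.sequence[lo:hi]
            ),
            params.salt_mM,
            params.strand_conc_nM,
        )[0].tm
        species = attenuate_towards(species, tm_ref, params.end_attenuation)
    return species


def well_name(index: int, plate_size: int = 96) -> str:
    """Row-major well label (A01..H12 on a 96-well plate)."""
    n_cols = 12 if plate_size % 8 == 0 else plate_size
    row, col = divmod(index, n_cols)
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def simulate_library(
    spec: TillingLibrarySpec,
    params: MeltModelParams,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[Plate], GroundTruth]:
    """Generate the full screen: per-amplicon plates of raw curves + truth.

    Each sample is assayed once per amplicon; samples fill 96-well plates in
    order.  The same seed reproduces both the plates and the ground truth.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng if rng is not None else params.seed)
    sample_ids = [f"S{i + 1:05d}" for i in range(spec.n_samples)]
    truth = GroundTruth()
    genotypes: dict[tuple[str, str], list[SequenceVariant]] = {}
    for amplicon in spec.amplicons:
        for sid in sample_ids:
            variants = draw_sample_variants(spec, amplicon, rng)
            genotypes[(sid, amplicon.name)] = variants
            for v in variants:
                truth.records.append(
                    GroundTruthRecord(
                        sid,
                        amplicon.name,
                        v,
                        amplicon.distance_to_window_end(v.position),
                    )
                )
    plates: list[Plate] = []
    for amplicon in spec.amplicons:
        thermo_cache: dict[tuple, list] = {}
        for p_idx in range(0, spec.n_samples, spec.plate_size):
            batch = sample_ids[p_idx : p_idx + spec.plate_size]
            plate_id = f"{amplicon.name}-P{p_idx // spec.plate_size + 1:02d}"
            curves, layout = [], {}
            for w_idx, sid in enumerate(batch):
                well = f"{plate_id}:{well_name(w_idx, spec.plate_size)}"
                variants = genotypes[(sid, amplicon.name)]
                key = tuple(sorted((v.key(), v.zygosity) for v in variants))
                if key not in thermo_cache or any(
                    v.zygosity == "het" and len(variants) > 1 for v in variants
                ):
                    thermo_cache[key] = duplexes_for_sample(
                        amplicon, variants, params, rng
                    )
                curves.append(
                    simulate_curve(thermo_cache[key], params, rng, well, sid)
                )
                layout[well] = sid
            plates.append(Plate(plate_id, amplicon.name, curves, layout))
    return plates, truth


def resimulate_wells(
    plates: list[Plate],
    truth: GroundTruth,
    spec: TillingLibrarySpec,
    params: MeltModelParams,
    sample_ids: list[str],
    amplicon: AmpliconDef,
    rng: np.random.Generator,
    plate_id: str = "RESCREEN",
) -> Plate:
    """Fresh-noise re-assay of selected samples on one amplicon (same genotypes)."""
    curves, layout = [], {}
    for w_idx, sid in enumerate(sample_ids):
        variants = [
            r.variant
            for r in truth.records
            if r.sample_id == sid and r.amplicon == amplicon.name
        ]
        well = f"{plate_id}:{well_name(w_idx, spec.plate_size)}"
        duplexes = duplexes_for_sample(amplicon, variants, params, rng)
        curves.append(simulate_curve(duplexes, params, rng, well, sid))
        layout[well] = sid
    return Plate(plate_id, amplicon.name, curves, layout)
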
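"""Nearest-neighbor duplex thermodynamics and the two-state melt transition.

A heterozygous PCR product, after the final denature/re-anneal step, is an
equal mixture of four duplex species: two perfectly matched homoduplexes
(wild/wild and mutant/mutant) and two heteroduplexes carrying a single internal
mismatch.  Each species gets a ΔH/ΔS/Tm from unified nearest-neighbor stack
parameters plus internal-mismatch parameters (tables taken from
``Bio.SeqUtils.MeltingTemp``), and contributes a two-state van't Hoff melt
transition to the observed fluorescence curve.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
from Bio.SeqUtils import MeltingTemp as mt

from .amplicons import AmpliconDef, SequenceVariant, apply_variants, validate_variant
from .errors import ThermoError

R_GAS = 1.987  # cal / (mol K)
CELSIUS = 273.15

#: Unified nearest-neighbor stack parameters (SantaLucia & Hicks 2004 set).
NN_TABLE = mt.DNA_NN4
#: Internal single-mismatch parameters (Allawi & SantaLucia; Peyret et al.).
IMM_TABLE = mt.DNA_IMM1

_PAIRED = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass(frozen=True)
class DuplexSpecies:
    """One strand pairing of a (possibly mismatched) amplicon duplex.

    ``top_strand`` runs 5'→3'; ``bottom_strand`` is index-aligned with it and
    therefore runs 3'→5' (the convention of Biopython's ``c_seq``).
    ``mismatch_positions`` are the aligned offsets where the two strands do not
    form a Watson-Crick pair.  ``weight`` is the species' fraction of the total
    duplex population for one genotype.
    """

    top_strand: str
    bottom_strand: str
    mismatch_positions: frozenset[int]
    weight: float
    dH: float | None = None  # kcal/mol, negative for a stable duplex
    dS: float | None = None  # cal/(mol K), salt-corrected
    tm: float | None = None  # deg C

    def __post_init__(self) -> None:
        if len(self.top_strand) != len(self.bottom_strand):
            raise ThermoError("strands must be equal length (no dangling ends)")
        if not 0.0 <= self.weight <= 1.0:
            raise ThermoError(f"weight {self.weight} outside [0, 1]")
        observed = frozenset(
            i
            for i, (t, b) in enumerate(zip(self.top_strand, self.bottom_strand))
            if (t, b) not in _PAIRED
        )
        if observed != self.mismatch_positions:
            raise ThermoError(
                f"mismatch_positions {sorted(self.mismatch_positions)} do not "
                f"match strand pair (observed {sorted(observed)})"
            )


def _complement_aligned(seq: str) -> str:
    """Complement without reversal: the bottom strand aligned to the top."""
    return seq.translate(str.maketrans("ACGT", "TGCA"))


def duplexes_for_alleles(
    allele_a: str, allele_b: str, heteroduplex_fraction: float = 0.5
) -> list[DuplexSpecies]:
    """Enumerate duplex species formed by re-annealing two allele sequences.

    Identical alleles give one perfectly matched species (weight 1).  Distinct
    alleles give four species: both homoduplexes and both heteroduplexes, the
    latter carrying the heteroduplex_fraction of the population (0.5 under
    complete re-annealing randomization, i.e. weights 0.25 each).
    """
    if len(allele_a) != len(allele_b):
        raise ThermoError("alleles must have equal length")
    if allele_a == allele_b:
        return [
            DuplexSpecies(
                top_strand=allele_a,
                bottom_strand=_complement_aligned(allele_a),
                mismatch_positions=frozenset(),
                weight=1.0,
            )
        ]
    if not 0.0 <= heteroduplex_fraction <= 1.0:
        raise ThermoError("heteroduplex_fraction must lie in [0, 1]")
    w_het = heteroduplex_fraction / 2.0
    w_hom = (1.0 - heteroduplex_fraction) / 2.0
    species = []
    for top, bottom_src, weight in (
        (allele_a, allele_a, w_hom),
        (allele_b, allele_b, w_hom),
        (allele_a, allele_b, w_het),
        (allele_b, allele_a, w_het),
    ):
        bottom = _complement_aligned(bottom_src)
        mismatches = frozenset(
            i for i, (x, y) in enumerate(zip(top, bottom_src)) if x != y
        )
        species.append(
            DuplexSpecies(
                top_strand=top,
                bottom_strand=bottom,
                mismatch_positions=mismatches,
                weight=weight,
            )
        )
    return species


def duplexes_for_genotype(
    amplicon: AmpliconDef,
    variant: SequenceVariant | None,
    zygosity: str | None = None,
    heteroduplex_fraction: float = 0.5,
) -> list[DuplexSpecies]:
    """Duplex species for a genotype carrying at most one variant.

    hom_ref (or no variant) → one matched species; het → four species (two
    homoduplexes, two single-mismatch heteroduplexes); hom_alt → one matched
    mutant species.
    """
    if variant is None:
        return duplexes_for_alleles(amplicon.sequence, amplicon.sequence)
    validate_variant(amplicon, variant)
    if not amplicon.in_scanned_window(variant.position):
        raise ThermoError(
            f"variant at {variant.position} outside scanned window "
            f"{amplicon.scanned_window} of {amplicon.name!r}"
        )
    zyg = zygosity or variant.zygosity
    ref_allele = amplicon.sequence
    alt_allele = apply_variants(amplicon.sequence, [variant])
    if zyg == "hom_ref":
        return duplexes_for_alleles(ref_allele, ref_allele)
    if zyg == "hom_alt":
        return duplexes_for_alleles(alt_allele, alt_allele)
    if zyg == "het":
        return duplexes_for_alleles(ref_allele, alt_allele, heteroduplex_fraction)
    raise ThermoError(f"unknown zygosity {zyg!r}")


def _nn_sums(top: str, bottom: str) -> tuple[float, float]:
    """Sum stack + mismatch + initiation ΔH (kcal/mol) and ΔS (cal/mol/K).

    Mirrors the accumulation used by ``Bio.SeqUtils.MeltingTemp.Tm_NN`` for an
    equal-length seq/c_seq pair so the two routes agree exactly on shared
    inputs.  Terminal mismatches are rejected: the scanning assay masks
    primer-proximal bases, so a variant can never sit on a duplex terminus.
    """
    n = len(top)
    if n < 2:
        raise ThermoError("duplex must be at least 2 bp")
    for idx in (0, n - 1):
        if (top[idx], bottom[idx]) not in _PAIRED:
            raise ThermoError(
                f"terminal mismatch at position {idx}; terminal-mismatch "
                "thermodynamics are not modeled"
            )
    d_h = NN_TABLE["init"][0]
    d_s = NN_TABLE["init"][1]
    has_gc = any(b in "GC" for b in top)
    key = "init_oneG/C" if has_gc else "init_allA/T"
    d_h += NN_TABLE[key][0]
    d_s += NN_TABLE[key][1]
    if top.startswith("T"):
        d_h += NN_TABLE["init_5T/A"][0]
        d_s += NN_TABLE["init_5T/A"][1]
    if top.endswith("A"):
        d_h += NN_TABLE["init_5T/A"][0]
        d_s += NN_TABLE["init_5T/A"][1]
    ends = top[0] + top[-1]
    n_at = ends.count("A") + ends.count("T")
    n_gc = ends.count("G") + ends.count("C")
    d_h += NN_TABLE["init_A/T"][0] * n_at + NN_TABLE["init_G/C"][0] * n_gc
    d_s += NN_TABLE["init_A/T"][1] * n_at + NN_TABLE["init_G/C"][1] * n_gc
    for i in range(n - 1):
        step = top[i : i + 2] + "/" + bottom[i : i + 2]
        if step in IMM_TABLE:
            vals = IMM_TABLE[step]
        elif step[::-1] in IMM_TABLE:
            vals = IMM_TABLE[step[::-1]]
        elif step in NN_TABLE:
            vals = NN_TABLE[step]
        elif step[::-1] in NN_TABLE:
            vals = NN_TABLE[step[::-1]]
        else:
            raise ThermoError(f"no nearest-neighbor parameters for step {step!r}")
        d_h += vals[0]
        d_s += vals[1]
    return d_h, d_s


def nn_thermo(
    duplex: DuplexSpecies, salt_mM: float = 50.0, strand_conc_nM: float = 50.0
) -> DuplexSpecies:
    """Fill ΔH, ΔS and Tm of a duplex species.

    ΔS receives the monovalent-salt entropy correction
    0.368·(N−1)·ln[Na+]; Tm = 1000·ΔH / (ΔS + R·ln(C_T/4)) − 273.15 for a
    non-self-complementary duplex at total strand concentration C_T.
    """
    if salt_mM <= 0 or strand_conc_nM <= 0:
        raise ThermoError("salt and strand concentrations must be positive")
    d_h, d_s = _nn_sums(duplex.top_strand, duplex.bottom_strand)
    d_s = d_s + 0.368 * (len(duplex.top_strand) - 1) * math.log(salt_mM / 1000.0)
    k = strand_conc_nM * 1e-9 / 4.0
    tm = (1000.0 * d_h) / (d_s + R_GAS * math.log(k)) - CELSIUS
    return replace(duplex, dH=d_h, dS=d_s, tm=tm)


def helicity(
    duplex: DuplexSpecies, temperature, vant_hoff_fraction: float = 1.0
):
    """Fraction of the duplex population still double-stranded at T (°C).

    Two-state van't Hoff transition centered on the duplex Tm:
    θ(T) = 1 / (1 + exp((ΔH_eff/R)(1/Tm − 1/T))) with ΔH_eff =
    vant_hoff_fraction·|ΔH|.  θ(Tm) = 0.5 by construction and θ is strictly
    decreasing in T.  ``vant_hoff_fraction`` < 1 broadens the transition to
    emulate the multi-domain melting of long amplicons.
    """
    if duplex.dH is None or duplex.tm is None:
        raise ThermoError("duplex thermodynamics not filled; call nn_thermo first")
    if vant_hoff_fraction <= 0:
        raise ThermoError("vant_hoff_fraction must be positive")
    t_k = np.asarray(temperature, dtype=float) + CELSIUS
    tm_k = duplex.tm + CELSIUS
    dh_eff = vant_hoff_fraction * abs(duplex.dH) * 1000.0  # cal/mol
    exponent = (dh_eff / R_GAS) * (1.0 / tm_k - 1.0 / t_k)
    theta = 1.0 / (1.0 + np.exp(np.clip(exponent, -700, 700)))
    if np.isscalar(temperature):
        return float(theta)
    return theta


def fill_thermo(
    duplexes: list[DuplexSpecies],
    salt_mM: float = 50.0,
    strand_conc_nM: float = 50.0,
) -> list[DuplexSpecies]:
    """nn_thermo over a genotype's species list."""
    return [nn_thermo(d, salt_mM, strand_conc_nM) for d in duplexes]


def attenuate_towards(
    duplexes: list[DuplexSpecies], tm_ref: float, factor: float
) -> list[DuplexSpecies]:
    """Shrink each species' Tm deviation from a reference Tm by ``factor``.

    Phenomenological model of the reduced melt-curve deviation produced by
    variants close to the scanned-window ends (factor 1 = no attenuation,
    0 = deviation fully suppressed).
    """
    if not 0.0 <= factor <= 1.0:
        raise ThermoError("attenuation factor must lie in [0, 1]")
    out = []
    for d in duplexes:
        if d.tm is None:
            raise ThermoError("thermo not filled")
        out.append(replace(d, tm=tm_ref + factor * (d.tm - tm_ref)))
    return out


def predicted_delta_tm(
    amplicon: AmpliconDef,
    variant: SequenceVariant,
    salt_mM: float = 50.0,
    strand_conc_nM: float = 50.0,
    domain_bp: int | None = 100,
) -> float:
    """Largest Tm depression (°C) among the heterozygote's non-reference species.

    A convenient scalar 'signal strength' for a planted variant: the matched
    homoduplex Tm minus the lowest species Tm of the heterozygous mixture,
    evaluated over the cooperative melting domain (``domain_bp`` window
    centered on the variant; None for the whole amplicon).
    """
    seq = amplicon.sequence
    lo, hi = 0, len(seq)
    if domain_bp is not None and domain_bp < len(seq):
        lo = min(max(0, variant.position - domain_bp // 2), len(seq) - domain_bp)
        hi = lo + domain_bp
    ref_seq = seq[lo:hi]
    alt_seq = (
        seq[: variant.position] + variant.alt_base + seq[variant.position + 1 :]
    )[lo:hi]
    ref = nn_thermo(
        duplexes_for_alleles(ref_seq, ref_seq)[0], salt_mM, strand_conc_nM
    )
    species = fill_thermo(
        duplexes_for_alleles(ref_seq, alt_seq), salt_mM, strand_conc_nM
    )
    return ref.tm - min(d.tm for d in species)
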
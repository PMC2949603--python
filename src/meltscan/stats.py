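"""Variant-effect annotation and screening summary statistics.

The screen's headline numbers: base pairs screened (scanned-window length ×
samples), confirmed mutation counts by effect class (stop / missense / silent
/ intron / splice), the library's mutation density as base pairs per mutation
(round to nearest), assay sensitivity as a floored percentage, and the
per-genome mutation-load extrapolation.  Also the simulation-mode evaluation
harness comparing confirmed calls against planted ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .amplicons import AmpliconDef, SequenceVariant, validate_variant
from .errors import AnnotationError, MeltScanError
from .simulate import GroundTruth
from .thermo import predicted_delta_tm

EFFECT_CLASSES = ("stop", "missense", "silent", "intron", "splice")
#: intronic bases at each exon boundary treated as splice-site (GT/AG rule)
SPLICE_WINDOW_BP = 2


@dataclass(frozen=True)
class LibrarySummary:
    """Per-gene (or total) row of the screening summary table."""

    gene: str
    exons_screened: int
    amplicons: int
    bp_screened: int
    stop: int
    missense: int
    silent: int
    intron: int
    splice: int

    @property
    def total_mutations(self) -> int:
        return self.stop + self.missense + self.silent + self.intron + self.splice

    @property
    def bp_per_mutation(self) -> int:
        return mutation_rate(self.bp_screened, self.total_mutations)


@dataclass(frozen=True)
class SensitivityReport:
    method: str
    detected: int
    total: int

    @property
    def percent(self) -> int:
        return sensitivity(self.detected, self.total)


def annotate_variant_effect(
    amplicon: AmpliconDef, variant: SequenceVariant
) -> str:
    """Classify a variant as stop / missense / silent / intron / splice.

    Exonic positions are translated in their annotated reading frame; the alt
    codon decides the class.  Intronic positions within SPLICE_WINDOW_BP of an
    exon boundary are splice-site changes, anything deeper is intron.
    """
    validate_variant(amplicon, variant)
    pos = variant.position
    segments = amplicon.exon_segments
    containing = next((s for s in segments if s.start <= pos < s.end), None)
    if containing is None:
        for s in segments:
            if 0 < pos - (s.end - 1) <= SPLICE_WINDOW_BP:
                return "splice"
            if 0 < s.start - pos <= SPLICE_WINDOW_BP:
                return "splice"
        return "intron"
    # build the concatenated CDS and locate the variant within it
    cds_parts, cds_pos, cumlen = [], None, 0
    phase0 = segments[0].frame
    for s in segments:
        expected = (3 - (cumlen - phase0) % 3) % 3 if cumlen else phase0
        if s.frame != expected:
            raise AnnotationError(
                f"frame of exon [{s.start},{s.end}) is {s.frame}, "
                f"expected {expected} from upstream segment lengths"
            )
        if s is containing:
            cds_pos = cumlen + (pos - s.start)
        cds_parts.append(amplicon.sequence[s.start : s.end])
        cumlen += len(s)
    cds = "".join(cds_parts)
    offset = cds_pos - phase0
    if offset < 0:
        raise AnnotationError("variant falls in a partial leading codon")
    codon_start = phase0 + 3 * (offset // 3)
    ref_codon = cds[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        raise AnnotationError("variant falls in a partial trailing codon")
    within = cds_pos - codon_start
    alt_codon = ref_codon[:within] + variant.alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == "*" and ref_aa != "*":
        return "stop"
    if alt_aa == ref_aa:
        return "silent"
    return "missense"


def bp_screened(amplicons, n_samples: int) -> int:
    """Total scanned bases: Σ scanned-window lengths × number of samples."""
    if n_samples < 0:
        raise MeltScanError("n_samples must be non-negative")
    return sum(a.scanned_length for a in amplicons) * n_samples


def mutation_rate(bp: int, n_mutations: int) -> int:
    """Base pairs screened per confirmed mutation, rounded to nearest."""
    if n_mutations < 1:
        raise MeltScanError("mutation rate undefined for zero mutations")
    # round-half-up matches the printed convention for .5 boundaries
    return int(math.floor(bp / n_mutations + 0.5))


def sensitivity(detected: int, total: int) -> int:
    """Detection sensitivity as an integer percent (floor of 100·d/t)."""
    if total < 1:
        raise MeltScanError("sensitivity undefined for an empty truth set")
    if not 0 <= detected <= total:
        raise MeltScanError(f"detected {detected} outside [0, {total}]")
    return (100 * detected) // total


def mutations_per_genome(bp_per_mutation: float, genome_size_bp: float) -> int:
    """Expected mutagen-induced load per F1 genome at the library's density."""
    if bp_per_mutation <= 0 or genome_size_bp <= 0:
        raise MeltScanError("both arguments must be positive")
    return int(math.floor(genome_size_bp / bp_per_mutation + 0.5))


def summarize_counts(rows: list[LibrarySummary]) -> pd.DataFrame:
    """Summary table with per-gene rows plus a computed total row."""
    if not rows:
        raise MeltScanError("no rows to summarize")
    records = []
    for r in rows:
        records.append(
            {
                "gene": r.gene,
                "exons_screened": r.exons_screened,
                "amplicons": r.amplicons,
                "bp_screened": r.bp_screened,
                "stop": r.stop,
                "missense": r.missense,
                "silent": r.silent,
                "intron": r.intron,
                "splice": r.splice,
                "total_mutations": r.total_mutations,
                "bp_per_mutation": r.bp_per_mutation,
            }
        )
    df = pd.DataFrame.from_records(records)
    total = LibrarySummary(
        gene="total",
        exons_screened=int(df["exons_screened"].sum()),
        amplicons=int(df["amplicons"].sum()),
        bp_screened=int(df["bp_screened"].sum()),
        stop=int(df["stop"].sum()),
        missense=int(df["missense"].sum()),
        silent=int(df["silent"].sum()),
        intron=int(df["intron"].sum()),
        splice=int(df["splice"].sum()),
    )
    df.loc[len(df)] = {
        "gene": total.gene,
        "exons_screened": total.exons_screened,
        "amplicons": total.amplicons,
        "bp_screened": total.bp_screened,
        "stop": total.stop,
        "missense": total.missense,
        "silent": total.silent,
        "intron": total.intron,
        "splice": total.splice,
        "total_mutations": total.total_mutations,
        "bp_per_mutation": total.bp_per_mutation,
    }
    return df


def reconstruct_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Recompute totals and rates from a raw counts table.

    Expects columns gene, exons_screened, amplicons, bp_screened, stop,
    missense, silent, intron, splice (one row per gene, no total row).
    """
    rows = [
        LibrarySummary(
            gene=str(rec.gene),
            exons_screened=int(rec.exons_screened),
            amplicons=int(rec.amplicons),
            bp_screened=int(rec.bp_screened),
            stop=int(rec.stop),
            missense=int(rec.missense),
            silent=int(rec.silent),
            intron=int(rec.intron),
            splice=int(rec.splice),
        )
        for rec in counts.itertuples()
    ]
    return summarize_counts(rows)


def load_medaka_screen_counts() -> pd.DataFrame:
    """Bundled per-gene counts from the medaka p53/atm/atr HRM screen."""
    with resources.files("meltscan.data").joinpath(
        "medaka_screen_counts.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_p53_variant_panel() -> pd.DataFrame:
    """Bundled p53 exon 5-6 variant panel with per-method detection flags."""
    with resources.files("meltscan.data").joinpath(
        "p53_variant_panel.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def detection_sensitivity(
    panel: pd.DataFrame, method: str, exclude_end_proximal: bool = False
) -> SensitivityReport:
    """Sensitivity of one detection method over a variant panel.

    The panel needs a ``{method}_detected`` flag column and, when excluding
    end-proximal variants, an ``end_proximal`` flag.  The truth set is every
    panel row (each row is a real variant confirmed by at least one method).
    """
    col = f"{method}_detected"
    if col not in panel.columns:
        raise MeltScanError(f"panel lacks a {col!r} column")
    rows = panel
    if exclude_end_proximal:
        rows = panel[panel["end_proximal"] == 0]
    return SensitivityReport(
        method=method, detected=int(rows[col].sum()), total=len(rows)
    )


@dataclass
class EvaluationReport:
    """Confusion summary of a simulated screen against its ground truth."""

    n_planted: int
    n_detected: int
    n_false_positive_wells: int
    per_variant: pd.DataFrame  # sample, amplicon, position, dtm, dist, detected
    power_by_dtm: pd.DataFrame
    power_by_distance: pd.DataFrame

    @property
    def power(self) -> float:
        return self.n_detected / self.n_planted if self.n_planted else float("nan")


def evaluate_screen(
    confirmed,
    truth: GroundTruth,
    amplicons,
    second_positive_samples: set[str] | None = None,
    dtm_bins=(0.0, 0.1, 0.2, 0.3, 0.5, np.inf),
    distance_bins=(0, 50, np.inf),
) -> EvaluationReport:
    """Per-variant detection outcomes and power binned by ΔTm and position.

    A planted heterozygous variant counts as detected when a confirmed record
    matches its sample, amplicon and base change.  False-positive wells are
    second positives whose sample carries no planted variant on that amplicon.
    """
    amp_by_name = {a.name: a for a in amplicons}
    confirmed_keys = {
        (cv.sample_id, cv.amplicon, *cv.variant.key()) for cv in confirmed
    }
    for cv in confirmed:
        if cv.amplicon not in amp_by_name:
            raise MeltScanError(f"confirmed variant on unknown amplicon {cv.amplicon!r}")
    rows = []
    for rec in truth.records:
        if rec.variant.zygosity == "hom_ref":
            continue
        amp = amp_by_name.get(rec.amplicon)
        if amp is None:
            raise MeltScanError(f"ground truth on unknown amplicon {rec.amplicon!r}")
        dtm = predicted_delta_tm(amp, rec.variant)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "amplicon": rec.amplicon,
                "position": rec.variant.position,
                "ref": rec.variant.ref_base,
                "alt": rec.variant.alt_base,
                "zygosity": rec.variant.zygosity,
                "origin": rec.variant.origin,
                "delta_tm": dtm,
                "distance_to_end": rec.distance_to_end,
                "detected": (rec.sample_id, rec.amplicon, *rec.variant.key())
                in confirmed_keys,
            }
        )
    per_variant = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "amplicon", "position", "ref", "alt", "zygosity",
            "origin", "delta_tm", "distance_to_end", "detected",
        ],
    )
    fp_wells = 0
    if second_positive_samples is not None:
        with_variants = truth.samples_with_variants()
        fp_wells = len(second_positive_samples - with_variants)

    def binned(values, bins, label):
        if per_variant.empty:
            return pd.DataFrame(columns=[label, "n", "detected", "power"])
        cats = pd.cut(values, bins=list(bins), right=False)
        grouped = per_variant.groupby(cats, observed=True)["detected"]
        out = grouped.agg(n="count", detected="sum").reset_index(names=label)
        out["power"] = out["detected"] / out["n"]
        return out

    return EvaluationReport(
        n_planted=len(per_variant),
        n_detected=int(per_variant["detected"].sum()) if len(per_variant) else 0,
        n_false_positive_wells=fp_wells,
        per_variant=per_variant,
        power_by_dtm=binned(per_variant.get("delta_tm"), dtm_bins, "delta_tm_bin"),
        power_by_distance=binned(
            per_variant.get("distance_to_end"), distance_bins, "distance_bin"
        ),
    )
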
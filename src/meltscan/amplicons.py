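"""Amplicon targets and sequence variants.

An amplicon is the PCR product scanned by the melt assay: the full sense-strand
sequence, the sub-interval actually scanned for variants (primer-proximal bases
are masked because mismatches there are poorly detected), and the coding-exon
segments needed for variant-effect annotation.  All coordinates are 0-based,
half-open; 1-based positions appear only in report output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AmpliconError

DNA_ALPHABET = frozenset("ACGT")
COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ExonSegment:
    """A CDS interval [start, end) with its reading-frame phase.

    ``frame`` follows the GFF convention: the number of bases at the start of
    the segment that complete the codon begun in the previous segment (0, 1
    or 2).
    """

    start: int
    end: int
    frame: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise AmpliconError(f"bad exon segment [{self.start}, {self.end})")
        if self.frame not in (0, 1, 2):
            raise AmpliconError(f"frame must be 0, 1 or 2, got {self.frame}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AmpliconDef:
    """A melt-scanned PCR amplicon.

    Parameters
    ----------
    name : str
        Identifier (used as the CHROM field in variant reports).
    sequence : str
        Uppercase sense-strand DNA of the full PCR product.
    scanned_window : tuple of int
        [start, end) offsets of the region screened for variants.
    exon_segments : tuple of ExonSegment
        Disjoint, sorted CDS intervals used for effect annotation.
    primer_len_left, primer_len_right : int
        Bases masked at each end (primer footprints).
    """

    name: str
    sequence: str
    scanned_window: tuple[int, int]
    exon_segments: tuple[ExonSegment, ...] = field(default_factory=tuple)
    primer_len_left: int = 0
    primer_len_right: int = 0

    def __post_init__(self) -> None:
        if not self.name:
            raise AmpliconError("amplicon needs a non-empty name")
        if not set(self.sequence) <= DNA_ALPHABET:
            bad = sorted(set(self.sequence) - DNA_ALPHABET)
            raise AmpliconError(f"non-ACGT characters in {self.name!r}: {bad}")
        start, end = self.scanned_window
        if not (0 <= start < end <= len(self.sequence)):
            raise AmpliconError(
                f"scanned_window {self.scanned_window} outside sequence of "
                f"length {len(self.sequence)}"
            )
        if self.primer_len_left < 0 or self.primer_len_right < 0:
            raise AmpliconError("primer lengths must be non-negative")
        prev_end = -1
        for seg in self.exon_segments:
            if seg.start < prev_end:
                raise AmpliconError("exon segments must be disjoint and sorted")
            if seg.end > len(self.sequence):
                raise AmpliconError("exon segment outside sequence")
            prev_end = seg.end

    @property
    def scanned_length(self) -> int:
        start, end = self.scanned_window
        return end - start

    def in_scanned_window(self, position: int) -> bool:
        start, end = self.scanned_window
        return start <= position < end

    def distance_to_window_end(self, position: int) -> int:
        """Distance (bp) from a position to the nearest scanned-window edge."""
        start, end = self.scanned_window
        return min(position - start, end - 1 - position)


@dataclass(frozen=True)
class SequenceVariant:
    """A single-base change within an amplicon.

    ``origin`` distinguishes mutagen-induced lesions (heterozygous in F1
    genomes) from strain polymorphisms segregating in the library.
    """

    position: int
    ref_base: str
    alt_base: str
    origin: str = "induced_mutation"  # or "snp"
    zygosity: str = "het"  # het | hom_ref | hom_alt

    def __post_init__(self) -> None:
        for b, label in ((self.ref_base, "ref"), (self.alt_base, "alt")):
            if b not in DNA_ALPHABET:
                raise AmpliconError(f"{label}_base must be one of ACGT, got {b!r}")
        if self.ref_base == self.alt_base:
            raise AmpliconError("ref_base and alt_base must differ")
        if self.origin not in ("induced_mutation", "snp"):
            raise AmpliconError(f"unknown origin {self.origin!r}")
        if self.zygosity not in ("het", "hom_ref", "hom_alt"):
            raise AmpliconError(f"unknown zygosity {self.zygosity!r}")

    def key(self) -> tuple[int, str, str]:
        """Identity of the base change (position, ref, alt)."""
        return (self.position, self.ref_base, self.alt_base)


def validate_variant(amplicon: AmpliconDef, variant: SequenceVariant) -> None:
    """Check that a variant is placeable on an amplicon.

    Raises
    ------
    AmpliconError
        If the position is outside the amplicon sequence or the stated
        reference base disagrees with the sequence.
    """
    if not 0 <= variant.position < len(amplicon.sequence):
        raise AmpliconError(
            f"variant position {variant.position} outside amplicon "
            f"{amplicon.name!r} (length {len(amplicon.sequence)})"
        )
    actual = amplicon.sequence[variant.position]
    if actual != variant.ref_base:
        raise AmpliconError(
            f"ref_base {variant.ref_base} does not match sequence base "
            f"{actual} at position {variant.position} of {amplicon.name!r}"
        )


def apply_variants(sequence: str, variants) -> str:
    """Return the sequence with each variant's alt base substituted."""
    seq = list(sequence)
    for v in variants:
        if seq[v.position] != v.ref_base:
            raise AmpliconError(
                f"ref mismatch at {v.position}: sequence has {seq[v.position]}"
            )
        seq[v.position] = v.alt_base
    return "".join(seq)
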
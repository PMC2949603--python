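"""Variant-effect annotation and screening summary arithmetic."""

import numpy as np
import pandas as pd
import pytest

from meltscan.amplicons import AmpliconDef, ExonSegment, SequenceVariant
from meltscan.errors import AnnotationError, MeltScanError
from meltscan.stats import (
    LibrarySummary,
    annotate_variant_effect,
    bp_screened,
    detection_sensitivity,
    evaluate_screen,
    load_medaka_screen_counts,
    load_p53_variant_panel,
    mutation_rate,
    mutations_per_genome,
    reconstruct_summary,
    sensitivity,
    summarize_counts,
)


def _coding_amplicon(context: str, phase: int, name="ctx") -> AmpliconDef:
    """One fully coding toy amplicon with the given starting phase."""
    return AmpliconDef(
        name, context, (0, len(context)),
        exon_segments=(ExonSegment(0, len(context), phase),),
    )


class TestEffectAnnotation:
    def test_nonsense_change_in_p53_context(self):
        """TAT→TAA at the Y186 codon: premature stop."""
        context = "TGGCCCAGTA" + "T" + "TTTGAAGACC"
        amp = _coding_amplicon(context, phase=2)  # codons start at offset 2
        assert annotate_variant_effect(amp, SequenceVariant(10, "T", "A")) == "stop"

    def test_third_position_degeneracy_is_silent(self):
        amp = _coding_amplicon("ATGCTGAAA", phase=0)  # M L K
        # CTG -> CTA still leucine
        assert annotate_variant_effect(amp, SequenceVariant(5, "G", "A")) == "silent"

    def test_amino_acid_change_is_missense(self):
        amp = _coding_amplicon("ATGCTGAAA", phase=0)
        # CTG -> CCG: Leu -> Pro
        assert annotate_variant_effect(amp, SequenceVariant(4, "T", "C")) == "missense"

    def test_splice_window_two_bp(self):
        seq = "GGAAACCGA" + "GTAAGTTTAGTC"  # exon | intron with GT donor
        amp = AmpliconDef(
            "sp", seq, (0, len(seq)), exon_segments=(ExonSegment(0, 9, 0),)
        )
        donor_plus2 = SequenceVariant(10, "T", "C")
        assert annotate_variant_effect(amp, donor_plus2) == "splice"
        deep = SequenceVariant(18, seq[18], "C" if seq[18] != "C" else "A")
        assert annotate_variant_effect(amp, deep) == "intron"

    def test_acceptor_side_splice(self):
        seq = "TTTTAG" + "ATGGGG"  # intron ...AG | exon
        amp = AmpliconDef(
            "acc", seq, (0, len(seq)), exon_segments=(ExonSegment(6, 12, 0),)
        )
        assert annotate_variant_effect(amp, SequenceVariant(4, "A", "T")) == "splice"
        assert annotate_variant_effect(amp, SequenceVariant(1, "T", "C")) == "intron"

    def test_inconsistent_frames_raise(self):
        amp = AmpliconDef(
            "bad", "ATGAAACCCGGGTTT", (0, 15),
            exon_segments=(ExonSegment(0, 7, 0), ExonSegment(9, 15, 0)),
        )  # second phase should be 2, not 0
        with pytest.raises(AnnotationError, match="frame"):
            annotate_variant_effect(amp, SequenceVariant(10, "G", "A"))

    def test_codon_spanning_two_exons(self):
        # CDS = ATG | AAA with the codon AAA split 2+1 across segments
        seq = "ATGAA" + "gttag".upper() + "ACCC"
        amp = AmpliconDef(
            "span", seq, (0, len(seq)),
            exon_segments=(ExonSegment(0, 5, 0), ExonSegment(10, 14, 1)),
        )
        # position 10 is the last base of the split AAA codon: AAA->AAC = K->N
        assert annotate_variant_effect(amp, SequenceVariant(10, "A", "C")) == "missense"

    def test_every_scanned_variant_gets_exactly_one_class(self, toy_amplicon):
        amp = AmpliconDef(
            toy_amplicon.name, toy_amplicon.sequence, toy_amplicon.scanned_window,
            exon_segments=(ExonSegment(60, 120, 0), ExonSegment(180, 240, 0)),
        )
        rng = np.random.default_rng(0)
        for _ in range(100):
            pos = int(rng.integers(20, 280))
            ref = amp.sequence[pos]
            alt = "ACGT"[(("ACGT".index(ref)) + 1) % 4]
            effect = annotate_variant_effect(amp, SequenceVariant(pos, ref, alt))
            assert effect in {"stop", "missense", "silent", "intron", "splice"}


class TestSummaryArithmetic:
    def test_bp_screened_examples(self, toy_amplicon):
        one = AmpliconDef("w", "A" * 300, (0, 295))
        assert bp_screened([one], 2) == 590
        assert bp_screened([], 10) == 0

    @pytest.mark.parametrize(
        "bp,n,expected",
        [
            (1_702_800, 5, 340_560),
            (7_837_612, 23, 340_766),  # 340765.7: forces round-to-nearest
            (7_740_932, 27, 286_701),
            (17_281_344, 55, 314_206),
            (100, 100, 1),
        ],
    )
    def test_bp_per_mutation_rounding(self, bp, n, expected):
        assert mutation_rate(bp, n) == expected

    def test_rate_undefined_for_zero_mutations(self):
        with pytest.raises(MeltScanError):
            mutation_rate(1000, 0)

    @pytest.mark.parametrize(
        "detected,total,expected", [(5, 8, 62), (6, 8, 75), (5, 6, 83), (0, 7, 0)]
    )
    def test_sensitivity_floor_percent(self, detected, total, expected):
        assert sensitivity(detected, total) == expected

    def test_sensitivity_bounds_checked(self):
        with pytest.raises(MeltScanError):
            sensitivity(9, 8)
        with pytest.raises(MeltScanError):
            sensitivity(0, 0)

    def test_mutations_per_genome(self):
        assert mutations_per_genome(314_206, 700_000_000) == 2228
        assert mutations_per_genome(12345, 12345) == 1
        assert mutations_per_genome(1000, 2_000_000) == 2 * mutations_per_genome(
            1000, 1_000_000
        )

    def test_summary_totals_and_rates(self):
        rows = [
            LibrarySummary("g1", 2, 1, 1000, 1, 1, 0, 0, 0),
            LibrarySummary("g2", 1, 1, 3000, 0, 2, 1, 0, 0),
        ]
        df = summarize_counts(rows)
        total = df[df.gene == "total"].iloc[0]
        assert total.total_mutations == 5
        assert total.bp_screened == 4000
        assert total.bp_per_mutation == 800
        for _, row in df.iterrows():
            assert row.total_mutations == (
                row.stop + row.missense + row.silent + row.intron + row.splice
            )


class TestBundledScreenTables:
    def test_counts_reconstruction_matches_published_cells(self):
        summary = reconstruct_summary(load_medaka_screen_counts())
        by_gene = summary.set_index("gene")
        assert by_gene.loc["p53", "bp_per_mutation"] == 340_560
        assert by_gene.loc["ATM", "bp_per_mutation"] == 286_701
        assert by_gene.loc["ATR", "bp_per_mutation"] == 340_766
        assert by_gene.loc["total", "total_mutations"] == 55
        assert by_gene.loc["total", "bp_per_mutation"] == 314_206

    def test_panel_sensitivities(self):
        panel = load_p53_variant_panel()
        assert detection_sensitivity(panel, "hrm").percent == 62
        assert detection_sensitivity(panel, "seq").percent == 75
        assert detection_sensitivity(panel, "hrm", exclude_end_proximal=True).percent == 83

    def test_panel_contexts_are_wellformed(self):
        panel = load_p53_variant_panel()
        for ctx in panel["context"]:
            left, rest = ctx.split("(")
            change, right = rest.split(")")
            ref, alt = change.split(">")
            assert set(left + right) <= set("ACGT")
            assert ref != alt and len(ref) == len(alt) == 1


class TestEvaluation:
    def test_perfect_caller_has_full_power_no_fp(self, toy_amplicon, default_params):
        from meltscan.calling import snp_filter, two_step_screen
        from meltscan.simulate import TillingLibrarySpec, simulate_library

        spec = TillingLibrarySpec(
            n_samples=192, amplicons=(toy_amplicon,), mutation_rate_per_bp=1 / 20000
        )
        plates, truth = simulate_library(spec, default_params, 21)
        result = two_step_screen(plates, truth, spec, default_params, 22)
        confirmed = snp_filter(result.confirmed)
        report = evaluate_screen(
            confirmed, truth, [toy_amplicon], result.second_positive_samples
        )
        assert report.n_planted > 0
        assert report.n_detected == report.n_planted
        assert report.n_false_positive_wells == 0

    def test_shuffled_truth_gives_chance_power(self, toy_amplicon, default_params):
        """Negative control: decoupling calls from truth destroys power."""
        from meltscan.calling import snp_filter, two_step_screen
        from meltscan.simulate import TillingLibrarySpec, simulate_library

        spec = TillingLibrarySpec(
            n_samples=192, amplicons=(toy_amplicon,), mutation_rate_per_bp=1 / 20000
        )
        plates, truth = simulate_library(spec, default_params, 21)
        result = two_step_screen(plates, truth, spec, default_params, 22)
        confirmed = snp_filter(result.confirmed)
        # reassign truth records to samples that were never called
        called = {cv.sample_id for cv in confirmed}
        free = [f"X{i}" for i in range(len(truth.records))]
        import dataclasses as dc

        shuffled = dc.replace(truth)
        shuffled.records = [
            dc.replace(r, sample_id=free[i]) for i, r in enumerate(truth.records)
        ]
        report = evaluate_screen(confirmed, shuffled, [toy_amplicon])
        assert report.n_detected == 0

    def test_id_mismatch_rejected(self, toy_amplicon):
        from meltscan.calling import ConfirmedVariant
        from meltscan.simulate import GroundTruth

        cv = ConfirmedVariant(
            "S1", "nonexistent", SequenceVariant(1, "A", "T"), "P1"
        )
        with pytest.raises(MeltScanError, match="unknown amplicon"):
            evaluate_screen([cv], GroundTruth(), [toy_amplicon])
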
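# Methods

This note documents the models, parameter choices and numerical decisions
behind `meltscan`, and what its synthetic experiments do and do not show.

## Duplex thermodynamics

Each duplex species (a top/bottom strand pairing, possibly mismatched) gets
ΔH and ΔS as sums over adjacent base-pair stacks using the unified
nearest-neighbor parameter set, with dedicated parameters for internal
single mismatches and the standard initiation/terminal terms. The parameter
tables are taken from `Bio.SeqUtils.MeltingTemp` (`DNA_NN4` stacks,
`DNA_IMM1` internal mismatches) and the accumulation mirrors Biopython's
`Tm_NN`, so the two routes agree to rounding; the test suite exploits this as
an independent cross-check, alongside a hand-frozen oracle value. Entropy
receives the monovalent-salt correction 0.368·(N−1)·ln[Na⁺], and

    Tm = 1000·ΔH / (ΔS + R·ln(C_T/4)) − 273.15

for a non-self-complementary duplex at total strand concentration C_T
(defaults: 50 mM Na⁺, 50 nM strands). Terminal mismatches are rejected
rather than silently mis-summed; they cannot arise in the pipeline because
variants are confined to the scanned window, which excludes primer-masked
ends.

A heterozygote is modeled as four species with weights 0.25 each (two
homoduplexes, two single-mismatch heteroduplexes), assuming complete
re-annealing randomization after the final denature/re-anneal step of the
PCR. The heteroduplex fraction is configurable
(`heteroduplex_fraction`, default 0.5) for partial re-annealing. Samples
carrying several heterozygous variants in one amplicon are phased randomly
onto two alleles and all four strand pairings are enumerated, so the
single-variant case is a special case of a general allele-pair model.

## The melt transition and the cooperative domain

Each species melts as a two-state van't Hoff transition,
θ(T) = 1/(1+exp((|ΔH|/R)(1/Tm − 1/T))), so θ(Tm) = 0.5 exactly and θ is
strictly decreasing. A multi-hundred-bp amplicon does not melt as one
two-state unit, and summing nearest-neighbor terms over the whole product
both dilutes a mismatch's effect (ΔTm ∝ 1/N) and produces an unphysically
sharp transition. The simulator therefore evaluates the duplex mixture over
a **cooperative melting domain** of `melt_domain_bp` (default 100 bp)
centered on the variant — the scanned-window center for wild type. This
yields heteroduplex Tm depressions of ~0.3–1.4 °C and a 10–90 % transition
width of ~1.3 °C, in the range instruments actually resolve, and
difference-plot amplitudes of roughly 2–20 percentage points for
heterozygotes. An optional `vant_hoff_fraction` (< 1) broadens transitions
further by scaling the effective enthalpy inside θ only; the default is 1
(pure two-state).

## The fluorescence model

    F(T) = bg_amplitude·e^(−bg_decay·(T−T₀)) ·
           [ss_floor + (ds_gain − ss_floor)·Σ_d w_d θ_d(T + δT_well)] + ε(T)

| parameter | default | meaning |
|---|---|---|
| `t_start`/`t_stop`/`t_step` | 65/98/0.1 °C | acquisition grid (ramp 0.3 °C/s; point density is an instrument unknown, 0.1 °C is the recorded guess) |
| `bg_amplitude`, `bg_decay` | 100, 0.02 /°C | exponential dye background |
| `ds_gain`, `ss_floor` | 1.0, 0.15 | fluorescence of fully double- vs single-stranded DNA (saturating dyes retain ~15 % residual signal) |
| `noise_sd` | 0.02 | additive Gaussian noise, ≈ 0.02 % of the initial amplitude — high-resolution-instrument optics |
| `well_temp_jitter_sd` | 0.03 °C | per-well temperature offset; HRM-class instruments quote Tm repeatability of 0.02–0.05 °C |
| `end_attenuation`, `end_window_bp` | 0.3, 50 bp | variants within 50 bp of a scanned-window end have their species' Tm deviations shrunk ×0.3 — a phenomenological model of the assay's reduced sensitivity near amplicon ends |
| `melt_domain_bp` | 100 bp | cooperative melting-domain width |
| `salt_mM`, `strand_conc_nM` | 50, 50 | thermodynamic conditions |

The well jitter enters the duplex term only (the offset perturbs the DNA's
melting, while the reported temperature axis and dye envelope are the
instrument's); this makes jittered curves *almost* pure translations after
normalization, with a small second-order envelope distortion that the
overlay cannot remove — a deliberate, realistic imperfection.

## Library generation

Each of `n_samples` F1 genomes draws, per amplicon,
Poisson(`mutation_rate_per_bp` × scanned bp) heterozygous induced mutations
at uniform positions (default rate 1/314,206 per bp, the density measured in
the medaka library), with substitution classes drawn from a configurable
spectrum: `uniform` over the six classes by default, plus an
`enu_at_biased` preset reflecting the A:T-targeted bias of ENU spectra.
SNP genotypes are drawn per catalog entry under Hardy–Weinberg at the given
allele frequency. Samples fill 96-well plates per amplicon in order; the
same seed reproduces plates and ground truth bit-for-bit.

## The analysis chain

**Exponential background subtraction.** B(T) = a·e^(cT) with
c = ln(s_U/s_L)/(T_U − T_L), where s_L, s_U are least-squares line slopes
over the pre- and post-melt cursor windows and T_L, T_U the window centers.
The amplitude a is fixed *self-consistently*: the same discrete
least-squares slope operator applied to B over the lower window must
reproduce s_L. On a pure exponential input the residual is then zero to
machine rounding (an analytic-derivative anchor would leave an O((λw)²)
residual). Non-negative window slopes (no dye decay to fit) are an error;
in plate processing such wells are flagged un-analyzable rather than failing
the plate. Cursor windows are auto-placed on the flattest spans (minimum
variance of d log F/dT) of the first and last thirds of the grid. The
default window width is 4 °C: with 2 °C windows the post-melt slope estimate
(small signal, ≈ −0.18 units/°C) is noisy enough that the extrapolated
background bows by ~1 % of the normalized scale, which the overlay then
amplifies into spurious calls.

**Normalization.** M(T) = 100·(F−F_post)/(F_pre−F_post) with F_pre/F_post
the mean corrected fluorescence over the cursor windows; window means land
at 100 %/0 % by construction, and re-normalizing is a no-op.

**Temperature overlay.** Each curve is shifted along T so its single
downward threshold crossing (linear interpolation on a 1 °C
Savitzky–Golay-smoothed curve) coincides with the reference crossing (mean
over designated wild-type wells, or all wells). Zero or multiple crossings
flag the well un-overlayable. The bare operation defaults to the
conventional 5 % threshold; the pipeline overlays at 10 %, which sits on the
steep flank of the transition where the crossing is least perturbed by
residual background curvature. Shifted curves are re-interpolated linearly
onto the common grid.

**Tm estimation.** The extremum of |dM/dT| from a Savitzky–Golay first
derivative (1 °C window, quadratic), refined by quadratic interpolation of
the three points around the peak; accurate to well under 0.1 °C on noiseless
two-state curves.

**Difference curves.** Sample minus the pointwise mean of the wild-type
(largest) cluster, in percentage points. The calling metric, max |Δ|, is
evaluated between the cursor windows — outside them the background model is
extrapolated and edge artifacts dominate.

## Calling, the two-step screen, the SNP filter

Per plate, the wild type is the largest cluster (wells within the absolute
floor of the pointwise median curve; their mean is the reference). A well is
positive when its max |Δ| exceeds median + k·MAD of the plate's metrics
(MAD normal-scaled), never less than an absolute floor of 0.5 percentage
points; k = 2.5 maps to the instrument's "high sensitivity", k = 4 to
normal, and k is freely configurable. The floor acts as a lower bound in all
cases so that clean plates do not fire on the tail of the max statistic. An
optional complete-linkage clustering on Chebyshev distance between
difference curves provides a subtraction-plot-style group view.

Step 2 re-assays the first positives (fresh noise, same genotypes) on plates
padded with the lowest-metric step-1 wells so the wild-type reference stays
defined; only wells positive twice are "sequenced", which in simulation is
an oracle lookup in the ground truth. The SNP filter then classifies any
exact base change confirmed ≥ `snp_min_count` times (default 3, i.e. "more
than two") as a strain polymorphism — counted across the whole screen
(`global`) or within each plate (`per_plate`), the latter reproducing the
misclassification of an SNP that happens to appear only once on one plate.

## Summary statistics

Effect annotation translates the variant codon in its annotated reading
frame (codons may span exon segments; inconsistent frames are an error);
intronic positions within 2 bp of an exon boundary are splice-site changes
(GT/AG rule; the window width is a choice, as published screens label such
variants simply "Splice"). Rates use round-to-nearest
(bp_screened/total mutations — forced by published cells such as
7,837,612/23 → 340,766), sensitivities use the floor of the percentage
(5/8 → 62 %), and the per-genome load is genome_size/bp_per_mutation with
genome size always a user input (700 Mb is used in examples as the medaka
assembly scale).

## What the synthetic experiments show — and don't

The generator reproduces the *structure* of a plate screen: duplex-mixture
curve shapes, background and noise, plate organization, end-of-amplicon
attenuation, recurrent SNPs versus unique induced mutations. Passing tests
therefore demonstrate that the analysis chain is internally consistent
(exact on its own model classes), that detection power behaves as the assay
does qualitatively (monotone in ΔTm, degrading with noise, weaker near
amplicon ends), and that the planted mutation density is recovered within
Poisson error through the full two-step screen (10 plates × 96 wells,
1/15,000 per bp — chosen so a run plants ~17 mutations and completes in
seconds). They do not demonstrate performance on real instrument exports:
real melts have multiple domains per amplicon, temperature-dependent dye
quantum yield, plate-edge effects and operator-drawn cluster boundaries,
none of which are modeled. The end-attenuation factor is phenomenological,
not mechanistic, and the detection-power numbers at the elevated noise used
in the power experiments characterize the simulator, not any instrument.

## Known limitations

- Homozygous variants are modeled (single shifted-Tm species) but the
  overlay deliberately removes pure Tm shifts, so they are usually invisible
  to the shape-based caller — as in real heteroduplex scanning.
- Variants farther apart than one melting domain in the same sample are only
  partially modeled (the domain is centered on their mean position).
- The step-2 re-assay assumes an independent noise draw on the same genotype;
  systematic per-sample artifacts (e.g. DNA quality) are not modeled.
- Sequencing confirmation is an oracle; a hook for real trace input exists
  but parsing chromatograms is out of scope.
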
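# Methods

This note documents the models, defaults, and numerical choices behind
`spddpcr`, and what its synthetic validation does and does not show.

## SuperSelective primer construction

Notation `A–B/C–f:1:t` is interpreted as: anchor length `A`, bridge
length `B` (primer side of the bubble), intervening template length `C`
(template side), and a foot of `f` matched bases 5' of the interrogated
nucleotide plus `t ∈ {0, 1}` matched bases 3' of it. The designer copies
the anchor from the template so that `A + C + f` bases separate the
anchor's 5' end from the variant, skips the `C` intervening bases, and
copies the foot with the interrogated position replaced by the mutant
allele. Reverse designs run the identical construction on the reverse
complement and are reported 5'→3'; a forward design on a template is
therefore identical to a reverse design on its reverse complement
(property-tested).

Generated bridges alternate A/T starting with A; if that start violates
the bubble-asymmetry check against the intervening bases, the T-start
alternation is tried; an explicit `bridge_override` always wins. The
published designs print both A-start and T-start bridges without a
stated rule, so the A-start preference is this package's own convention
(it reproduces the printed bridge wherever the printed segments are
internally consistent).

**Bubble asymmetry.** The bridge must not zip up against the intervening
template. We compute the longest contiguous Watson–Crick complementary
run between the two single strands in antiparallel register — equal to
the longest common substring of the bridge and the reverse complement of
the intervening bases — and fail the check when it exceeds 3 (the source
protocol says only "non-complementary"; 3 is this package's threshold,
chosen as the longest run that still cannot nucleate a stable stem at
60 °C annealing).

**Melting temperatures.** Nearest-neighbor thermodynamics (unified
Allawi–SantaLucia parameter set via Biopython), with defaults 50 mM
monovalent cation, 3 mM Mg²⁺ (folded into a sodium-equivalent entropy
correction), and 250 nM primer. For a SuperSelective primer only the
anchor contributes (anchor-only policy). The standard-pair designer
searches complementary primers of 18–28 nt with amplicon ≤ 100 bp and
accepts a Tm mismatch ≤ 2 °C. The 2 °C tolerance is a design choice
("same melting temperature" is stated without tolerance); all seven
published anchor/complementary pairs fall within it under this model
(largest observed difference 1.4 °C).

**Validation.** `validate_assay` never raises on a bad design: every
check (geometry, anchor match, foot match against mutant, exactly one
foot mismatch against wild-type at the interrogated position, bridge
length/composition/asymmetry, amplicon length, Tm match) is a report
entry. Checks are classed structural vs thermodynamic so that primers
transcribed from the published table — three of which carry typesetting
inconsistencies (bridge lengths that contradict their own notation for
two assays; one amplicon truncated so its stated 28-nt anchor cannot
fit) — can be represented verbatim and audited rather than silently
repaired.

**Specificity.** A local mismatch-tolerant sliding-window scan over
user-supplied FASTA references (both strands, defaults: ≤ 2 mismatches
total, perfect match over the 3'-terminal 5 bases), not a genome-scale
BLAST. For SuperSelective primers only anchor + foot is scanned; the
bridge never hybridizes. The scan is vectorized (numpy) and is checked
against an exhaustive pure-Python enumeration in the tests.

## Droplet simulator

The simulator emulates the plasmid-mixture characterization experiments:
`mutant = round(total · VAF/100)` molecules plus wild-type filler are
partitioned into droplets and counted in two channels.

- **Partitioning** is equal-probability multinomial over `n_droplets`
  (default 20,000 droplets of 0.85 nl in a 20 µl reaction). All input
  molecules land in accepted droplets (no dead volume, no droplet loss),
  so molecule conservation holds exactly and the empty-droplet fraction
  follows the Poisson limit `exp(−n/d)`. Because of this convention,
  parameter-recovery comparisons use `copies_in_partition`
  (λ · accepted); `copies_per_reaction` additionally applies the
  instrument-software volume scaling, which matters only for real
  exports where droplets do not hold the whole reaction.
- **Activation**: each mutant molecule renders its droplet positive in
  the SSP channel with probability `p_detect_mutant` (default 0.95);
  each wild-type molecule leaks through with `p_leak_wildtype` (default
  0.001); in the standard channel every molecule detects with
  `p_detect_standard` (default 0.95). Leak is per wild-type molecule, so
  the 0%-VAF background sits near a fixed VAF (≈ leak/detect ≈ 0.1%)
  rather than a fixed count — matching how the published per-assay
  backgrounds (means 0.03–0.19%) behave. The default leak is a
  calibration to the middle of that range, not a measured quantity.
- **Seeding**: a master seed deterministically spawns per-level,
  per-replicate, per-channel substreams (`numpy` `SeedSequence`);
  identical seeds give identical wells, byte-stable fixture files
  included.

What the simulator does **not** model: droplet-volume variation,
fluorescence amplitude and "rain" near threshold, PCR kinetics,
cross-reactivity between assays, or sample-quality effects. Passing
simulation-based tests therefore demonstrates that the quantification
pipeline is mathematically correct and unbiased under the stated
partitioning model — not that any particular wet-lab assay will achieve
these numbers.

## Quantification

- λ is estimated as `−ln(1 − positives/accepted)`; its 95% CI uses the
  delta method on the positive fraction (`var λ = p/((1−p)·n)`). A fully
  positive well is flagged saturated with an infinite sentinel rather
  than an error.
- VAF = 100 · SNV copies / total copies; values above 100% are returned
  with an over-unity warning. Read-based (sequencing) VAFs use the same
  formula with half-even rounding to 2 decimals at the report layer;
  all internal computation is full precision.
- Replicates aggregate as mean ± SEM with sample SD (n−1); a single
  replicate yields SD 0 with a warning instead of failing.
- LOD = mean + k·SD of blank measurements (k = 3); fewer than 9
  replicates sets a low-confidence flag but still returns an estimate.
  A measurement is called detected only when its mean VAF strictly
  exceeds the LOD (ties conservatively not detected).
- Dilution linearity uses ordinary least squares and Pearson r
  (two-sided p from t with n−2 df) on per-level replicate means.
- The qPCR comparator converts a Cq difference to VAF as
  `100 · E^(Cq_total − Cq_mutant)` with efficiency E ∈ (1, 2], default 2
  (perfect doubling); non-finite Cq maps to "not detected".
- 33 ng of genomic DNA at 3.3 pg per haploid genome ↔ 10,000 haploid
  genome equivalents.

## Prioritization

Hard filters (depth ≥ 10 reads; gnomAD max-population AF ≤ 0.05, missing
AF survives) precede the functional cascade (impact ∈ {MODERATE, HIGH};
≥ 3 of 5 predictor votes with strict thresholds, so boundary values do
not vote; COSMIC id present; WES VAF ≤ 10%). Missing annotations
conservatively fail the criterion that needs them and are marked
"missing" in the audit trail. The VAF cap is compared on the 2-decimal
rounded VAF and is configurable, because the published selection itself
retained one variant at 10.87%. Selected variants are ranked by (votes
descending, VAF ascending, genomic position) for deterministic output.
An optional `in_both_callers` boolean column stands in for the
Mutect2 ∩ Strelka intersection; the callers themselves are out of scope.

## Problem sizes and determinism in the test suite

The linearity check runs 100 seeded series of 5 levels × 3 replicate
well pairs (each 20,000 droplets) and requires Pearson R² ≥ 0.9645 —
the lower end of the published per-assay range — in at least 95% of
runs; observed 5th-percentile R² is ≈ 0.994. Parameter recovery uses
200 single-replicate runs at 5.61% truth with perfect selectivity.
Property tests (hypothesis) run derandomized with fixed profiles, and
all stochastic tests use fixed seeds, so the suite is deterministic.

## Known limitations

- Printed patient-sample VAFs (e.g. 34.70 ± 0.73% in a carcinoma) are
  carried as packaged reference values only; they require real DNA and
  are not recomputable.
- The Tm model is a standard nearest-neighbor calculation; it is not the
  tool the original primers were designed with, so standard-pair search
  results can differ from the published complementary primers while
  still meeting the same constraints.
- The leak/detection parameters are per-assay in reality but global in
  the simulator; no attempt is made to fit assay-specific backgrounds.
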
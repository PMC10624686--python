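# spddpcr

Design and quantification tooling for **SP-ddPCR**: the combination of
SuperSelective primers with droplet digital PCR to measure rare
single-nucleotide variants (SNVs) — down to variant allele frequencies
(VAFs) of a few tenths of a percent — in tumor and histologically normal
tissue.

## Who this is for

Molecular-biology groups who have a shortlist of somatic SNVs (typically
from whole-exome sequencing) and want to (a) design allele-selective
ddPCR assays for them, (b) quantify mutant and total copies from droplet
counts, and (c) decide, against a per-assay limit of detection, whether a
variant is truly present in a sample.

## The method

A **SuperSelective primer** has three parts, written
`anchor–bridge/intervening–f:1:t` (e.g. `21–7/8–5:1:1`):

- a long 5' **anchor** that hybridizes stably and sets the primer's
  effective melting temperature (computed from the anchor alone);
- a short 3' **foot** carrying the interrogated nucleotide (matching the
  *mutant* allele) that gates extension — a single mismatch against
  wild-type template suppresses amplification;
- an A/T **bridge** between them that forms an asymmetric single-stranded
  bubble with the `intervening` template bases, enforcing foot-dependent
  priming. Foot layouts `4:1:1`, `5:1:1` (interrogated base second-last)
  and `6:1:0` (last) are supported.

Total copies are measured with a standard pair that reuses the anchor
plus a Tm-matched complementary primer (amplicon ≤ 100 bp). Droplet
counts are converted to copies by Poisson occupancy correction,

```
λ = −ln(1 − positives/accepted),    VAF(%) = 100 · SNV copies / total copies
```

and each assay's limit of detection is `LOD = mean + 3·SD` of the VAF
measured in wild-type-only material over nine or more replicates.

The package also includes a droplet-partition simulator with known
ground truth (for validation and power exploration), a dilution-series
linearity fit (Pearson R² of measured vs expected VAF), a Cq-based qPCR
comparator, and the WES variant-prioritization cascade (read depth ≥ 10,
gnomAD max AF ≤ 0.05, SnpEff impact MODERATE/HIGH, ≥ 3 of 5 pathogenicity
predictors positive — PolyPhen > 0.85, LRT < 0.1, SIFT < 0.05, CADD > 15,
MutationTaster "D"/"D,D" — COSMIC membership, WES VAF ≤ 10%).

## Worked example

```python
from spddpcr import (AmpliconTemplate, VariantSpec, design_superselective,
                     parse_strategy, compute_vaf, estimate_lambda)
from spddpcr.published import assay_by_key

assay = assay_by_key("APC", "c.4128T>A")       # packaged reference assay
primer = design_superselective(assay.template(),
                               parse_strategy("21–7/8–5:1:1"), "forward")
print(primer.anchor, primer.bridge, primer.foot)
# GTGCTCAGACACCCAAAAGTC ATATATA CACTAAG
```

The designed primer reproduces the characterized assay: a 21-nt anchor, a
7-nt alternating bridge, and a 7-nt foot whose second-last base is the
variant (A) allele. Quantification from droplet counts:

```python
from spddpcr import WellCount, Channel
ssp = estimate_lambda(WellCount(520, 20_000, Channel.SSP))
std = estimate_lambda(WellCount(7869, 20_000, Channel.STANDARD))
print(f"{ssp.copies_in_partition:.0f} / {std.copies_in_partition:.0f} "
      f"= {compute_vaf(ssp.copies_in_partition, std.copies_in_partition):.2f}%")
# 527 / 9999 = 5.27%
```

520 positive droplets of 20,000 correspond to 527 mutant copies after
Poisson correction; against ~10,000 total copies that is a 5.27% VAF.

A command-line tool wraps the same functionality:

```
spddpcr --seed 7 simulate --vaf-levels 1.0,0.5,0.25,0.13,0 --out wells.csv
spddpcr quantify --wells wells.csv
spddpcr dilution --wells wells.csv --expected 1.0,0.5,0.25,0.13,0
spddpcr lod --wells background.csv --k 3 --min-n 9
spddpcr prioritize --variants calls.tsv --min-votes 3 --max-af 0.05 --max-vaf 10
spddpcr fixtures --out fixtures/
```

## File formats

- **FASTA** for templates and specificity references.
- **Assay sheet (TSV)**: `gene, hgvs_c, direction, strategy,
  ssp_sequence` (anchor-bridge-foot joined by `-`),
  `complementary_primer, standard_primer, amplicon` (with a `(ref/alt)`
  marker at the interrogated position).
- **Well counts (CSV)**: `well_id, scenario, channel, positives,
  accepted_droplets, seed`; instrument-style exports
  (`Well/Sample/Target/Positives/AcceptedDroplets`) are mapped
  automatically.
- **Variant tables**: TSV with the `AnnotatedVariant` schema, or a
  minimal SNV-only VCF with INFO keys `GENE, HGVSC, IMPACT, DP, VD,
  GNOMAD_AF, POLYPHEN, LRT, SIFT, CADD, MT, COSMIC`.
- **Run configuration**: TOML with sections `[run] [thermo] [partition]
  [selectivity] [lod] [prioritize]`; unknown keys are rejected.

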
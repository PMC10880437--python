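# Methods

## The problem

Tumor mutational burden (TMB) — the density of somatic mutations per
megabase of sequenced genome — is used clinically to select patients for
immune-checkpoint inhibition (the regulatory TMB-high bound is ≥ 10
mut/Mb). On a targeted panel without a matched normal, the raw variant
list mixes four populations: true somatic mutations, leaked germline
polymorphisms, fixation-induced deamination artifacts (for FFPE tissue),
and run-level systematic artifacts. TMB estimation is therefore a
filtering problem, and the score depends strongly on the filter
parameterization. `tmbkit` implements that filtering as a cascade of
independent per-variant predicates under named, fully explicit profiles,
plus the surrounding machinery: sample QC, VAF-sweep diagnostics, cohort
summaries, curation of TMB-high cases, and a ground-truthed simulator.

## Filter model

Each variant is evaluated by five pure predicates; retention is their
conjunction, so the outcome is independent of evaluation order. Attrition
reporting attributes each removal to the first failing stage in the fixed
order *quality → recurrence → germline → class/driver → VAF/depth*.

| Stage | IC profile (strict) | FO profile (permissive) |
|---|---|---|
| caller quality | — | PASS tag required |
| intra-run recurrence | remove if > 15% of run samples carry the variant | — |
| germline | any AF > 0.1% in 1000 Genomes, gnomAD or ExAC | any AF > 0.1% in 1000 Genomes or ExAC |
| class / driver | keep missense, nonsense, indels; drop synonymous, splice-site, non-coding; COSMIC ignored | keep synonymous, splice-site, missense, nonsense, indels; drop non-coding and COSMIC-listed drivers |
| VAF / depth | VAF > 10% (FFPE) / > 5% (frozen); depth > 100X | VAF > 5% (both); depth > 100X |

TMB = retained count / panel footprint (1.6 Mb default). Scores are kept
unrounded; rounding is display-only.

Numerical conventions:

* **All threshold comparisons are strict** (`>`), matching the "higher
  than" convention of the filter definitions; `strict=False` switches a
  profile to `≥` for interoperability. Two deliberate exceptions on the
  curation side are inclusive *as printed in their definitions*: the
  MSIsensor bound (≥ 10%) and the DDR allelic-ratio bound (≥ 10%).
* A population-database entry that is absent never triggers germline
  removal — absence is informative, not missing data.
* Parsed Float INFO allele frequencies are rounded to 9 decimals to undo
  htslib's float32 quantization; otherwise a stored 0.001 would read back
  as 0.001000000047 and wrongly fail the strict 0.1% boundary.
* Unknown consequence or region (unannotated/unmappable terms) is
  excluded from TMB in every profile — conservative, and counted in a
  warning.
* An unset VCF FILTER column (`.`) is *not* a PASS; this is why VCF
  parsing is built on pysam, which distinguishes the two states.
* Degenerate runs: the recurrence predicate is applied as written even
  when a run has fewer than 7 samples (where 15% < one sample and any
  shared variant is removed); a warning is emitted.
* The somatic/germline-zygosity style of germline subtraction used by
  commercial pipelines is not reimplemented; `apply_profile` accepts an
  `external_germline` mapping of per-variant verdicts as a pluggable
  hook, and the FO profile otherwise approximates germline removal by
  population databases alone.
* Multi-allelic records are split per alternate allele before anything
  else; indel keys are taken as written (no left-alignment), acceptable
  because recurrence matching operates within one pipeline's own output.
  Known limitation for cross-pipeline comparisons.
* An indel whose annotation places it at a splice boundary is classified
  by the annotator's consequence term — splice-site wins over indel —
  so the strict profile excludes it.

## Sample QC and sweep diagnostics

A sample is *contributive* when it has ≥ 20 million reads and ≥ 15% of
captured regions covered above 1000X; the gate fails on the strict `<`
side, so boundary values pass, and missing metrics raise rather than
silently skipping the gate.

The VAF sweep recomputes TMB over a grid of minimum-VAF cutoffs (default
1%–30% in 1% steps) with all other filters fixed; the curve is provably
non-increasing. `plateau_vaf` reports the smallest cutoff from which
every successive relative decrease is ≤ `rel_tol` (default 0.05 —
plateaus are described only qualitatively in the literature, so the
tolerance is a package choice). In validation we run the plateau
diagnostic on the 1%–12% sub-grid: the simulator draws clonal somatic
VAFs above 12%, so beyond that point any decrease reflects the clonal
VAF distribution's tail, not artifact exhaustion. On real data the
equivalent statement is that the diagnostic is informative only below
the clonal VAF range.

## Cohort layer

* Per-tumor-type summaries report n, median and observed min–max,
  optionally restricted to an MSI/POLE/preservation stratum.
* TMB bins default to [0,10], (10,30], (30,100], (100,∞): right-closed
  at 10 so that "between 0 and 10 mut/Mb" includes a score of exactly
  10, with the edges configurable.
* The top-decile threshold is the 90th percentile with linear
  interpolation between order statistics (the selection rule "top 10%"
  does not fix a percentile method; this is the documented choice);
  TMB-high cases are those strictly above it.
* Curation rules, in order: (1) reclassify as a true hypermutator
  (MSI/POLE) when MSIsensor ≥ 10%, or a pathogenic MMR-gene variant, or
  an MSI signature, or a POLE proofreading mutation, or an APOBEC
  signature; (2) otherwise explained-by-DDR when TP53/PTEN/ARID1A carry
  a pathogenic variant at allelic ratio ≥ 10%; (3) otherwise
  unexplained. Signature and MSI scores are consumed as precomputed
  features; computing them is upstream of this package.

## Synthetic cohorts

The generator emits per-sample annotated VCFs (VarScan2 or Mutect2
genotype dialect; ANNOVAR- or snpEff-style annotation payloads) plus a
metadata manifest and an exact truth table. Default conditions, chosen
once as a realistic routine cohort:

| Parameter | Default | Why |
|---|---|---|
| countable somatic density | 8/Mb mean, lognormal σ=0.4 across samples | typical MSS pan-cancer panel burden |
| class mixture | 22% synonymous, 48% missense, 5% nonsense, 9% indels, 4% splice, 12% non-coding | rough coding-variant consequence proportions |
| somatic VAF | Beta(6,10) truncated below 0.12 | clonal variants at adequate tumor purity; keeps the truth identity exact (see below) |
| germline leakage | 30/sample; 85% common (AF > 0.1%), the rest rare incl. mass exactly at 0.001 | a handful of private polymorphisms survive database filtering; the boundary case is always exercised |
| FFPE artifacts | 25/Mb (high-quality) vs 120/Mb (low-quality); VAF Beta(1.5,28) vs Beta(1.5,9) | high-quality artifact mass sits below 10% VAF; low quality has a heavy tail past 10% |
| recurrent artifacts | 3 sites/run in 30% of the run's samples | systematic callable artifacts the recurrence filter targets |
| depth | lognormal, median 1500X, floor 150X | deep panel; the 100X filter is inert unless `low_depth_fraction` is raised |
| hypermutators | `msi_fraction`/`pole_fraction` (density ×5/×8); `hidden_msi_fraction` for hypermutators whose routine MSI status reads MSS | the hidden class is what biological curation exists to catch |

Truth bookkeeping: `true_density` counts somatic variants of countable
classes (missense, nonsense, indels) per Mb. Because clonal VAFs are
truncated above every profile cutoff and depths above 100X, a run with
zero artifacts and zero leakage must recover `true_density` *exactly*
under the strict profile — this identity is asserted in the tests and
acceptance script, and it is why the truncation default exists.
`evaluate_against_truth` label-joins retained variants with the truth
table to count artifact leak-through, germline leak-through and true
somatic loss per sample.

What the simulator does **not** model: read-level errors, UMI
deduplication, shared germline haplotypes across samples (each sample's
germline positions are private, so the recurrence filter never collides
with germline variants), panel gene composition, per-tumor-type burden
differences, and subclonal somatic structure below the truncation floor.
Passing tests on synthetic data therefore demonstrate the correctness of
the filtering/accounting machinery and the direction of the
preservation-specific cutoff effects — not clinical performance on real
FFPE archives.

## Problem sizes in validation

Tests and the acceptance script use cohorts of 2–60 samples (60–400
variant records per sample), 100 random small cohorts for the
cascade-vs-oracle equivalence check, and a 16-sample artifact-free
cohort for the exact-calibration check; the full suite runs in well
under a minute. These sizes are the package's own validation choices:
every property asserted is size-free (exact identities, monotonicity,
set equalities), so larger cohorts would add runtime, not evidence.

## Known limitations

* No confidence intervals on TMB (point scores only, matching routine
  reporting).
* The 1.6 Mb denominator is the full capture footprint; coding-only
  normalization is not implemented as a default.
* VCFs must arrive pre-annotated; the package never calls or annotates
  variants, and never touches BAMs.
* Chromosome normalization is limited to stripping a leading `chr`.
* One VCF record (after multi-allelic splitting) counts as one event;
  multi-nucleotide substitutions are not decomposed.
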
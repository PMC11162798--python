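# Methods

## CE sizing model

A repeat-primed PCR (RP-PCR) of an STR locus produces a gene-specific (GS)
amplicon from the two flanking primers plus a ladder of repeat-primed
products one unit apart. Fragment-analysis software reduces a CE run to a
peak table of (size bp, intensity); `repstab` starts from that table —
local-maximum extraction from raw traces and vendor binary formats (.fsa)
are out of scope.

The copy number of a GS peak is

```
repeat_length = round((size_bp / migration_factor − flank_bp) / unit_bp)
```

rounded to the nearest integer, ties away from zero (integer copy numbers
are reported in this field but the rounding rule is rarely stated; ties-away
is the fixed convention here). The migration factor corrects the anomalous
mobility of GC-rich amplicons relative to the size standard; for the
C9orf72 G4C2 assay it is 0.95, the non-repeat amplicon is 175 bp and the
unit is 6 bp. These constants ship in `repstab/loci/c9orf72.yaml`; CTG/GAA
templates ship with a null `flank_bp` because those assays' non-repeat
lengths are not published, and the loader refuses them until configured.
`SizingModel.calibrated()` offers per-run migration-factor calibration from
a sample of known length. For samples whose absolute sizing is unreliable
(3′ breaks), `offset_to_repeat_length` applies the same formula to the
difference between the GS product and the smallest repeat-primed product.

Sizes implying negative copies are rejected as sub-flank artifacts. The
default analysis window spans 0–1000 copies, padded by half a migrated
unit, and is configurable per assay.

### Background rule and mosaic calling

Signal below 20% of the highest peak in the window is background
(`count_minor_peaks` and species calling both use this fraction; the
boundary is inclusive — exactly 20% is signal, since only signal *below*
the fraction is removed). Equal-intensity ties for the highest peak resolve
toward the larger fragment, which is conservative toward expansion calls.

Mosaic samples carry several repeat species; each species is an independent
allele. `call_alleles` accepts a peak as a species when it is (a) at or
above the 20% fraction of the highest peak and (b) a local intensity
maximum over its ±1.5-unit neighbourhood. Criterion (b) is what separates
genuine species from the RP ladder and stutter: every ladder rung and
stutter shoulder sits one unit from a stronger peak, while a species peak
dominates its neighbourhood. The corollary is a resolution limit shared
with CE itself: a minor species inside the ladder shoulder of the primary
peak must exceed the local ladder intensity to be called. The mosaic
species threshold reuses the 20% background fraction because no separate
mosaic threshold is established; it is exposed as `species_frac`.

## Somatic and intergenerational classification

Somatic outcomes use absolute copy-number bands; the defaults are the
96-copy-parent G4C2 bands: expanded ≥ 105 (the parent plus roughly ten
additional copies), retained 90–104, contracted < 90, and large deletion
for samples with no GS product (lost priming site). The bands must tile the
integers (`expanded_min == retained_max + 1`), so every length falls in
exactly one band. For other parental lengths the bands are required
configuration; `bands_from_parental` (parental −6 / +8) is offered as a
convenience but never applied implicitly.

Transmissions are classified by the offspring/parent fold change:
expansion at ≥ 1.5×, contraction at ≤ 0.5×, retention in between. Both
bounds are inclusive, following the definition "1.5-fold or more" /
"0.5-fold or less"; published column headers sometimes print the strict
forms, and the inclusive reading is taken as authoritative.
`fold_range` reports the (min, max) fold over a set of offspring, half-up
rounded to 2 decimals.

## Cohort summaries

Frequencies are percentages rounded half-up to 1 decimal; ratios
(expansion/contraction, expansion/retention, contraction/retention) are
computed from the unrounded frequencies — equivalently from the raw counts
— and rounded half-up to 2 decimals, reported as NA when the denominator
category is empty. Two counting modes handle mosaicism:

* `per_allele` (somatic default): denominator is the total allele count; a
  large-deletion sample contributes one allele; frequencies sum to 100%
  before rounding.
* `per_sample_indicator` (transmission tables, optional for somatic):
  denominator is the sample count and a sample counts once per category it
  contains, so category percentages can sum past 100% in mosaic cohorts.

Published tables of this design are reproduced by these rules except where
the source's own rounding is internally inconsistent (e.g. a printed ratio
that differs in the last digit from the ratio of its own printed
components); such cells are noted in the tests rather than fitted.

## Read counting

The 150 bp immediately upstream (prefix) and downstream (suffix) of the
repeat tract are located in each read by Smith–Waterman local alignment
(match +1, mismatch −1, gap open −2, gap extend −1, via
`Bio.Align.PairwiseAligner`). Each anchor must reach a normalized score
(score / anchor length, an identity-equivalent fraction) of at least 0.6,
and the prefix must end at or before the suffix start; both read
orientations are tried and reverse-complement hits are mapped back to
read-forward, 0-based half-open coordinates. This is a sequence-space
analog of raw-signal tandem-repeat genotypers for nanopore data (which
threshold a signal-alignment score with no sequence-space equivalent), not
a reimplementation of one.

Copies are counted as anchored span length divided by unit length, rounded
ties-away — robust to substitutions inside a pure repeat, while indels bias
the count (the simulator therefore emits substitutions only; a stated
limitation). The read-set call is the modal per-read count, binned at
`bin_width` copies (default 1); ties break toward the smaller length,
conservative against expansion calls. Secondary modes with at least
`secondary_frac` (default 0.5) of the top bin's occupancy are reported so
mosaic read sets surface their minor species. Zero usable reads produce an
explicit empty result.

## Synthetic data

The generator emulates the structure the analysis assumes, not instrument
physics:

* **Traces** — per-species GS peaks at the forward-sized position with
  intensity ∝ abundance (unit-abundance amplitude 10 000 fluorescence
  units), symmetric ±1-unit stutter at `stutter_prob` (default 0.05; real
  stutter is unmodelled in the source assay, so this is a convention), and
  a repeat-primed ladder descending from the largest GS peak with geometric
  per-rung decay (default 0.85, which puts ~10 rungs above the 20%
  threshold, matching the visual extent of real RP ladders). Gaussian
  intensity noise (`noise_sd`, default 0) and a baseline floor are applied
  per peak. No quantitative noise/stutter estimates exist for the source
  CE runs; the defaults are conventions, not estimates.
* **Reads** — `prefix + L × unit + suffix` with substitution errors at
  `per_base_error` and constant Phred qualities matching that rate (a
  simplification); optional reverse-complementation per read
  (`rc_fraction`). The shipped 150 bp flanks are deterministic synthetic
  stand-ins (the real locus flanks are not redistributed); counting is
  flank-sequence-agnostic.
* **Cohorts** — each sample's outcome is drawn from the requested
  proportions and all its species are then drawn inside that outcome's
  copy-number band, so classification recovers the labels exactly; mosaic
  samples carry 2–5 species (the observed per-sample maximum).
  `cohort_from_counts` builds exact-count cohorts deterministically for
  reconstructing published summaries.
* **Pedigrees** — offspring lengths are drawn on the integer sub-range of
  each category's fold band (e.g. retention for a 400-copy parent:
  201–599), so rounding can never flip a category; mosaic offspring draw
  their extra species' categories independently, which is what makes
  indicator counts exceed the offspring total.

All generators take explicit seeds; independent operations derive child
seeds from one top-level seed via `numpy.random.SeedSequence` spawning, and
identical seeds give byte-identical outputs. What passing closed-loop tests
show is that the pipeline's stages are mutually consistent under the
assumed data structure; they do not validate instrument-level effects the
simulators omit (indels, electrophoretic spikes, dye pull-up, PCR
chemistry).

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: reconstructed
cohorts of ~1000 alleles (category counts = round(10 × percent), which
preserves the published proportions exactly), closed-loop cohorts of 2000
samples against 99% binomial bounds, read sets of 8–40 reads per condition
across the 3–550-copy allelic series. All rounding of reported quantities
is half-up (ties away from zero); percentages 1 decimal, ratios and folds
2 decimals. Determinism contracts are tested byte-for-byte on serialized
outputs.

## Known limitations

* Peak detection from raw fluorescence traces, vendor formats and
  Southern-blot sizing are out of scope; inputs are peak tables and reads.
* Span-based repeat counting is biased by indels; at indel-dominated error
  profiles a motif-aware counter would be needed.
* The per-sample-indicator mode caps a sample's contribution at one per
  category; it does not weight by species abundance.
* The CE species caller cannot resolve a minor species inside the ladder
  shoulder of the primary peak (see above), matching the physical
  resolution limit of the assay.
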
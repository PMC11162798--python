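# repstab

Analysis of short tandem repeat (STR) instability from fragment-analysis and
sequencing data. Disease-causing STRs — such as the GGGGCC (G4C2)
hexanucleotide repeat in *C9orf72* intron 1 — change copy number both
somatically and between generations. `repstab` implements the desk side of
such a study for cohorts of subclones, tissues and pedigrees:

* **CE sizing** (`repstab.ce_sizing`) — convert repeat-primed-PCR capillary
  electrophoresis (CE) peak tables into integer repeat-length calls, using

  ```
  repeat_length = round( (size_bp / migration_factor − flank_bp) / unit_bp )
  ```

  with the G4C2 assay constants `migration_factor = 0.95`, `flank_bp = 175`,
  `unit_bp = 6` (an offset variant sizes from the gene-specific vs
  smallest repeat-primed product difference). Signal below 20% of the
  highest peak is background; mosaic samples yield one call per repeat
  species; samples with no gene-specific product are flagged as large
  deletions.
* **Read counting** (`repstab.read_counter`) — anchor the 150 bp flanks of a
  repeat tract in each read by local alignment and count copies as
  span/unit length; the cohort call is the modal per-read count.
* **Classification** (`repstab.classifier`) — somatic outcomes by absolute
  copy-number bands (for a 96-copy parent: expanded ≥ 105, retained 90–104,
  contracted < 90, plus large deletion); intergenerational outcomes by
  offspring/parent fold change (expansion ≥ 1.5×, contraction ≤ 0.5×,
  retention in between, bounds inclusive).
* **Cohort summaries** (`repstab.report`) — outcome frequencies,
  expansion/contraction-type ratios and maximum repeat length, in per-allele
  or per-sample-indicator counting modes, plus an end-to-end pipeline driver.
* **Synthetic data** (`repstab.synthetic_data`) — simulators for every input
  (electropherograms with repeat-primed ladder and stutter, read sets,
  subclone cohorts, transmission tables), so the whole pipeline is testable
  without instrument data.

## Worked example

Call a mosaic sample from a simulated trace, then summarize a cohort:

```python
from repstab import SizingModel, call_alleles
from repstab.classifier import classify_sample
from repstab.report import summarize_somatic
from repstab.synthetic_data import (
    SpeciesSpec, TraceSimParams, cohort_from_counts, simulate_trace,
)

model = SizingModel()  # G4C2: unit 6 bp, flank 175 bp, migration factor 0.95
trace = simulate_trace(
    [SpeciesSpec(96, 0.7), SpeciesSpec(150, 0.3)],
    model, TraceSimParams(noise_sd=50.0, seed=1),
)
call = call_alleles(trace, model)
print(call.species)         # [(96, 1.0), (150, 0.43)] — two species, primary 96

counts = {"expanded": 183, "contracted": 218, "retained": 427, "large_deletion": 185}
summary = summarize_somatic(
    [classify_sample(c) for c in cohort_from_counts(counts, seed=0)]
)
print(summary.to_text())
```

```
# of samples analyzed	1013
# of alleles (mode=per_allele)	1013
Large deletion (%)	18.3
Contracted (%)	21.5
Retained (%)	42.2
Expanded (%)	18.1
Expansion/contraction ratio	0.84
Expansion/retention ratio	0.43
Contraction/retention ratio	0.51
Max repeat length	249
```

The trace call recovers both simulated species with the most abundant one
(96 copies) as the sample's repeat length; the cohort summary turns raw
per-allele outcome counts into percentages and derived ratios — here 183
expanded vs 218 contracted alleles give an expansion/contraction ratio of
0.84.

The same steps are available from the shell:

```sh
repstab call-ce --peaks trace.csv --locus c9orf72
repstab count-reads --fastq reads.fastq --anchors anchors.fa --unit GGGGCC
repstab pipeline --config config.yaml
```

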
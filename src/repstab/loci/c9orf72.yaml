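# C9orf72 G4C2 repeat-primed PCR / capillary electrophoresis assay constants
name: C9orf72-G4C2
unit_bp: 6              # GGGGCC hexanucleotide
flank_bp: 175           # non-repeat amplicon length, bp
migration_factor: 0.95  # empirical mobility correction for the GC-rich amplicon
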
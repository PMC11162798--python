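# FXN GAA assay template. The non-repeat amplicon length of this assay is
# not published; fill in flank_bp (and a calibrated migration_factor) before use.
name: FXN-GAA
unit_bp: 3
flank_bp: null
migration_factor: 1.0
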
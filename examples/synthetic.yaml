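# Full pipeline run on the bundled synthetic fixture.
# `synthetic: {}` uses the generator defaults (three waves of 8 TFs with one
# hub each, 1200 targets, 21-TF knockdown panel); any key under `synthetic`
# overrides them.
outdir: run
seed: 11
synthetic: {}
de_rule: agree_by_two
fdr_threshold: 0.05
n_waves: 3
lfc_threshold: 1.0
efficiency_gate: 0.6
centrality_variant: closeness
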
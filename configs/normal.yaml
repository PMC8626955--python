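# Normal property-optimization protocol: full budget per seed, reseeding
# every 2000 steps (the Multi model); use mode: single for the fixed-seed run.
config_version: 1
score: qed
mode: multi
steps: 10000
cycle_interval: 2000
seed: 0
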
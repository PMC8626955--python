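# Similarity-constrained penalized-logP optimization: 4 cycles x 50 steps
# per seed; run at delta 0.2 / 0.4 / 0.6 by editing the threshold.
config_version: 1
score: constrained-plogp
mode: multi
steps: 200
cycle_interval: 50
delta: 0.4
seed: 0
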
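"""Run a reduced hidden-neuron sweep over model variants and print the
results table (the full protocol uses H = 10..300 step 10 with population
and iteration counts of 100)."""

import chaoelm as ce
from chaoelm.sweep import run_sweep

table = ce.generate_synthetic(ce.SyntheticSpec(seed=6))
split = ce.shuffle_split(
    ce.apply_normalization(table, ce.fit_normalization(table)), 0.7, seed=6
)

frame = run_sweep(
    split,
    variants=["none", "cjaya"],
    grid=[10, 30, 50],
    population=20,
    iterations=20,
    seed=6,
    objective_mode="validation",
)
print(frame[["variant", "H", "tr_acc", "ts_acc", "sen", "spe", "gmean", "auc"]]
      .to_string(index=False))
# "none" is the plain ELM baseline; each row is one trained model with its
# test-split metric battery, reproducible from its own derived seed.
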
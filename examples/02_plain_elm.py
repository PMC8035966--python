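"""Train a plain extreme learning machine and report the diagnostic
metric battery on the held-out test split."""

import chaoelm as ce

table = ce.generate_synthetic(ce.SyntheticSpec(seed=2))
split = ce.shuffle_split(
    ce.apply_normalization(table, ce.fit_normalization(table)), 0.7, seed=2
)

# 100 random sigmoid hidden neurons; output weights solved in closed form
model = ce.train_elm(split.train, hidden=100, seed=2)
train_report, test_report = ce.final_evaluate(model, split)

print("test-split metrics:")
for key, value in test_report.rounded().items():
    print(f"  {key:12s} {value}")
# Sensitivity is the detection rate on diseased samples, specificity the
# rate on healthy ones; gmean/fscore summarize their balance, and AUC is
# the probability a random positive outscores a random negative.
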
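# chaoelm

Metaheuristic-trained extreme learning machines for binary clinical
tabular classification — chiefly the **chaotic-Jaya optimized ELM
(CJaya-ELM)**, with plain ELM, Jaya-ELM, TLBO-ELM and multilayer-perceptron
baselines, a synthetic clinical-data generator, and the full
diagnostic-metric evaluation battery (sensitivity, specificity, Gmean,
Sn/Sp F-score, ROC/AUC) used in diabetes-diagnosis benchmarks.

## Who this is for

Researchers studying fast neural classifiers for small clinical tables
(the reference schema is the Pima Indian diabetes layout: 768 patients,
8 numeric features, binary diseased/healthy outcome) and anyone who needs
a tested, reproducible implementation of Jaya-family metaheuristics or of
the Sn/Sp-based metric conventions common in this literature. No external
dataset is required: the synthetic generator emulates the schema, and the
CSV loader accepts real data in the same layout.

## The model

An **extreme learning machine** is a single-hidden-layer feed-forward
network whose hidden parameters are random and fixed. With hidden
activation matrix `H` (sigmoid, entries `H[s,i] = σ(x_s·w_i + b_i)`) and
target vector `T ∈ {−1,+1}^n`, the output weights are the minimum-norm
least-squares solution

    β̂ = H† T

via the Moore–Penrose pseudo-inverse — no iterative training. The random
hidden layer, however, makes performance unstable. CJaya-ELM optimizes it:
each candidate of a population encodes all `(d+1)·H` hidden weights and
biases; evaluating a candidate solves its `β` in closed form and measures
the misclassification rate; the **Jaya** update moves every candidate
toward the current best and away from the current worst,

    z' = z + r₁ (z_best − |z|) − r₂ (z_worst − |z|),

with greedy replacement. In **chaotic Jaya** the uniform multipliers
`r₁, r₂` are replaced by iterates of the logistic map `x ← 4x(1−x)` at
full chaos. **TLBO** (teaching-learning-based optimization) is the
two-phase alternative baseline, and a 3×5 sigmoid MLP trained by
backpropagation-with-momentum or by the same metaheuristics completes the
comparison set.

## Worked example

```python
import chaoelm as ce

table = ce.generate_synthetic(ce.SyntheticSpec(seed=2))      # 768 x 8, ~35% positive
split = ce.shuffle_split(
    ce.apply_normalization(table, ce.fit_normalization(table)), 0.7, seed=2
)
model = ce.train_elm(split.train, hidden=100, seed=2)
_, test_report = ce.final_evaluate(model, split)
print(test_report.rounded())
```

prints

```
{'accuracy': 0.7662, 'sensitivity': 0.6173, 'specificity': 0.8467,
 'gmean': 0.7229, 'fscore': 0.714, 'tp': 50, 'fn': 31, 'fp': 23,
 'tn': 127, 'auc': 0.8002}
```

Accuracy is the fraction of the 231 held-out patients classified
correctly; sensitivity is the detection rate among the diseased,
specificity among the healthy; `gmean = √(Sn·Sp)` and
`fscore = 2·Sn·Sp/(Sn+Sp)` summarize their balance (the F-score here is
the Sn/Sp harmonic mean used in this benchmark line, *not* the
precision/recall F1); AUC is the probability a random diseased patient
outscores a random healthy one. Swapping `train_elm` for
`train_hybrid_elm` with a `HybridConfig(variant="cjaya", ...)` optimizes
the hidden layer — see `examples/04_cjaya_elm.py`, and the other
`examples/` scripts for data generation, the optimizer benchmark, metric
arithmetic and the hidden-neuron sweep.

A thin CLI wraps the same functions:

```bash
chaoelm generate --n 768 --d 8 --seed 1 --out data.csv
chaoelm train --in data.csv --variant cjaya --hidden 50 --model-out model.json
chaoelm sweep --in data.csv --grid 10,20,30 --out-dir sweep_out
```

## Notes

- Candidate evaluation defaults to the historical protocol
  (`objective_mode="paper"`), which scores candidates on the test split.
  Use `objective_mode="validation"` for leak-free model selection; see
  `docs/methods.md` for why this matters when interpreting benchmark
  accuracies.
- Models serialize to JSON (including the fitted normalization), sweep
  results and convergence traces to CSV.
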
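# Methods

This note documents the models, the numerical choices and the synthetic
study conditions behind `chaoelm`, and what the test suite does and does
not establish.

## Data model and preprocessing

All stages consume a `FeatureTable`: an `n × d` float matrix with labels
in `{−1, +1}` (+1 = diseased). CSV input with `{0, 1}` outcomes is
remapped on read; missing values are rejected rather than imputed, since
the reference schema (Pima-style clinical tables) declares none.

Min–max normalization maps each feature onto `[a, b]` (default `(−1, 1)`,
matching the ±1 target coding and the `[−1, 1]` weight boxes):
`Mn = a + (b − a)(M − Dmin)/(Dmax − Dmin)`. By default the spec is fitted
on the **full** table before splitting, reproducing the historical
pipeline; a `fit_on_train` option fits on the training split only and
linearly extrapolates out-of-range test values (no clipping), which is
the statistically sound alternative. A constant feature would divide by
zero; it is mapped to the interval midpoint with a warning. Labels are
never normalized — only features. The 7:3 split takes the first
`floor(0.7·n)` rows of a seeded permutation, so a single integer
reproduces the partition exactly.

## ELM

Hidden weights and biases are i.i.d. uniform on `[−1, 1]` (the paper-line
literature leaves the range unstated; we match the normalized feature
range). Output weights solve `min ‖Hβ − T‖₂` with minimum norm via an
SVD-based least-squares solve (singular values below
`eps·max(n, H)·σ_max` treated as zero). An optional ridge term
(`ridge > 0`, default off) is available for severely ill-conditioned
activation matrices. Classification thresholds the real-valued score at
0, ties to the positive class — fixed and testable. ROC scores are the
raw pre-threshold outputs.

## Optimizers

All variants share: uniform random initialization inside the box, clipping
to the box after every move, greedy replacement (strict improvement;
ties keep the incumbent), and best/worst ties resolved to the lowest
index. Candidates are processed **sequentially with immediate
replacement**: an accepted move can become the best (or stop being the
worst) for the candidates processed after it within the same iteration.
This is the canonical formulation for TLBO and a standard one for
Jaya-family methods; it converges measurably faster than a synchronous
batch update at identical evaluation budgets and is what the sphere
benchmark figures in `scripts/acceptance.py` reflect.

- **Jaya**: `z' = z + r₁(z_best − |z|) − r₂(z_worst − |z|)` with fresh
  `r₁, r₂ ~ U(0,1)` per dimension, candidate and iteration. Some printed
  statements of the rule show `z_best + |z|` in the attraction term; that
  form systematically inflates candidates toward `|z|` and contradicts
  the method's best-attraction intent, so the canonical form is the
  default and the literal variant is kept behind `as_printed=True` for
  comparison.
- **CJaya**: identical update with `r₁, r₂` replaced by two independent
  per-dimension draws from a logistic-map stream (`x ← 4x(1−x)`). Initial
  states are uniform on `(0, 1)` excluding the map's fixed and
  eventually-fixed points `{0, ¼, ½, ¾, 1}`; the states derive from the
  run's single seed, so one integer reproduces the whole run. The map's
  invariant (arcsine) density has mean ½ — the long-run stream mean is
  checked against that.
- **TLBO**: teacher phase `z' = z + r(z_teacher − Tf·mean)` with the mean
  frozen at phase start, `Tf` drawn uniformly from `{1, 2}` per candidate
  (the standard choice; the source literature names `Tf` without defining
  it); learner phase moves toward a uniformly drawn better peer or away
  from a worse one. Both phases run each iteration, so TLBO spends two
  evaluations per candidate per iteration versus Jaya's one.

Every run records a best-so-far trace (length `iterations + 1`) whose
non-increase is asserted at runtime, and exports to CSV.

## CJaya-ELM hybrid

A candidate encodes the entire hidden layer — the `d × H` weight matrix
column-major, then the `H` biases, `D = (d+1)·H` values in `[−1, 1]^D`.
(Describing candidates as length-`H` vectors, as the source line does,
cannot hold the `d × H` weights the ELM randomizes; the multiplication
`training_input × P_i` itself requires `d` rows.) Evaluating a candidate
solves its `β` on the training data and scores misclassification on an
evaluation set. The winning candidate's `β` is obtained by re-running the
same deterministic solve, which reproduces bit-for-bit the value recorded
during its evaluation. Plain ELM and the hybrid share one `β`-solve path,
so they differ only in how the hidden layer is chosen.

**Objective modes.** `"paper"` scores candidates on the held-out test
split — the historical protocol. This leaks the test set into model
selection, and the package quantifies the effect (the paired test in the
suite shows paper-mode test error is at or below validation-mode error in
median over matched seeds). It plausibly accounts for benchmark
accuracies near 0.97 on data where the leak-free literature norm is
around 0.77. `"validation"` scores candidates on an internal 80/20 split
of the training data and is used for every generalization claim in the
tests. The default remains `"paper"` for fidelity to the protocol being
reproduced; interpret its test metrics accordingly.

## MLP baseline

Fixed architecture `[d, 5, 5, 5, 1]`, sigmoid everywhere, targets
`{0, 1}` with threshold 0.5 (kept deliberately separate from the ELM's
±1/0 convention). Training loss is `E(w) = ½ Σ_s (o_s − t_s)²`;
full-batch backpropagation with momentum updates
`Δw(t) = −ε ∂E/∂w + α Δw(t−1)` (the gradient-descent rule the
surrounding method requires; some printed statements omit the gradient
factor). Defaults `ε = 0.01`, `α = 0.9`, 500 epochs — unstated in the
source line, chosen as ordinary values for full-batch sigmoid nets.
Metaheuristic MLP training flattens all 111 parameters (for `d = 8`) in
documented layer order and minimizes the training misclassification rate.
Backprop gradients are verified against central finite differences
(`h = 1e−5`, max relative error `< 1e−5` over random small nets).

## Metrics

Positive class +1. `Sn = TP/(TP+FN)`, `Sp = TN/(TN+FP)`;
`Gmean = √(Sn·Sp)` — the square root is forced by the benchmark's own
published rows, e.g. `√(0.8727 · 0.6923) = 0.7773` matches the printed
cell while the bare product does not. The F-score is the **Sn/Sp harmonic
mean** `2·Sn·Sp/(Sn+Sp)`, exposed as `sp_sn_fscore` to avoid confusion
with precision/recall F1, which is deliberately not provided. Rates with
empty denominators return NaN with a warning. Table values round to 4
decimals, half away from zero (`0.96875 → 0.9688`). ROC sweeps thresholds
over unique scores with ∞ sentinels; AUC is trapezoidal and equals
pair-counting probability `P(s₊ > s₋) + ½P(tie)` (property-tested to
1e−12, and cross-checked against scikit-learn).

Known inconsistencies in the published benchmark tables (test accuracies
that disagree with the same row's confusion counts, one specificity cell
contradicting its own counts) are out of scope: only within-row
arithmetic is reproduced.

## Synthetic study conditions

The generator emulates the Pima schema: `n = 768`, `d = 8`, prevalence
0.35, non-negative features from truncated normals with class-shifted
means, 2% label flips. The default shift (0.5 per feature at unit noise)
gives a Bayes-style error near 0.24 — deliberately in the range of the
real dataset's ~0.77 accuracy ceiling, as the worked example shows.
Property tests that need separability raise the shift to 4 standard
deviations with no label noise. What the generator does **not** emulate:
the real features' skewness, heteroscedastic and correlated measurements,
integer-valued columns, or the biologically implausible zeros of the real
Pima table. Passing tests therefore demonstrate correctness of the
algorithms and pipeline, not clinical performance on real cohorts.

## Problem sizes

The full historical protocol (hidden neurons 10–300 step 10, population
and iterations 100) is available through `run_sweep` and the CLI. The
test suite and acceptance script run reduced instances chosen as the
smallest sizes at which each property is informative: sphere benchmark at
the full population/iteration setting, hybrid comparisons at `n = 400`,
`H = 30`, population 30, 30 iterations over 11 paired seeds, oracle
checks at 50–100 random instances.

## Known limitations

- Binary single-output models only; no multi-class, no kernel or
  sequential ELM variants, no regularization beyond optional ridge.
- Box clipping is the only constraint handling; no alternative chaotic
  maps.
- The paper-mode objective is retained for protocol fidelity despite its
  leakage; its test metrics must not be read as generalization estimates.
- Plot rendering is out of scope; all figures' underlying numbers are
  exported as CSV (traces, sweep tables).
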
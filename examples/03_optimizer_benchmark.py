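"""Minimize the 10-D sphere function with each population optimizer and
compare final objectives and convergence speed."""

import numpy as np

import chaoelm as ce


def sphere(z):
    return float(np.sum(np.square(z)))


for variant in ("jaya", "cjaya", "tlbo"):
    cfg = ce.OptimizerConfig(
        variant=variant, dims=10, population=100, iterations=100, seed=3
    )
    best, trace = ce.optimize(sphere, cfg)
    b = trace.best_objective
    print(f"{variant:6s} start {b[0]:.3f}  iter 50 {b[50]:.2e}  final {b[-1]:.2e}")
# All variants drive the objective toward the optimum at 0; the trace is
# the best-so-far value, guaranteed non-increasing by greedy replacement.
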
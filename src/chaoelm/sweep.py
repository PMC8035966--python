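"""Hidden-neuron sweep experiment runner.

Trains every requested model variant at every hidden-layer size on one
fixed train/test split and tabulates the full metric battery per cell,
mirroring the usual reporting layout of ELM benchmark studies (one row per
(variant, H) with train/test accuracy, confusion counts, sensitivity,
specificity, Gmean, F-score and AUC).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .data import SplitPair
from .hybrid import HybridConfig, final_evaluate, train_hybrid_elm
from .metrics import round4

__all__ = ["default_grid", "run_sweep"]

SWEEP_COLUMNS = [
    "variant",
    "H",
    "tr_acc",
    "ts_acc",
    "TP",
    "FN",
    "FP",
    "TN",
    "sen",
    "spe",
    "gmean",
    "fscore",
    "auc",
]


def default_grid() -> list[int]:
    """Hidden-neuron grid 10, 20, ..., 300."""
    return list(range(10, 301, 10))


def child_seed(master_seed: int, index: int) -> int:
    """Independent per-cell seed derived from the master seed, so any cell
    can be reproduced in isolation."""
    return int(
        np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0]
        % (2**31)
    )


def run_sweep(
    data: SplitPair,
    variants: list[str] = ("none", "jaya", "cjaya", "tlbo"),
    grid: list[int] | None = None,
    population: int = 100,
    iterations: int = 100,
    seed: int = 0,
    objective_mode: str = "paper",
    trace_sink=None,
) -> pd.DataFrame:
    """Run the full (variant x H) grid and return the results table.

    A failed cell is recorded with an ``error`` note and skipped rather
    than aborting the sweep.  ``trace_sink(variant, H, trace)`` is called
    with each run's convergence trace when provided.
    """
    if grid is None:
        grid = default_grid()
    rows = []
    idx = 0
    for variant in variants:
        for hidden in grid:
            cell_seed = child_seed(seed, idx)
            idx += 1
            try:
                config = HybridConfig(
                    variant=variant,
                    hidden=hidden,
                    population=population,
                    iterations=iterations,
                    seed=cell_seed,
                    objective_mode=objective_mode,
                )
                model, trace = train_hybrid_elm(data, config)
                tr, ts = final_evaluate(model, data)
            except Exception as exc:  # a bad cell must not kill the sweep
                rows.append({"variant": variant, "H": hidden, "error": str(exc)})
                continue
            if trace_sink is not None:
                trace_sink(variant, hidden, trace)
            rows.append(
                {
                    "variant": variant,
                    "H": hidden,
                    "tr_acc": round4(tr.accuracy),
                    "ts_acc": round4(ts.accuracy),
                    "TP": ts.counts.tp,
                    "FN": ts.counts.fn,
                    "FP": ts.counts.fp,
                    "TN": ts.counts.tn,
                    "sen": round4(ts.sensitivity),
                    "spe": round4(ts.specificity),
                    "gmean": round4(ts.gmean),
                    "fscore": round4(ts.fscore),
                    "auc": round4(ts.auc) if ts.auc is not None else np.nan,
                    "seed": cell_seed,
                }
            )
    return pd.DataFrame(rows)
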
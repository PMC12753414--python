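"""Monte-Carlo calibration of the segmented-index ANCOVA.

Repeatedly draws synthetic Cq tables from a named preset, runs the full
quantification + developmental-index pipeline, and tallies per-segment
interaction-test rejections.  Under the ``null`` preset (δ = 0, arms
exchangeable) the rejection rate estimates the test's attained level;
under ``withdrawal_delay`` it estimates power in each segment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cqindex.devindex import run_devindex_pipeline
from cqindex.quantify import PanelConfig, compute_dcq, compute_fold_change
from cqindex.simulate import preset, simulate_cq_table


def interaction_rejection_rates(
    preset_name: str,
    n_sim: int,
    seed: int,
    alpha: float = 0.05,
    index_scale: str = "log",
    **design_overrides,
) -> pd.DataFrame:
    """Per-segment rejection rates of the ANCOVA interaction test.

    Each replicate re-simulates the whole study at an independent child
    seed, re-runs quantification and the index pipeline, and counts a
    rejection when the segment is evaluable with interaction p < alpha.
    Rates are taken over evaluable replicates (segments with an empty up-
    or down-set contribute to ``n_non_evaluable`` instead).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_sim)

    config = None
    tally: dict = {}
    for s in child_seeds:
        truth = preset(preset_name, seed=int(s), **design_overrides)
        if config is None:
            config = PanelConfig(genes=tuple(truth.genes), alpha=alpha)
        table = simulate_cq_table(truth)
        fc = compute_fold_change(compute_dcq(table, config), config)
        result = run_devindex_pipeline(fc, config, index_scale=index_scale)
        for comp in result.slope_comparisons:
            rec = tally.setdefault(
                comp.segment.label, {"n_evaluable": 0, "n_rejected": 0,
                                     "n_non_evaluable": 0}
            )
            if comp.evaluable:
                rec["n_evaluable"] += 1
                rec["n_rejected"] += int(comp.interaction_p < alpha)
            else:
                rec["n_non_evaluable"] += 1

    rows = []
    for label, rec in tally.items():
        rate = rec["n_rejected"] / rec["n_evaluable"] if rec["n_evaluable"] else np.nan
        rows.append({"segment": label, **rec, "rejection_rate": rate})
    return pd.DataFrame(rows)
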
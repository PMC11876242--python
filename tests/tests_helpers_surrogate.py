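"""Shared helper: synthesize a feature/label table with a known linear law."""

import numpy as np
import pandas as pd

from enzkin.surrogate import FEATURE_NAMES, features_from_condition
from enzkin.synthetic_data import ExperimentCondition


def make_linear_table(n_rows: int, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_rows):
        cond = ExperimentCondition(
            enzyme="HRP" if i % 2 == 0 else "heme",
            pH=float(rng.choice([4.0, 7.0])),
            temperature_C=float(rng.uniform(18.0, 25.0)),
            substrate="ABTS",
            substrate_conc_uM=float(rng.choice([25.0, 100.0, 500.0, 1000.0])),
        )
        f = features_from_condition(cond)
        row = dict(zip(FEATURE_NAMES, f))
        row["condition_id"] = f"r{i}"
        row["log_K_M"] = 4.0 + 0.2 * f[2] + 0.3 * f[0]
        row["log_kcat"] = 1.0 + 0.08 * (f[3] - 22.0) + 0.5 * f[1]
        rows.append(row)
    return pd.DataFrame(rows)
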
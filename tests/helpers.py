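"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's vectorized code paths: plain Python
loops over genes, one pair at a time.
"""

import numpy as np
import pandas as pd


def brute_nsd(values) -> float:
    v = np.asarray(values, dtype=float)
    return float(np.std(v, ddof=1) / v.mean())


def brute_candidates(control_df: pd.DataFrame, target: str, k: int):
    """Exhaustive candidate-index scan for one target.

    Returns the k (index_gene, nsd) pairs with smallest NSD of the ratio
    target/index over the columns of ``control_df``; ties broken by gene id.
    """
    t = control_df.loc[target].to_numpy(dtype=float)
    records = []
    for gene in control_df.index:
        if gene == target:
            continue
        e = control_df.loc[gene].to_numpy(dtype=float)
        if (e == 0).any():
            continue
        records.append((gene, brute_nsd(t / e)))
    records.sort(key=lambda r: (r[1], r[0]))
    return records[:k]


def brute_database(control_df: pd.DataFrame, targets, k: int):
    """Exhaustive candidate database: list of (target, index, nsd)."""
    out = []
    for target in targets:
        t = control_df.loc[target].to_numpy(dtype=float)
        if not (t > 0).any():
            continue
        for gene, value in brute_candidates(control_df, target, k):
            out.append((target, gene, value))
    return out
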
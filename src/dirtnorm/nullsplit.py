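"""Artificial control/disease relabeling for null-hypothesis testing.

Mixing true control and case samples into two artificial arms removes any
genuine group effect; running the full pipeline on the relabeled design
should then produce no small adjusted p-values.  The split is stratified by
time point with explicit quotas: per time point, a fixed number of original
controls and original cases go to the artificial control arm, the rest to
the artificial disease arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, CountMatrix, DataError, SampleDesign
from .dirt import (
    DirtDatabase,
    build_candidate_db,
    filter_index_validity,
    test_pairs,
)
from .normalize import apply_normalization, rle_size_factors, select_abundant
from .stats import group_test_matrix

__all__ = ["NullDesign", "NullResult", "make_null_design", "run_null_pipeline"]

ART_CONTROL = "art_control"
ART_DISEASE = "art_disease"


@dataclass
class NullDesign:
    """Original design plus the artificial arm assignment per sample."""

    table: pd.DataFrame  # sample_id, group, time_point, subject_id, artificial_group
    quotas: tuple[int, int]  # (controls, cases) sent to art_control per time point
    seed: int | None

    def arm(self, which: str) -> list[str]:
        sel = self.table[self.table["artificial_group"] == which]
        return list(sel["sample_id"])

    def as_design(self) -> SampleDesign:
        """Relabeled design: art_control -> control, art_disease -> case."""
        t = self.table.copy()
        t["group"] = np.where(
            t["artificial_group"] == ART_CONTROL, CONTROL, CASE
        )
        return SampleDesign(t.drop(columns=["artificial_group"]))


def make_null_design(
    design: SampleDesign,
    ctrl_to_artctrl_per_tp: int,
    case_to_artctrl_per_tp: int,
    seed: int | None = None,
) -> NullDesign:
    """Assign every sample to an artificial arm, stratified by time point.

    Within each time point, samples of each original group are ordered by
    sample id (or shuffled when ``seed`` is given); the first
    ``ctrl_to_artctrl_per_tp`` controls and ``case_to_artctrl_per_tp``
    cases join the artificial control arm, the remainder the artificial
    disease arm.
    """
    tab = design.table.copy()
    rng = np.random.default_rng(seed) if seed is not None else None
    assignment: dict[str, str] = {}
    for tp in design.time_points:
        for group, quota in (
            (CONTROL, ctrl_to_artctrl_per_tp),
            (CASE, case_to_artctrl_per_tp),
        ):
            ids = sorted(
                tab[(tab["time_point"] == tp) & (tab["group"] == group)][
                    "sample_id"
                ]
            )
            if quota > len(ids):
                raise DataError(
                    f"quota {quota} exceeds {len(ids)} {group} samples at "
                    f"time point {tp!r}"
                )
            if rng is not None:
                ids = list(rng.permutation(ids))
            for s in ids[:quota]:
                assignment[s] = ART_CONTROL
            for s in ids[quota:]:
                assignment[s] = ART_DISEASE
    tab["artificial_group"] = tab["sample_id"].map(assignment)
    for arm in (ART_CONTROL, ART_DISEASE):
        n = int((tab["artificial_group"] == arm).sum())
        if n < 2:
            raise DataError(f"artificial arm {arm!r} has {n} samples; need >= 2")
    return NullDesign(
        table=tab,
        quotas=(ctrl_to_artctrl_per_tp, case_to_artctrl_per_tp),
        seed=seed,
    )


@dataclass
class NullResult:
    """Outputs of the pipeline run under the artificial relabeling."""

    db: DirtDatabase  # tested + filtered pair database
    gene_stats_rle: pd.DataFrame
    min_p_adj: float
    counts_below: dict = field(default_factory=dict)  # threshold -> n pairs


def run_null_pipeline(
    counts: CountMatrix,
    null_design: NullDesign,
    n_top: int | None = None,
    k: int = 10,
    alpha: float = 0.05,
    thresholds: tuple[float, ...] = (0.05, 0.1),
    zero_policy: str = "drop",
) -> NullResult:
    """Run abundance filter → candidate scan → pair tests → index filter
    under the artificial labels and report how small the adjusted p-values
    get.

    ``n_top`` defaults to every gene; BH family sizes follow the database
    size (pairs) and candidate-gene count (genes), as in the main pipeline.
    """
    design = null_design.as_design()
    design.check_pairing(counts)
    if n_top is None:
        n_top = counts.n_genes
    abundant, _ = select_abundant(counts, n_top)
    sub = counts.subset_genes(abundant)

    db = build_candidate_db(sub, design, k=k)
    m_pairs = db.params["n_targets_requested"] * k
    tested = test_pairs(db, sub, design, m=m_pairs, zero_policy=zero_policy)

    rle = apply_normalization(sub, rle_size_factors(sub))
    gene_stats = group_test_matrix(rle, design, m=n_top)
    filtered = filter_index_validity(tested, gene_stats, alpha=alpha)

    padj = filtered.pairs["p_adj"].to_numpy(dtype=float)
    min_p = float(padj.min()) if padj.size else 1.0
    counts_below = {thr: int((padj < thr).sum()) for thr in thresholds}
    return NullResult(
        db=filtered,
        gene_stats_rle=gene_stats,
        min_p_adj=min_p,
        counts_below=counts_below,
    )
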
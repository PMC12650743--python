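"""End-to-end orchestration of the ratio-transformation workflow.

``run_pipeline`` glues the stages together in the published order:
abundance filter → gene-level CPM/RLE/TMM baselines → candidate-index scan
(control samples only) → pair tests with full-family BH → index-validity
filter → per-target summaries.  ``RunConfig`` holds every tunable constant
so a run manifest fully reproduces a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import pandas as pd
import yaml

from .containers import CountMatrix, DataError, SampleDesign
from .dirt import (
    DirtDatabase,
    TargetSummaries,
    build_candidate_db,
    filter_index_validity,
    summarize_targets,
    test_pairs,
)
from .normalize import (
    apply_normalization,
    cpm,
    rle_size_factors,
    select_abundant,
    tmm_factors,
)
from .stats import group_test_matrix

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """All tunable constants of one pipeline run.

    Defaults are the full-scale published constants: 10,000 abundant
    genes, 10 candidate indexes per target (hence a 100,000-pair BH
    family), gene-level BH family 10,000, index validity at adjusted
    p > 0.05.
    """

    n_top: int = 10_000
    k: int = 10
    k_extended: int = 100
    m_pairs: int | None = None  # default: n_top * k
    m_genes: int | None = None  # default: n_top
    index_alpha: float = 0.05
    zero_policy: str = "drop"
    pseudocount: float = 0.5
    per_timepoint: bool = False
    null_ctrl_quota: int = 10
    null_case_quota: int = 9
    seed: int = 0

    def validate(self) -> None:
        if self.n_top <= 0 or self.k <= 0:
            raise DataError("n_top and k must be positive")
        if self.k_extended < self.k:
            raise DataError("k_extended must be >= k")
        if not 0 <= self.index_alpha <= 1:
            raise DataError("index_alpha must lie in [0, 1]")
        if self.zero_policy not in ("drop", "pseudocount"):
            raise DataError(f"unknown zero_policy {self.zero_policy!r}")

    @property
    def effective_m_pairs(self) -> int:
        return self.m_pairs if self.m_pairs is not None else self.n_top * self.k

    @property
    def effective_m_genes(self) -> int:
        return self.m_genes if self.m_genes is not None else self.n_top

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise DataError(f"unknown config keys: {unknown}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    """Everything a run produces, plus the funnel of pair counts."""

    abundant_genes: list[str]
    abundance_threshold: float
    gene_stats: dict[str, pd.DataFrame]  # method -> gene-level table
    db_candidates: DirtDatabase
    db_tested: DirtDatabase
    db_filtered: DirtDatabase
    summaries: TargetSummaries
    funnel: dict[str, int]
    manifest: dict


def run_pipeline(
    counts: CountMatrix, design: SampleDesign, config: RunConfig | None = None
) -> PipelineResult:
    """Run the complete workflow on one count matrix.

    ``config.n_top`` is clipped to the gene count only by raising — pass an
    explicit smaller value for desk-scale matrices.
    """
    cfg = config or RunConfig()
    cfg.validate()
    design.check_pairing(counts)
    design.require_group_sizes(2)
    counts.validate_for_analysis()

    abundant, threshold = select_abundant(counts, cfg.n_top)
    sub = counts.subset_genes(abundant)
    m_genes = cfg.effective_m_genes
    m_pairs = cfg.effective_m_pairs

    gene_stats: dict[str, pd.DataFrame] = {}
    gene_stats["cpm"] = group_test_matrix(
        cpm(sub), design, m=m_genes, stratify_by_time=cfg.per_timepoint
    )
    gene_stats["rle"] = group_test_matrix(
        apply_normalization(sub, rle_size_factors(sub)),
        design,
        m=m_genes,
        stratify_by_time=cfg.per_timepoint,
    )
    gene_stats["tmm"] = group_test_matrix(
        apply_normalization(sub, tmm_factors(sub)),
        design,
        m=m_genes,
        stratify_by_time=cfg.per_timepoint,
    )

    db = build_candidate_db(sub, design, k=cfg.k)
    tested = test_pairs(
        db,
        sub,
        design,
        m=m_pairs,
        zero_policy=cfg.zero_policy,
        pseudocount=cfg.pseudocount,
        per_timepoint=cfg.per_timepoint,
    )
    filtered = filter_index_validity(
        tested, gene_stats["rle"], alpha=cfg.index_alpha
    )
    summaries = summarize_targets(filtered, all_targets=db.targets)

    funnel = {
        "n_genes_input": counts.n_genes,
        "n_abundant": len(abundant),
        "n_candidate_pairs": len(db),
        "n_tested_pairs": len(tested),
        "n_retained_pairs": len(filtered),
        "n_targets_with_valid_pair": len(summaries.table),
        "n_targets_omitted": len(summaries.omitted_targets),
    }
    manifest = {
        "config": asdict(cfg),
        "m_pairs": m_pairs,
        "m_genes": m_genes,
        "abundance_threshold": threshold,
        "funnel": funnel,
        "n_samples": counts.n_samples,
    }
    return PipelineResult(
        abundant_genes=abundant,
        abundance_threshold=threshold,
        gene_stats=gene_stats,
        db_candidates=db,
        db_tested=tested,
        db_filtered=filtered,
        summaries=summaries,
        funnel=funnel,
        manifest=manifest,
    )
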
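"""Synthetic blood RNA-seq count generator with a ground-truth ledger.

The generator emulates the statistical structure the ratio transformation
exploits in longitudinal blood transcriptomes:

* wide log-normal spread of baseline gene abundance;
* per-sample library-size variation (log-normal);
* per-time-point multiplicative batch drift, either *global* (one factor
  per time point, shared by all genes — removable by any scaling
  normalization) or *per-gene-module* (each gene follows its own
  trajectory across time points — removable only by a within-module
  ratio, the regime where pairwise normalization has its advantage);
* planted differentially expressed genes with known fold changes, active
  in case samples at every time point;
* planted *stable partners*: for selected targets a partner gene is given
  exactly the target's batch trajectory, so the target/partner ratio
  carries counting noise only.

Counts are negative binomial with variance = mean + phi·mean².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, CountMatrix, DataError, SampleDesign

__all__ = ["SimConfig", "SimTruth", "simulate_counts", "truth_eval",
           "partner_recovery"]


@dataclass
class SimConfig:
    """Parameters of one simulated study.

    Defaults mirror a three-time-point blood study with 19 control and 18
    case subjects, each sampled at every time point, at a desk-scale gene
    count.
    """

    n_genes: int = 2000
    controls_per_tp: int = 19
    cases_per_tp: int = 18
    n_timepoints: int = 3
    log_mean: float = float(np.log(100.0))  # natural-log mean of baseline abundance
    log_sd: float = 1.5
    dispersion: float = 0.1  # NB phi; 0 -> Poisson
    libsize_log_sd: float = 0.3
    batch_mode: str = "module"  # "none" | "global" | "module"
    batch_log_sd: float = 0.4
    n_degs: int = 20
    fold_range: tuple[float, float] = (2.0, 4.0)
    deg_direction: str = "both"  # "up" | "down" | "both"
    n_stable_pairs: int = 20
    #: planted DEGs/partners are drawn from genes above this baseline-abundance
    #: quantile: the workflow analyzes abundantly expressed genes only, so
    #: planted truth must live in that regime to be measurable at all
    plant_abundance_quantile: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 3:
            raise DataError("need at least 3 genes")
        extra = max(0, self.n_stable_pairs - self.n_degs)
        n_plantable = int(self.n_genes * (1.0 - self.plant_abundance_quantile))
        if self.n_degs + self.n_stable_pairs + extra > n_plantable:
            raise DataError(
                "planted features exceed the number of genes above the "
                "plant_abundance_quantile"
            )
        if not 0.0 <= self.plant_abundance_quantile < 1.0:
            raise DataError("plant_abundance_quantile must lie in [0, 1)")
        if min(self.fold_range) <= 0:
            raise DataError("fold changes must be positive")
        if self.dispersion < 0:
            raise DataError("dispersion must be non-negative")
        if self.batch_mode not in ("none", "global", "module"):
            raise DataError(f"unknown batch_mode {self.batch_mode!r}")
        if self.controls_per_tp < 1 or self.cases_per_tp < 1:
            raise DataError("need at least one sample per group per time point")


@dataclass
class SimTruth:
    """Ground-truth ledger emitted alongside a simulated matrix."""

    deg_folds: dict  # gene id -> fold applied in case samples
    stable_pairs: list  # (target gene id, partner gene id)
    batch: pd.DataFrame  # genes x time points, realized multipliers
    lib_sizes: pd.Series  # per-sample library scale
    seed: int

    @property
    def deg_ids(self) -> set:
        return set(self.deg_folds)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "degs": pd.DataFrame(
                {"gene_id": list(self.deg_folds),
                 "fold": list(self.deg_folds.values())}
            ),
            "stable_pairs": pd.DataFrame(
                self.stable_pairs, columns=["target_gene", "partner_gene"]
            ),
            "batch": self.batch.reset_index(names="gene_id"),
            "lib_sizes": self.lib_sizes.rename("scale")
            .rename_axis("sample_id")
            .reset_index(),
        }


def _time_labels(n: int) -> list[str]:
    if n == 3:
        return ["d3", "d7", "d10"]
    return [f"d{i + 1}" for i in range(n)]


def simulate_counts(
    config: SimConfig,
) -> tuple[CountMatrix, SampleDesign, SimTruth]:
    """Draw one study: counts, design and the truth ledger.

    Deterministic given ``config.seed``.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    tps = _time_labels(cfg.n_timepoints)

    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    lam = rng.lognormal(cfg.log_mean, cfg.log_sd, cfg.n_genes)

    # sample layout: every control subject then every case subject, at each tp
    rows = []
    for tp in tps:
        for s in range(cfg.controls_per_tp):
            rows.append((f"C{s + 1:02d}_{tp}", CONTROL, tp, f"C{s + 1:02d}"))
        for s in range(cfg.cases_per_tp):
            rows.append((f"T{s + 1:02d}_{tp}", CASE, tp, f"T{s + 1:02d}"))
    design = SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "group", "time_point",
                                    "subject_id"])
    )
    n_samples = len(rows)
    lib = rng.lognormal(0.0, cfg.libsize_log_sd, n_samples)

    # planted features: DEGs first, then stable partners (non-DEG genes);
    # pair partners to DEG targets first, remaining pairs to null targets.
    # Features are planted above the configured abundance quantile.
    threshold = np.quantile(lam, cfg.plant_abundance_quantile)
    plantable = np.flatnonzero(lam >= threshold)
    perm = plantable[rng.permutation(plantable.size)]
    deg_pos = perm[: cfg.n_degs]
    partner_pos = perm[cfg.n_degs : cfg.n_degs + cfg.n_stable_pairs]
    n_deg_paired = min(cfg.n_degs, cfg.n_stable_pairs)
    extra_targets = perm[
        cfg.n_degs + cfg.n_stable_pairs :
        cfg.n_degs + 2 * cfg.n_stable_pairs - n_deg_paired
    ]
    target_pos = np.concatenate([deg_pos[:n_deg_paired], extra_targets])

    folds = rng.uniform(cfg.fold_range[0], cfg.fold_range[1], cfg.n_degs)
    if cfg.deg_direction == "down":
        folds = 1.0 / folds
    elif cfg.deg_direction == "both":
        flip = rng.random(cfg.n_degs) < 0.5
        folds[flip] = 1.0 / folds[flip]
    fold_vec = np.ones(cfg.n_genes)
    fold_vec[deg_pos] = folds

    # batch multipliers per (gene, time point)
    if cfg.batch_mode == "none":
        B = np.ones((cfg.n_genes, cfg.n_timepoints))
    elif cfg.batch_mode == "global":
        B = np.tile(
            rng.lognormal(0.0, cfg.batch_log_sd, cfg.n_timepoints),
            (cfg.n_genes, 1),
        )
    else:  # module: one trajectory per gene; partners copy their target's
        B = rng.lognormal(0.0, cfg.batch_log_sd,
                          (cfg.n_genes, cfg.n_timepoints))
    stable_pairs: list[tuple[str, str]] = []
    for t_pos, p_pos in zip(target_pos, partner_pos):
        B[p_pos] = B[t_pos]
        stable_pairs.append((gene_ids[t_pos], gene_ids[p_pos]))

    tp_index = {tp: i for i, tp in enumerate(tps)}
    tp_of = np.array([tp_index[tp] for _, _, tp, _ in rows])
    is_case = np.array([g == CASE for _, g, _, _ in rows])

    mu = (
        lam[:, None]
        * lib[None, :]
        * B[:, tp_of]
        * np.where(is_case[None, :], fold_vec[:, None], 1.0)
    )
    if cfg.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / cfg.dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                     columns=[sid for sid, *_ in rows])
    )
    truth = SimTruth(
        deg_folds={gene_ids[i]: float(fold_vec[i]) for i in deg_pos},
        stable_pairs=stable_pairs,
        batch=pd.DataFrame(B, index=pd.Index(gene_ids, name="gene_id"),
                           columns=tps),
        lib_sizes=pd.Series(lib, index=[sid for sid, *_ in rows]),
        seed=cfg.seed,
    )
    return cm, design, truth


def truth_eval(results: pd.DataFrame, truth: SimTruth,
               alpha: float = 0.05) -> dict:
    """Recovery metrics of a caller against the planted truth.

    ``results`` is a gene-level table (``gene_id``/``p_adj``) or a target
    summary (``target_gene``/``best_p_adj``); features with adjusted p
    below ``alpha`` are the calls.  FDR of an empty call set is 0 by
    convention.
    """
    if "gene_id" in results.columns:
        ids, padj = results["gene_id"], results["p_adj"]
    elif "target_gene" in results.columns:
        ids, padj = results["target_gene"], results["best_p_adj"]
    else:
        raise DataError("results must carry gene_id/p_adj or "
                        "target_gene/best_p_adj columns")
    known = set(ids)
    unknown = truth.deg_ids - set(truth.batch.index)
    if unknown:
        raise DataError(f"truth genes missing from simulation: {sorted(unknown)[:5]}")
    calls = set(ids[np.asarray(padj, dtype=float) < alpha])
    tp = len(calls & truth.deg_ids)
    fp = len(calls - truth.deg_ids)
    tpr = tp / len(truth.deg_ids) if truth.deg_ids else 0.0
    fdr = fp / len(calls) if calls else 0.0
    return {
        "tpr": tpr,
        "fdr": fdr,
        "n_calls": len(calls),
        "n_true": len(truth.deg_ids),
        "n_scored": len(known),
    }


def partner_recovery(db_pairs: pd.DataFrame, truth: SimTruth) -> dict:
    """Fraction of planted partners found among their target's candidates.

    ``db_pairs`` is a candidate database table (``target_gene``,
    ``index_gene``).  Only planted pairs whose target appears in the
    database are scored.
    """
    by_target = db_pairs.groupby("target_gene")["index_gene"].apply(list)
    hits = 0
    scored = 0
    for target, partner in truth.stable_pairs:
        if target not in by_target.index:
            continue
        scored += 1
        if partner in by_target[target]:
            hits += 1
    return {
        "recovered": hits,
        "scored": scored,
        "fraction": hits / scored if scored else 0.0,
    }
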
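"""The ratio-transformation core: index selection, pair testing, filtering.

The method replaces a target gene's read count with its per-sample ratio to
an *index gene* — a gene whose expression tracks the target's under control
conditions but does not itself respond to the condition.  Because the ratio
is formed within each sample, any per-sample multiplicative distortion
(sequencing depth, global batch scaling, shared regulatory drift) cancels
exactly; this is the property the whole workflow rests on.

Pipeline order:

1. :func:`candidate_indexes` / :func:`build_candidate_db` — for every
   target, rank all other genes by the NSD (coefficient of variation) of
   the target/index ratio across *control samples only* and keep the ``k``
   most stable.
2. :func:`test_pairs` — equal-variance t-test of the ratio between control
   and case samples, BH-adjusted with the full family size ``m``.
3. :func:`filter_index_validity` — drop pairs whose index gene itself
   responds to the condition (RLE-based adjusted p ≤ alpha).
4. :func:`summarize_targets` — the smallest adjusted p among a target's
   retained pairs defines its significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, CountMatrix, DataError, SampleDesign
from .stats import bh_adjust, t_equal_var_rows

__all__ = [
    "DirtDatabase",
    "TargetSummaries",
    "nsd",
    "candidate_indexes",
    "build_candidate_db",
    "test_pairs",
    "filter_index_validity",
    "summarize_targets",
    "extend_candidates",
    "pair_ratios",
]


def nsd(values, kind: str = "cv") -> float:
    """Normalized standard deviation of a ratio vector.

    ``kind="cv"`` (default): sample standard deviation (n−1 denominator)
    divided by the mean — the coefficient of variation.  Alternatives:
    ``"sd_over_median"`` and ``"sd_of_log"`` (standard deviation of the
    natural log of the values).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DataError("NSD needs at least 2 values")
    if np.any(v < 0):
        raise DataError("NSD is defined for non-negative values")
    if kind == "cv":
        center = v.mean()
    elif kind == "sd_over_median":
        center = float(np.median(v))
    elif kind == "sd_of_log":
        if np.any(v <= 0):
            return np.nan
        return float(np.std(np.log(v), ddof=1))
    else:
        raise ValueError(f"unknown NSD kind {kind!r}")
    if center <= 0:
        return np.nan
    return float(np.std(v, ddof=1) / center)


@dataclass
class DirtDatabase:
    """An ordered collection of target–index pairs with their statistics.

    ``pairs`` always has ``target_gene, index_gene, nsd``; after
    :func:`test_pairs` it gains ``t, p, p_adj`` and after
    :func:`filter_index_validity` the ``index_valid`` flag.
    """

    pairs: pd.DataFrame
    params: dict = field(default_factory=dict)
    skipped_targets: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def targets(self) -> list[str]:
        seen: list[str] = []
        for t in self.pairs["target_gene"]:
            if t not in seen:
                seen.append(t)
        return seen


# ---------------------------------------------------------------------------
# candidate index selection


def _control_matrix(counts: CountMatrix, design: SampleDesign) -> CountMatrix:
    design.check_pairing(counts)
    ctrl = design.samples_in_group(CONTROL)
    if len(ctrl) < 2:
        raise DataError("index selection needs at least 2 control samples")
    return counts.subset_samples(ctrl)


def _eligible_index_ids(control_counts: CountMatrix) -> list[str]:
    """Genes usable as indexes: strictly positive in every control sample.

    Returned sorted lexicographically so that positional stable sorts break
    NSD ties toward the smaller gene id.
    """
    positive = (control_counts.data > 0).all(axis=1)
    return sorted(control_counts.data.index[positive])

def _nsd_block(T: np.ndarray, E: np.ndarray) -> np.ndarray:
    """NSD of ratio vectors for a block of targets against all indexes.

    ``T`` is (b, S) target counts, ``E`` is (ne, S) index counts; returns a
    (b, ne) matrix of coefficients of variation of T/E across samples.
    """
    S = T.shape[1]
    R = T[:, None, :] / E[None, :, :]
    m = R.mean(axis=2)
    sd = np.sqrt(((R - m[..., None]) ** 2).sum(axis=2) / (S - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return sd / m


def _top_k_positions(row: np.ndarray, k: int) -> np.ndarray:
    """Positions of the k smallest values; ties broken by position order."""
    if row.size == k:
        kth = np.max(row)
    else:
        kth = np.partition(row, k - 1)[k - 1]
    cand = np.flatnonzero(row <= kth)
    order = cand[np.lexsort((cand, row[cand]))]
    return order[:k]


def candidate_indexes(
    control_counts: CountMatrix, target: str, k: int = 10
) -> pd.DataFrame:
    """Rank index candidates for one target over control samples.

    Every other gene with no zero control count is scored by the NSD of the
    per-sample ratio target/index; the ``k`` lowest-NSD genes are returned
    (columns ``index_gene, nsd``), ties broken lexicographically.
    """
    db = build_candidate_db(
        control_counts, None, targets=[target], k=k, on_error="strict"
    )
    return db.pairs[["index_gene", "nsd"]].reset_index(drop=True)


def build_candidate_db(
    counts: CountMatrix,
    design: SampleDesign | None,
    targets: list[str] | None = None,
    k: int = 10,
    block_size: int | None = None,
    on_error: str = "warn",
) -> DirtDatabase:
    """Build the target–index candidate database over control samples.

    Parameters
    ----------
    counts, design
        Count matrix and its design; only control samples are used.  Pass
        ``design=None`` when ``counts`` already holds control samples only.
    targets
        Targets to scan (default: every gene in ``counts``).
    k
        Candidate indexes kept per target.
    block_size
        Targets per vectorized block; results are independent of it.
    on_error
        ``"warn"`` skips targets that cannot be scanned (recorded in
        ``skipped_targets``); ``"strict"`` raises.
    """
    ctrl = counts if design is None else _control_matrix(counts, design)
    if ctrl.n_samples < 2:
        raise DataError("need at least 2 control samples")
    if targets is None:
        targets = ctrl.gene_ids
    else:
        missing = [t for t in targets if t not in ctrl.data.index]
        if missing:
            raise DataError(f"targets absent from count matrix: {missing[:5]}")
    if k <= 0:
        raise ValueError("k must be positive")

    eligible = _eligible_index_ids(ctrl)
    E = ctrl.data.loc[eligible].to_numpy(dtype=float)
    elig_pos = {g: i for i, g in enumerate(eligible)}
    n_elig = len(eligible)
    T_all = ctrl.data.loc[list(targets)].to_numpy(dtype=float)

    if block_size is None:
        # bound the (block, n_eligible, n_samples) ratio tensor near 200 MB
        per_target = max(1, n_elig * ctrl.n_samples * 8)
        block_size = int(np.clip(2e8 // per_target, 1, 4096))

    skipped: list[tuple[str, str]] = []
    rows_t: list[str] = []
    rows_i: list[np.ndarray] = []
    rows_n: list[np.ndarray] = []
    eligible_arr = np.asarray(eligible, dtype=object)

    for start in range(0, len(targets), block_size):
        chunk = list(targets[start : start + block_size])
        Tb = T_all[start : start + block_size]
        nsd_mat = _nsd_block(Tb, E)
        for local, target in enumerate(chunk):
            row = nsd_mat[local]
            pos_self = elig_pos.get(target)
            if pos_self is not None:
                row = row.copy()
                row[pos_self] = np.inf
            n_avail = n_elig - (pos_self is not None)
            if not np.any(Tb[local] > 0):
                msg = "target has no positive control count"
                if on_error == "strict":
                    raise DataError(f"{target}: {msg}")
                skipped.append((target, msg))
                continue
            if n_avail < k:
                msg = f"only {n_avail} eligible index genes (< k={k})"
                if on_error == "strict":
                    raise DataError(f"{target}: {msg}")
                skipped.append((target, msg))
                continue
            top = _top_k_positions(row, k)
            rows_t.append(target)
            rows_i.append(eligible_arr[top])
            rows_n.append(row[top])

    if skipped and on_error == "warn":
        warnings.warn(
            f"{len(skipped)} targets skipped during candidate scan "
            f"(first: {skipped[0]})",
            stacklevel=2,
        )
    pairs = pd.DataFrame(
        {
            "target_gene": np.repeat(np.asarray(rows_t, dtype=object), k)
            if rows_t
            else np.array([], dtype=object),
            "index_gene": np.concatenate(rows_i)
            if rows_i
            else np.array([], dtype=object),
            "nsd": np.concatenate(rows_n) if rows_n else np.array([], dtype=float),
        }
    )
    params = {
        "k": k,
        "n_targets_requested": len(targets),
        "n_targets_scanned": len(rows_t),
        "n_eligible_indexes": n_elig,
        "n_control_samples": ctrl.n_samples,
    }
    return DirtDatabase(pairs=pairs, params=params, skipped_targets=skipped)


def extend_candidates(
    counts: CountMatrix,
    design: SampleDesign,
    target: str,
    k_extended: int = 100,
    k: int = 10,
) -> pd.DataFrame:
    """Re-rank index candidates for one target with a larger list.

    The first ``k`` rows equal the :func:`candidate_indexes` output; the
    extension rescues targets whose top-``k`` indexes were all condition
    responsive.
    """
    if k_extended < k:
        raise DataError(f"k_extended={k_extended} smaller than k={k}")
    ctrl = _control_matrix(counts, design)
    return candidate_indexes(ctrl, target, k=k_extended)


# ---------------------------------------------------------------------------
# pair testing


def pair_ratios(
    counts: CountMatrix,
    target: str,
    index: str,
    pseudocount: float = 0.0,
) -> pd.Series:
    """Per-sample ratio of target to index read counts."""
    t = counts.data.loc[target].astype(float) + pseudocount
    i = counts.data.loc[index].astype(float) + pseudocount
    return t / i


def test_pairs(
    db: DirtDatabase,
    counts: CountMatrix,
    design: SampleDesign,
    m: int,
    zero_policy: str = "drop",
    pseudocount: float = 0.5,
    per_timepoint: bool = False,
) -> DirtDatabase:
    """Control-vs-case t-tests on every pair's ratio vector.

    BH adjustment runs across all tested pairs with family size ``m``
    (the full candidate-database scale).  Pairs whose index gene has a zero
    count in a case sample are dropped with a warning (``zero_policy=
    "drop"``) or rescued by adding ``pseudocount`` to both numerator and
    denominator (``zero_policy="pseudocount"``).
    """
    if m < len(db):
        raise DataError(f"BH family size m={m} smaller than database size {len(db)}")
    if zero_policy not in ("drop", "pseudocount"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    design.check_pairing(counts)
    design.require_group_sizes(2)
    ctrl = design.samples_in_group(CONTROL)
    case = design.samples_in_group(CASE)

    pairs = db.pairs.copy()
    tg = counts.data.loc[pairs["target_gene"]].to_numpy(dtype=float)
    ig = counts.data.loc[pairs["index_gene"]].to_numpy(dtype=float)
    col = {s: j for j, s in enumerate(counts.sample_ids)}
    ctrl_j = [col[s] for s in ctrl]
    case_j = [col[s] for s in case]

    index_zero = (ig == 0).any(axis=1)
    n_zero = int(index_zero.sum())
    if n_zero and zero_policy == "drop":
        warnings.warn(
            f"{n_zero} pairs dropped: index gene has a zero count in some sample",
            stacklevel=2,
        )
        keep = ~index_zero
        pairs = pairs.loc[keep].reset_index(drop=True)
        tg, ig = tg[keep], ig[keep]
    elif n_zero:
        tg = tg + pseudocount
        ig = ig + pseudocount

    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = tg / ig
    X = ratios[:, ctrl_j]
    Y = ratios[:, case_j]
    t, p = t_equal_var_rows(X, Y)
    pairs["t"] = t
    pairs["p"] = p
    pairs["p_adj"] = bh_adjust(p, m)
    if per_timepoint:
        tab = design.table
        for tp in design.time_points:
            sel = tab[tab["time_point"] == tp]
            c_tp = [col[s] for s in sel[sel["group"] == CONTROL]["sample_id"]]
            k_tp = [col[s] for s in sel[sel["group"] == CASE]["sample_id"]]
            if len(c_tp) < 2 or len(k_tp) < 2:
                raise DataError(
                    f"time point {tp!r} lacks 2 samples per group"
                )
            _, p_tp = t_equal_var_rows(ratios[:, c_tp], ratios[:, k_tp])
            pairs[f"p_{tp}"] = p_tp
    params = dict(db.params)
    params.update(
        {"m": m, "zero_policy": zero_policy, "n_zero_index_pairs": n_zero}
    )
    return DirtDatabase(pairs=pairs, params=params,
                        skipped_targets=list(db.skipped_targets))


# not a pytest item despite the name
test_pairs.__test__ = False  # type: ignore[attr-defined]


def filter_index_validity(
    db: DirtDatabase, gene_stats_rle: pd.DataFrame, alpha: float = 0.05
) -> DirtDatabase:
    """Drop pairs whose index gene responds to the condition.

    A pair is retained iff its index gene's RLE-based adjusted p-value is
    *strictly greater* than ``alpha`` (a boundary value exactly at alpha is
    excluded).  ``gene_stats_rle`` must cover every index gene and carry
    columns ``gene_id`` and ``p_adj`` adjusted at the candidate-gene family
    size.
    """
    if "p_adj" not in db.pairs.columns:
        raise DataError("database must be tested before filtering")
    lookup = gene_stats_rle.set_index("gene_id")["p_adj"]
    missing = sorted(set(db.pairs["index_gene"]) - set(lookup.index))
    if missing:
        raise DataError(f"index genes absent from gene statistics: {missing[:5]}")
    idx_padj = lookup[db.pairs["index_gene"]].to_numpy(dtype=float)
    valid = idx_padj > alpha
    pairs = db.pairs.assign(index_valid=valid)
    retained = pairs.loc[valid].reset_index(drop=True)
    params = dict(db.params)
    params.update(
        {
            "index_alpha": alpha,
            "n_before_filter": len(pairs),
            "n_after_filter": len(retained),
        }
    )
    return DirtDatabase(pairs=retained, params=params,
                        skipped_targets=list(db.skipped_targets))


# ---------------------------------------------------------------------------
# summaries


@dataclass
class TargetSummaries:
    """Per-target best pair; targets with no retained pair are listed aside."""

    table: pd.DataFrame  # target_gene, best_index_gene, best_p_adj, n_valid_pairs
    omitted_targets: list[str]


def summarize_targets(
    db: DirtDatabase, all_targets: list[str] | None = None
) -> TargetSummaries:
    """The smallest adjusted p among a target's retained pairs defines it.

    ``all_targets`` (default: targets seen in the tested database before
    filtering, if recorded, else targets present) determines which targets
    count as omitted when every one of their pairs was filtered away.
    """
    if "p_adj" not in db.pairs.columns:
        raise DataError("database must be tested before summarizing")
    pairs = db.pairs
    rows = []
    for target, grp in pairs.groupby("target_gene", sort=False):
        best = grp.sort_values(
            ["p_adj", "index_gene"], kind="stable"
        ).iloc[0]
        rows.append(
            {
                "target_gene": target,
                "best_index_gene": best["index_gene"],
                "best_p_adj": float(best["p_adj"]),
                "n_valid_pairs": int(len(grp)),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["target_gene", "best_index_gene", "best_p_adj", "n_valid_pairs"],
    )
    if len(table):
        table = table.sort_values(
            ["best_p_adj", "target_gene"], kind="stable"
        ).reset_index(drop=True)
    present = set(table["target_gene"])
    if all_targets is None:
        omitted: list[str] = []
    else:
        omitted = [t for t in all_targets if t not in present]
    return TargetSummaries(table=table, omitted_targets=omitted)
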
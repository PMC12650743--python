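"""Scaling normalizations for count matrices: CPM, RLE and TMM.

These are the global baselines the ratio transformation is compared
against.  All three are native implementations of the published
procedures:

* CPM — counts scaled by library total, times one million.
* RLE (median-of-ratios) — each sample is compared with a pseudo-reference
  built from per-gene geometric means; the size factor is the median ratio.
  Genes with a zero in any sample are excluded from the reference.
* TMM — per-sample scale factors from doubly trimmed, precision-weighted
  log2 fold changes against a reference sample (the one whose 75th CPM
  percentile is closest to the mean), rescaled so the factors multiply to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, DataError

__all__ = [
    "SizeFactors",
    "NormMatrix",
    "cpm",
    "select_abundant",
    "rle_size_factors",
    "tmm_factors",
    "apply_normalization",
]


@dataclass
class SizeFactors:
    """Per-sample positive scale factors plus the method that produced them."""

    factors: pd.Series  # index = sample_id
    method: str  # "rle" | "tmm" | "libsize"

    def __post_init__(self) -> None:
        f = self.factors.to_numpy(dtype=float)
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise DataError(f"size factors must be positive and finite ({self.method})")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.factors.index, "factor": self.factors.to_numpy()}
        )


@dataclass
class NormMatrix:
    """Normalized gene-by-sample expression values with a method tag."""

    data: pd.DataFrame
    method: str

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def cpm(counts: CountMatrix) -> NormMatrix:
    """Counts per million: each column scaled to sum to 1e6."""
    totals = counts.data.sum(axis=0)
    dead = totals[totals <= 0]
    if len(dead):
        raise DataError(f"zero library size for samples: {list(dead.index)}")
    values = counts.data.div(totals, axis=1) * 1e6
    return NormMatrix(values, "cpm")


def select_abundant(counts: CountMatrix, n_top: int) -> tuple[list[str], float]:
    """Pick the ``n_top`` most abundant genes by mean CPM over all samples.

    Returns the selected gene ids (ranked, most abundant first) and the mean
    CPM of the last admitted gene — the effective abundance threshold.
    Boundary ties are broken toward the lexicographically smaller gene id.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > counts.n_genes:
        raise DataError(
            f"n_top={n_top} exceeds gene count {counts.n_genes}"
        )
    mean_cpm = cpm(counts).data.mean(axis=1)
    # rank on (-cpm, gene id): boundary ties go to the smaller id
    order = sorted(mean_cpm.index, key=lambda g: (-mean_cpm[g], g))
    selected = order[:n_top]
    threshold = float(mean_cpm[selected[-1]])
    return selected, threshold


def rle_size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors against a geometric-mean reference.

    Only genes positive in every sample contribute to the reference; the
    factor for sample *j* is the median over those genes of
    ``count(g, j) / reference(g)``.
    """
    values = counts.values()
    positive = np.all(values > 0, axis=1)
    if not positive.any():
        raise DataError("no gene has positive counts in every sample; "
                        "cannot build RLE reference")
    sub = values[positive]
    log_ref = np.mean(np.log(sub), axis=1)
    ratios = sub / np.exp(log_ref)[:, None]
    factors = np.median(ratios, axis=0)
    return SizeFactors(
        pd.Series(factors, index=counts.data.columns, name="factor"), "rle"
    )


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Single-sample TMM factor versus the reference column."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        log_r = np.log2(p_obs / p_ref)
        abs_e = (np.log2(p_obs) + np.log2(p_ref)) / 2.0
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    keep = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[keep], abs_e[keep], v[keep]
    if log_r.size == 0:
        warnings.warn("no genes usable for TMM; factor set to 1", stacklevel=3)
        return 1.0
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_r = pd.Series(log_r).rank().to_numpy()
    rank_e = pd.Series(abs_e).rank().to_numpy()
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        warnings.warn("no genes survive TMM trimming; factor set to 1",
                      stacklevel=3)
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def tmm_factors(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> SizeFactors:
    """Trimmed-mean-of-M-values scale factors.

    ``trim_m`` and ``trim_a`` are the per-tail trim fractions on the log
    fold change (M) and average abundance (A) axes.  The returned factors
    are rescaled so their product is exactly 1.
    """
    if counts.n_samples < 2:
        raise DataError("TMM needs at least 2 samples")
    values = counts.values()
    lib = values.sum(axis=0)
    if np.any(lib <= 0):
        raise DataError("TMM requires positive library sizes")
    # reference column: 75th percentile of count proportions closest to mean
    q75 = np.quantile(values, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array(
        [
            _tmm_pair_factor(values[:, j], values[:, ref_idx], lib[j],
                             lib[ref_idx], trim_m, trim_a)
            for j in range(values.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return SizeFactors(
        pd.Series(factors, index=counts.data.columns, name="factor"), "tmm"
    )


def apply_normalization(counts: CountMatrix, factors: SizeFactors) -> NormMatrix:
    """Divide counts by per-sample scale factors.

    Conventions per method: ``rle`` divides counts by the size factor only
    (DESeq2-style normalized counts); ``tmm`` and ``libsize`` divide by the
    effective library size (library total × factor) and scale to one million
    (edgeR-style effective CPM).
    """
    missing = [s for s in counts.sample_ids if s not in factors.factors.index]
    if missing:
        raise DataError(f"no size factor for samples: {missing[:5]}")
    f = factors.factors[counts.data.columns]
    if factors.method == "rle":
        values = counts.data.div(f, axis=1)
    elif factors.method in ("tmm", "libsize"):
        lib = counts.data.sum(axis=0)
        values = counts.data.div(lib * f, axis=1) * 1e6
    else:
        raise DataError(f"unknown size-factor method {factors.method!r}")
    return NormMatrix(values.astype(float), factors.method)
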
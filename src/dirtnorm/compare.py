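"""Method-comparison utilities: top-k lists, Venn overlaps, heatmap prep."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .containers import CASE, CONTROL, DataError, SampleDesign
from .normalize import NormMatrix

__all__ = [
    "FeatureSet",
    "top_features",
    "unique_targets",
    "overlap_counts",
    "heatmap_matrix",
]


@dataclass
class FeatureSet:
    """Ordered feature ids selected from one method's results."""

    method: str
    ids: list[str]  # ordered by ascending p_adj, lexicographic tie-break
    rule: dict  # e.g. {"k": 1000, "statistic": "p_adj"}

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            dup = [i for i in self.ids if self.ids.count(i) > 1]
            raise DataError(f"duplicate feature ids: {sorted(set(dup))[:5]}")

    def __len__(self) -> int:
        return len(self.ids)


def _id_and_p_columns(stats: pd.DataFrame) -> tuple[str, str]:
    if "gene_id" in stats.columns:
        return "gene_id", "p_adj"
    if "target_gene" in stats.columns and "p_adj" in stats.columns:
        return "target_gene", "p_adj"
    if "target_gene" in stats.columns and "best_p_adj" in stats.columns:
        return "target_gene", "best_p_adj"
    raise DataError("unrecognized result table layout")


def top_features(
    stats: pd.DataFrame, k: int, method: str = "", pair_level: bool = False
) -> FeatureSet:
    """The ``k`` features with the smallest adjusted p-values.

    For pair-level tables (``pair_level=True``) the selected features are
    pairs, identified as ``target/index``; otherwise the id column is used
    directly.  Ties at the boundary are broken lexicographically.
    """
    if k > len(stats):
        raise DataError(f"k={k} exceeds table size {len(stats)}")
    id_col, p_col = _id_and_p_columns(stats)
    tab = stats.copy()
    if pair_level:
        if "index_gene" not in tab.columns:
            raise DataError("pair_level requires an index_gene column")
        tab["_feature"] = tab["target_gene"] + "/" + tab["index_gene"]
        id_col = "_feature"
    tab = tab.sort_values([p_col, id_col], kind="stable").head(k)
    return FeatureSet(
        method=method,
        ids=list(tab[id_col]),
        rule={"k": k, "statistic": p_col, "pair_level": pair_level},
    )


def unique_targets(pairs: pd.DataFrame, k: int | None = None,
                   method: str = "") -> FeatureSet:
    """Deduplicate a ranked pair table to unique target genes.

    The input is ordered (or is ordered here) by ascending adjusted p;
    the first occurrence — the best pair — of each target is kept.  With
    ``k`` the table is first cut to its top-``k`` pairs.
    """
    id_col, p_col = _id_and_p_columns(pairs)
    if id_col != "target_gene":
        raise DataError("unique_targets expects a pair-level table")
    tab = pairs.sort_values([p_col, "target_gene", "index_gene"],
                            kind="stable")
    if k is not None:
        if k > len(tab):
            raise DataError(f"k={k} exceeds table size {len(tab)}")
        tab = tab.head(k)
    tab = tab.drop_duplicates(subset="target_gene", keep="first")
    return FeatureSet(
        method=method,
        ids=list(tab["target_gene"]),
        rule={"k": k, "statistic": p_col, "deduplicated": True},
    )


def overlap_counts(sets: list[FeatureSet]) -> dict[str, int]:
    """Exact Venn-region cardinalities for 2 or 3 feature sets.

    Keys are sorted '+'-joined method names per region (e.g. ``"dirt"``,
    ``"dirt+rle"``, ``"dirt+rle+tmm"``); values are exclusive region
    counts, summing to the size of the union.
    """
    if not 2 <= len(sets) <= 3:
        raise DataError("overlap_counts takes 2 or 3 feature sets")
    names = [s.method or f"set{i}" for i, s in enumerate(sets)]
    if len(set(names)) != len(names):
        raise DataError("feature sets need distinct method names")
    members = {n: set(s.ids) for n, s in zip(names, sets)}
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            outside = [n for n in names if n not in inside]
            region = set.intersection(*(members[n] for n in inside))
            for n in outside:
                region -= members[n]
            regions["+".join(sorted(inside))] = len(region)
    return regions


def heatmap_matrix(
    values: NormMatrix | pd.DataFrame,
    features: FeatureSet,
    design: SampleDesign,
) -> pd.DataFrame:
    """Per-feature expression relative to its mean over all samples.

    Each cell is value / row-mean, so every row has mean exactly 1; values
    above 1 read as above-average (the conventional red), below 1 as
    below-average (blue).  Columns are ordered by (group, time point,
    sample id); rows follow the feature set's order.
    """
    data = values.data if isinstance(values, NormMatrix) else values
    missing = [f for f in features.ids if f not in data.index]
    if missing:
        raise DataError(f"features absent from value matrix: {missing[:5]}")
    tab = design.table
    order = tab.sort_values(
        ["group", "time_point", "sample_id"],
        key=lambda c: c.map({CONTROL: 0, CASE: 1}) if c.name == "group" else c,
        kind="stable",
    )["sample_id"]
    sub = data.loc[features.ids, list(order)]
    row_means = sub.mean(axis=1)
    dead = row_means[row_means == 0]
    if len(dead):
        raise DataError(f"features with zero mean: {list(dead.index)[:5]}")
    return sub.div(row_means, axis=0)
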
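"""Core in-memory containers: count matrices and sample-design tables.

The whole workflow operates on two objects: a gene-by-sample matrix of raw
read counts (:class:`CountMatrix`) and a per-sample metadata table
(:class:`SampleDesign`).  Both are thin, validated wrappers around
:class:`pandas.DataFrame` so that downstream code can rely on their
invariants (non-negative integral counts, unique identifiers, matching
sample sets) without re-checking them at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "DataError",
    "CONTROL",
    "CASE",
]

#: canonical group labels
CONTROL = "control"
CASE = "case"


class DataError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class CountMatrix:
    """Gene-by-sample matrix of raw read counts.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as the index and sample identifiers
        as the columns.  Values must be non-negative integers.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene ids: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dup}")
        values = df.to_numpy()
        if values.size == 0:
            raise DataError("empty count matrix")
        if not np.issubdtype(values.dtype, np.number):
            raise DataError("counts must be numeric")
        if np.any(values < 0):
            g, s = np.argwhere(values < 0)[0]
            raise DataError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                g, s = np.argwhere(np.mod(values, 1) != 0)[0]
                raise DataError(
                    f"non-integer count at gene {df.index[g]!r}, "
                    f"sample {df.columns[s]!r}"
                )
            self.data = df.astype(np.int64)

    # -- basic accessors ---------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.float64)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise DataError(f"unknown gene ids: {missing[:5]}")
        return CountMatrix(self.data.loc[list(gene_ids)])

    def subset_samples(self, sample_ids) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise DataError(f"unknown sample ids: {missing[:5]}")
        return CountMatrix(self.data[list(sample_ids)])

    def validate_for_analysis(self) -> None:
        """Check every sample has at least one positive count."""
        totals = self.data.sum(axis=0)
        dead = totals[totals <= 0]
        if len(dead):
            raise DataError(
                f"samples with zero total counts: {list(dead.index)}"
            )


@dataclass
class SampleDesign:
    """Per-sample metadata: group (control/case), time point, subject.

    ``table`` must have columns ``sample_id``, ``group``, ``time_point`` and
    optionally ``subject_id``.  Group labels are canonical ``control`` /
    ``case``.
    """

    table: pd.DataFrame = field()

    REQUIRED = ("sample_id", "group", "time_point")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise DataError(f"design table missing required columns: {missing}")
        if "subject_id" not in t.columns:
            t = t.assign(subject_id=t["sample_id"])
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise DataError(f"duplicate sample ids in design: {dup}")
        bad = sorted(set(t["group"]) - {CONTROL, CASE})
        if bad:
            raise DataError(
                f"unknown group labels {bad}; allowed: ['{CASE}', '{CONTROL}']"
            )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def time_points(self) -> list[str]:
        seen: list[str] = []
        for tp in self.table["time_point"]:
            if tp not in seen:
                seen.append(tp)
        return seen

    def samples_in_group(self, group: str) -> list[str]:
        if group not in (CONTROL, CASE):
            raise DataError(f"unknown group {group!r}")
        sel = self.table[self.table["group"] == group]
        return list(sel["sample_id"])

    def check_pairing(self, counts: CountMatrix) -> None:
        """Verify the design covers exactly the matrix's samples."""
        design_ids = set(self.sample_ids)
        matrix_ids = set(counts.sample_ids)
        only_design = sorted(design_ids - matrix_ids)
        only_matrix = sorted(matrix_ids - design_ids)
        if only_design or only_matrix:
            raise DataError(
                "design/count-matrix sample mismatch: "
                f"design-only={only_design[:5]}, matrix-only={only_matrix[:5]}"
            )

    def require_group_sizes(self, minimum: int = 2) -> None:
        for group in (CONTROL, CASE):
            n = len(self.samples_in_group(group))
            if n < minimum:
                raise DataError(
                    f"group {group!r} has {n} samples; at least {minimum} required"
                )
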
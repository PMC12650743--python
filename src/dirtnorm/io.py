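"""Reading and writing count matrices, design tables and result tables.

Supported input dialects:

* plain TSV — first column gene id, one column per sample;
* featureCounts default output — leading ``#`` comment line(s) and the
  annotation columns ``Geneid/Chr/Start/End/Strand/Length`` followed by one
  column per sample (annotation columns are recognised by name and dropped).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .containers import CASE, CONTROL, CountMatrix, DataError, SampleDesign

__all__ = ["read_counts", "read_design", "write_results", "read_results"]

_FEATURECOUNTS_ANNOTATION = {"Chr", "Start", "End", "Strand", "Length"}

#: spellings accepted for the two canonical group labels
DEFAULT_GROUP_MAP = {
    "control": CONTROL,
    "ctrl": CONTROL,
    "case": CASE,
    "tim": CASE,
}


def read_counts(path, format: str = "tsv", strict: bool = True) -> CountMatrix:
    """Read a gene-by-sample count matrix.

    Parameters
    ----------
    path
        File to read.
    format
        ``"tsv"`` (first column = gene id) or ``"featurecounts"``
        (featureCounts default output; ``#`` comments skipped, annotation
        columns dropped).
    strict
        If True (default), non-integer counts are an error; otherwise they
        are truncated toward zero with a warning (some quantifiers emit
        fractional counts for multi-mapping reads).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("tsv", "featurecounts"):
        raise ValueError(f"unknown count-matrix format {format!r}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        raise DataError(f"empty count file: {path}") from None
    if df.shape[1] < 2:
        raise DataError(f"count file {path} has no sample columns")
    gene_col = df.columns[0]
    if format == "featurecounts":
        drop = [c for c in df.columns if c in _FEATURECOUNTS_ANNOTATION]
        df = df.drop(columns=drop)
    if df[gene_col].duplicated().any():
        dup = df.loc[df[gene_col].duplicated(), gene_col].tolist()
        raise DataError(f"duplicate gene ids in {path}: {dup}")
    df = df.set_index(gene_col)
    df.index.name = "gene_id"
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        loc = numeric.isna().stack()
        gene, sample = loc[loc].index[0]
        raise DataError(
            f"non-numeric count at gene {gene!r}, sample {sample!r} in {path}"
        )
    if not strict:
        frac = (numeric % 1) != 0
        if frac.any().any():
            warnings.warn(
                f"{int(frac.to_numpy().sum())} non-integer counts truncated "
                f"while reading {path}",
                stacklevel=2,
            )
            numeric = numeric.apply(lambda c: c.astype(float)).astype("int64")
        else:
            numeric = numeric.astype("int64")
    return CountMatrix(numeric)


def read_design(path, group_map: dict[str, str] | None = None) -> SampleDesign:
    """Read a sample-design table (CSV or TSV, sniffed from the header line).

    Columns: ``sample_id``, ``group``, ``time_point``; ``subject_id``
    optional.  Group labels are lower-cased and mapped through ``group_map``
    (defaults accept control/ctrl and case/tim); anything else is an error
    listing the allowed labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    mapping = dict(DEFAULT_GROUP_MAP)
    if group_map:
        mapping.update({k.lower(): v for k, v in group_map.items()})
    if "group" in df.columns:
        raw = df["group"].str.lower()
        unknown = sorted(set(raw) - set(mapping))
        if unknown:
            raise DataError(
                f"unknown group labels {unknown}; allowed: "
                f"{sorted(set(mapping))} (mapped to control/case)"
            )
        df = df.assign(group=raw.map(mapping))
    return SampleDesign(df)


def write_results(records: pd.DataFrame, path, allow_empty: bool = False) -> None:
    """Write a result table (gene- or pair-level statistics) as TSV.

    Column order is preserved; floats are written at full round-trip
    precision so that ``read_results(write_results(x)) == x``.
    """
    if len(records) == 0 and not allow_empty:
        raise DataError("refusing to write an empty result table "
                        "(pass allow_empty=True to permit)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`.

    Uses correctly-rounded float parsing so numeric columns round-trip at
    full precision.
    """
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
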
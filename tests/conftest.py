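import pandas as pd
import pytest

from dirtnorm import CountMatrix, SampleDesign, SimConfig, simulate_counts


@pytest.fixture
def toy_counts() -> CountMatrix:
    """4 genes x 4 samples, no zeros, deterministic."""
    return CountMatrix(
        pd.DataFrame(
            {
                "c1": [10, 20, 5, 100],
                "c2": [12, 24, 6, 110],
                "t1": [40, 21, 5, 105],
                "t2": [44, 19, 6, 95],
            },
            index=pd.Index(["gA", "gB", "gC", "gD"], name="gene_id"),
        )
    )


@pytest.fixture
def toy_design() -> SampleDesign:
    return SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ["c1", "c2", "t1", "t2"],
                "group": ["control", "control", "case", "case"],
                "time_point": ["d3", "d3", "d3", "d3"],
                "subject_id": ["s1", "s2", "s3", "s4"],
            }
        )
    )


@pytest.fixture
def paper_layout_design() -> SampleDesign:
    """The published study layout: 19 controls and 18 cases x 3 time points."""
    rows = []
    for tp in ["d3", "d7", "d10"]:
        for i in range(19):
            rows.append((f"C{i + 1:02d}_{tp}", "control", tp, f"C{i + 1:02d}"))
        for i in range(18):
            rows.append((f"T{i + 1:02d}_{tp}", "case", tp, f"T{i + 1:02d}"))
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "group", "time_point",
                                    "subject_id"])
    )


@pytest.fixture
def small_sim():
    """A small seeded simulation shared across tests (200 genes, 5v5 x 2tp)."""
    cfg = SimConfig(
        n_genes=200,
        controls_per_tp=5,
        cases_per_tp=5,
        n_timepoints=2,
        n_degs=5,
        n_stable_pairs=5,
        fold_range=(4.0, 4.0),
        deg_direction="up",
        dispersion=0.05,
        seed=11,
    )
    return simulate_counts(cfg)
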
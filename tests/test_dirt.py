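import numpy as np
import pandas as pd
import pytest

from dirtnorm import (
    CountMatrix,
    DataError,
    SampleDesign,
    build_candidate_db,
    candidate_indexes,
    extend_candidates,
    filter_index_validity,
    nsd,
    summarize_targets,
    test_pairs,
)
from helpers import brute_candidates, brute_database


def _matrix(values, genes=None, samples=None) -> CountMatrix:
    values = np.asarray(values)
    genes = genes or [f"g{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=genes, columns=samples))


def _design(n_ctrl, n_case, tp="d3"):
    ids = [f"s{j}" for j in range(n_ctrl + n_case)]
    return SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ids,
                "group": ["control"] * n_ctrl + ["case"] * n_case,
                "time_point": [tp] * (n_ctrl + n_case),
            }
        )
    )


# -------------------------------------------------------------------- NSD


def test_nsd_examples_and_scale_invariance():
    assert nsd([7, 7, 7]) == 0.0
    assert nsd([1, 2, 3]) == pytest.approx(0.5)  # sd=1, mean=2
    v = np.array([3.0, 5.0, 9.0, 4.0])
    assert nsd(2 * v) == pytest.approx(nsd(v), rel=1e-12)


def test_nsd_alternative_definitions():
    v = [1.0, 2.0, 3.0]
    assert nsd(v, kind="sd_over_median") == pytest.approx(0.5)
    assert nsd(v, kind="sd_of_log") == pytest.approx(np.std(np.log(v), ddof=1))
    with pytest.raises(ValueError):
        nsd(v, kind="mad")


def test_nsd_degenerate_inputs():
    assert np.isnan(nsd([0.0, 0.0, 0.0]))
    with pytest.raises(DataError):
        nsd([1.0])


# -------------------------------------------------- candidate index scans


def test_exact_proportional_gene_is_rank_one_candidate():
    """Gene B = 2 x gene A in every control sample: the ratio A/B is constant,
    so B is the first candidate with NSD exactly 0."""
    a = np.array([10, 25, 13, 40])
    cm = _matrix(
        np.vstack([a, 2 * a, a + [3, 0, 5, 1], [7, 7, 8, 9]]),
        genes=["gA", "gB", "gC", "gD"],
    )
    out = candidate_indexes(cm, "gA", k=2)
    assert out.iloc[0]["index_gene"] == "gB"
    assert out.iloc[0]["nsd"] == 0.0


def test_candidate_scan_matches_brute_force():
    rng = np.random.default_rng(17)
    counts = rng.integers(0, 400, size=(50, 10))
    cm = _matrix(counts)
    for target in ["g000", "g007", "g031"]:
        mine = candidate_indexes(cm, target, k=10)
        ref = brute_candidates(cm.data, target, 10)
        assert list(mine["index_gene"]) == [g for g, _ in ref]
        np.testing.assert_allclose(mine["nsd"], [v for _, v in ref], rtol=1e-10)


def test_candidate_scan_requires_enough_eligible_genes():
    cm = _matrix([[5, 6], [7, 8], [9, 10]])
    with pytest.raises(DataError, match="eligible"):
        candidate_indexes(cm, "g000", k=10)


def test_genes_with_zero_control_counts_are_ineligible_indexes():
    cm = _matrix([[10, 20], [5, 0], [30, 60], [8, 9]])
    out = candidate_indexes(cm, "g000", k=2)
    assert "g001" not in set(out["index_gene"])


def test_database_size_and_order_independence():
    rng = np.random.default_rng(23)
    cm = _matrix(rng.integers(1, 300, size=(12, 8)))
    design = _design(5, 3)
    db = build_candidate_db(cm, design, targets=cm.gene_ids[:5], k=2)
    assert len(db) == 10  # 5 targets x 2
    # permuting sample order leaves the database identical
    perm = list(np.random.default_rng(1).permutation(cm.sample_ids))
    db_perm = build_candidate_db(cm.subset_samples(perm), design,
                                 targets=cm.gene_ids[:5], k=2)
    pd.testing.assert_frame_equal(db.pairs, db_perm.pairs)


def test_database_independent_of_block_size():
    rng = np.random.default_rng(29)
    cm = _matrix(rng.integers(1, 500, size=(40, 6)))
    full = build_candidate_db(cm, None, k=5, block_size=40)
    tiny = build_candidate_db(cm, None, k=5, block_size=3)
    pd.testing.assert_frame_equal(full.pairs, tiny.pairs)


def test_database_matches_brute_force_with_zeros_and_ties():
    rng = np.random.default_rng(31)
    counts = rng.integers(0, 60, size=(30, 7))  # plenty of zeros
    cm = _matrix(counts)
    db = build_candidate_db(cm, None, k=4, on_error="warn")
    ref = brute_database(cm.data, cm.gene_ids, 4)
    mine = list(
        zip(db.pairs["target_gene"], db.pairs["index_gene"], db.pairs["nsd"])
    )
    assert [(t, i) for t, i, _ in mine] == [(t, i) for t, i, _ in ref]
    np.testing.assert_allclose(
        [v for *_, v in mine], [v for *_, v in ref], rtol=1e-10
    )


def test_extend_candidates_prefix_property():
    rng = np.random.default_rng(37)
    cm = _matrix(rng.integers(1, 300, size=(40, 9)))
    design = _design(9, 0)
    design.table.loc[:, "group"] = "control"
    design = SampleDesign(design.table)
    base = candidate_indexes(cm, "g003", k=10)
    extended = extend_candidates(cm, design, "g003", k_extended=25, k=10)
    pd.testing.assert_frame_equal(extended.head(10), base)
    with pytest.raises(DataError, match="k_extended"):
        extend_candidates(cm, design, "g003", k_extended=5, k=10)


# ----------------------------------------------------------- pair testing


def test_identical_ratio_distributions_give_p_one():
    a = np.array([10, 20, 30, 40, 10, 20, 30, 40])
    cm = _matrix(np.vstack([a, 2 * a, a + 5]), genes=["gA", "gB", "gC"])
    design = _design(4, 4)
    db = build_candidate_db(cm.subset_samples(design.samples_in_group("control")),
                           None, targets=["gA"], k=1)
    tested = test_pairs(db, cm, design, m=1)
    assert tested.pairs.iloc[0]["index_gene"] == "gB"
    assert tested.pairs.iloc[0]["p"] == 1.0


def test_per_sample_scaling_leaves_all_statistics_unchanged():
    """Multiplying one sample's counts by 7 cancels in every ratio: NSD, t
    and p are bit-identical — the core invariance of the transformation."""
    rng = np.random.default_rng(41)
    cm = _matrix(rng.integers(1, 200, size=(20, 10)))
    design = _design(5, 5)
    scaled_values = cm.data.copy()
    scaled_values.iloc[:, 3] *= 7
    scaled = CountMatrix(scaled_values)

    db = build_candidate_db(cm, design, k=3)
    db_s = build_candidate_db(scaled, design, k=3)
    pd.testing.assert_frame_equal(db.pairs, db_s.pairs)

    t1 = test_pairs(db, cm, design, m=len(db))
    t2 = test_pairs(db_s, scaled, design, m=len(db_s))
    np.testing.assert_array_equal(t1.pairs["t"], t2.pairs["t"])
    np.testing.assert_array_equal(t1.pairs["p"], t2.pairs["p"])


def test_pair_family_size_must_cover_database():
    rng = np.random.default_rng(43)
    cm = _matrix(rng.integers(1, 200, size=(10, 8)))
    design = _design(4, 4)
    db = build_candidate_db(cm, design, k=2)
    with pytest.raises(DataError, match="family size"):
        test_pairs(db, cm, design, m=len(db) - 1)


def test_zero_policy_drop_versus_pseudocount():
    values = np.array(
        [
            [10, 20, 30, 15, 25, 35],
            [5, 10, 15, 8, 0, 18],  # zero in a case sample
            [9, 18, 27, 14, 23, 31],
        ]
    )
    cm = _matrix(values, genes=["gT", "gZ", "gO"])
    design = _design(3, 3)
    ctrl = cm.subset_samples(design.samples_in_group("control"))
    db = build_candidate_db(ctrl, None, targets=["gT"], k=2)
    assert set(db.pairs["index_gene"]) == {"gO", "gZ"}
    with pytest.warns(UserWarning, match="dropped"):
        dropped = test_pairs(db, cm, design, m=2, zero_policy="drop")
    assert set(dropped.pairs["index_gene"]) == {"gO"}
    kept = test_pairs(db, cm, design, m=2, zero_policy="pseudocount")
    assert len(kept) == 2
    assert np.isfinite(kept.pairs["p"]).all()


# ------------------------------------------------- validity filter, summary


def _tested_db_with_indices(index_padj: dict[str, float]) -> tuple:
    pairs = pd.DataFrame(
        {
            "target_gene": ["gT"] * len(index_padj),
            "index_gene": list(index_padj),
            "nsd": 0.1,
            "t": 1.0,
            "p": 0.5,
            "p_adj": 0.8,
        }
    )
    gene_stats = pd.DataFrame(
        {
            "gene_id": list(index_padj) + ["gT"],
            "p_adj": list(index_padj.values()) + [0.001],
        }
    )
    from dirtnorm.dirt import DirtDatabase

    return DirtDatabase(pairs=pairs), gene_stats


def test_index_validity_boundary_conventions():
    """Retained iff index adjusted p strictly exceeds alpha: 0.52 kept,
    0.04 excluded, exactly 0.05 excluded."""
    db, stats = _tested_db_with_indices({"gI1": 0.52, "gI2": 0.04, "gI3": 0.05})
    filtered = filter_index_validity(db, stats, alpha=0.05)
    assert list(filtered.pairs["index_gene"]) == ["gI1"]
    assert filtered.params["n_before_filter"] == 3
    assert filtered.params["n_after_filter"] == 1


def test_index_validity_requires_coverage():
    db, stats = _tested_db_with_indices({"gI1": 0.5})
    with pytest.raises(DataError, match="absent"):
        filter_index_validity(db, stats[stats["gene_id"] == "gT"], alpha=0.05)


def test_target_summaries_take_minimum_and_count_omitted():
    from dirtnorm.dirt import DirtDatabase

    pairs = pd.DataFrame(
        {
            "target_gene": ["gA", "gA", "gB"],
            "index_gene": ["gX", "gY", "gZ"],
            "nsd": 0.1,
            "t": 1.0,
            "p": [0.2, 0.005, 0.4],
            "p_adj": [0.3, 0.01, 0.5],
        }
    )
    db = DirtDatabase(pairs=pairs)
    out = summarize_targets(db, all_targets=["gA", "gB", "gC"])
    tab = out.table.set_index("target_gene")
    assert tab.loc["gA", "best_p_adj"] == 0.01
    assert tab.loc["gA", "best_index_gene"] == "gY"
    assert tab.loc["gA", "n_valid_pairs"] == 2
    assert out.omitted_targets == ["gC"]
    # ordering is by best adjusted p
    assert list(out.table["target_gene"]) == ["gA", "gB"]


def test_target_summaries_stable_under_pair_permutation():
    from dirtnorm.dirt import DirtDatabase

    pairs = pd.DataFrame(
        {
            "target_gene": ["gA", "gB", "gA", "gB"],
            "index_gene": ["gX", "gY", "gZ", "gW"],
            "nsd": 0.1,
            "t": 1.0,
            "p": [0.1, 0.2, 0.3, 0.05],
            "p_adj": [0.2, 0.4, 0.6, 0.1],
        }
    )
    a = summarize_targets(DirtDatabase(pairs=pairs))
    b = summarize_targets(
        DirtDatabase(pairs=pairs.sample(frac=1, random_state=3).reset_index(drop=True))
    )
    pd.testing.assert_frame_equal(a.table, b.table)
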
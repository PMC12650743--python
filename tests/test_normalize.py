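import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dirtnorm import (
    CountMatrix,
    DataError,
    apply_normalization,
    cpm,
    rle_size_factors,
    select_abundant,
    tmm_factors,
)


def _matrix(values, genes=None, samples=None) -> CountMatrix:
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=genes, columns=samples))


# ---------------------------------------------------------------------- CPM


def test_cpm_formula_and_symmetry():
    cm = _matrix([[1, 1], [1, 1], [2, 2]])
    out = cpm(cm).data
    np.testing.assert_allclose(out["s0"], [250_000, 250_000, 500_000])
    np.testing.assert_array_equal(out["s0"], out["s1"])


def test_cpm_columns_sum_to_one_million():
    rng = np.random.default_rng(3)
    cm = _matrix(rng.integers(0, 500, size=(20, 6)) + 1)
    totals = cpm(cm).data.sum(axis=0)
    np.testing.assert_allclose(totals, 1e6, rtol=1e-9)


def test_cpm_zero_library_names_sample():
    cm = _matrix([[1, 0], [2, 0]])
    with pytest.raises(DataError, match="s1"):
        cpm(cm)


# ------------------------------------------------------- abundance ranking


def test_select_abundant_ranking_and_threshold():
    # single-sample matrix: mean CPM order follows raw counts
    cm = _matrix([[10], [8], [6], [4], [2]], genes=list("abcde"))
    genes, threshold = select_abundant(cm, 3)
    assert genes == ["a", "b", "c"]
    assert threshold == pytest.approx(6 / 30 * 1e6)


def test_select_abundant_identity_and_bounds():
    cm = _matrix([[10], [8], [6]], genes=list("abc"))
    genes, threshold = select_abundant(cm, 3)
    assert genes == ["a", "b", "c"]
    assert threshold == pytest.approx(6 / 24 * 1e6)
    with pytest.raises(DataError):
        select_abundant(cm, 4)


def test_select_abundant_boundary_tie_is_lexicographic():
    cm = _matrix([[10], [4], [4]], genes=["a", "z", "b"])
    genes, _ = select_abundant(cm, 2)
    assert genes == ["a", "b"]


# ------------------------------------------------------------------- RLE


def test_rle_identical_libraries_give_unit_factors():
    cm = _matrix([[5, 5], [9, 9], [2, 2]])
    np.testing.assert_allclose(rle_size_factors(cm).factors, [1.0, 1.0])


def test_rle_pure_depth_scaling():
    """Library B = 3 x library A: geometric-mean reference splits the depth
    symmetrically, factors (1/sqrt(3), sqrt(3)) with ratio exactly 3."""
    a = np.array([10, 40, 200, 7, 33])
    cm = _matrix(np.column_stack([a, 3 * a]))
    f = rle_size_factors(cm).factors.to_numpy()
    np.testing.assert_allclose(f, [1 / np.sqrt(3), np.sqrt(3)], rtol=1e-12)
    assert f[1] / f[0] == pytest.approx(3.0, rel=1e-12)


def test_rle_excludes_zero_genes_from_reference():
    """Brute-force median-of-ratios on a 5x3 matrix with one zero-bearing gene."""
    values = np.array(
        [[10, 20, 30], [0, 5, 5], [100, 90, 110], [7, 7, 7], [50, 60, 40]]
    )
    cm = _matrix(values)
    keep = values[np.all(values > 0, axis=1)]
    ref = np.exp(np.mean(np.log(keep), axis=1))
    expected = np.median(keep / ref[:, None], axis=0)
    np.testing.assert_allclose(rle_size_factors(cm).factors, expected, rtol=1e-12)


def test_rle_matches_median_of_ratios_reference_implementation():
    """Frozen factors from an independent median-of-ratios implementation
    (odd gene count, so the linear and log-scale medians coincide)."""
    values = np.column_stack(
        [
            [173, 427, 485, 5, 484, 285, 217],
            [199, 450, 287, 307, 360, 372, 405],
            [211, 209, 195, 324, 19, 250, 307],
        ]
    )
    cm = _matrix(values, samples=["a", "b", "c"])
    oracle = [0.955877539845, 1.314065325009, 0.838489070039]
    np.testing.assert_allclose(rle_size_factors(cm).factors, oracle, atol=1e-9)


def test_rle_requires_a_zero_free_gene():
    cm = _matrix([[0, 1], [1, 0]])
    with pytest.raises(DataError, match="reference"):
        rle_size_factors(cm)


# ------------------------------------------------------------------- TMM


def test_tmm_identical_and_depth_scaled_libraries_give_unit_factors():
    a = np.array([30, 50, 200, 9, 120, 77])
    same = _matrix(np.column_stack([a, a, a]))
    np.testing.assert_allclose(tmm_factors(same).factors, 1.0, atol=1e-12)
    scaled = _matrix(np.column_stack([a, 5 * a]))
    np.testing.assert_allclose(tmm_factors(scaled).factors, 1.0, atol=1e-12)


def test_tmm_matches_reference_implementation_on_composition_bias():
    """Factors frozen from the published trimmed-mean-of-M-values reference
    implementation on a composition-biased matrix (one gene takes ~half of
    one library)."""
    rng = np.random.default_rng(42)
    counts = rng.negative_binomial(10, 10 / (10 + 100), size=(200, 4))
    counts[0, 2] = counts[:, 2].sum()
    counts[5, 3] = 3 * counts[5, 3] + 50
    cm = _matrix(counts, samples=["s1", "s2", "s3", "s4"])
    oracle = [1.182148257722, 1.184330646759, 0.593596050636, 1.203272754380]
    np.testing.assert_allclose(tmm_factors(cm).factors, oracle, atol=1e-6)


def test_tmm_factor_product_is_one():
    rng = np.random.default_rng(9)
    cm = _matrix(rng.integers(1, 400, size=(150, 5)))
    f = tmm_factors(cm).factors.to_numpy()
    assert np.prod(f) == pytest.approx(1.0, rel=1e-9)


@settings(max_examples=20, deadline=None)
@given(scale=st.integers(min_value=2, max_value=50), seed=st.integers(0, 100))
def test_factor_scale_equivariance(scale, seed):
    """Multiplying one zero-free library by c multiplies its RLE factor by c
    (relative to the others) and leaves every TMM factor at 1 for pure-depth
    pairs."""
    rng = np.random.default_rng(seed)
    a = rng.integers(1, 300, size=40)
    b = rng.integers(1, 300, size=40)
    base = _matrix(np.column_stack([a, b]))
    bumped = _matrix(np.column_stack([a, b * scale]))
    f0 = rle_size_factors(base).factors.to_numpy()
    f1 = rle_size_factors(bumped).factors.to_numpy()
    assert f1[1] / f1[0] == pytest.approx(scale * f0[1] / f0[0], rel=1e-9)
    depth = _matrix(np.column_stack([a, a * scale]))
    np.testing.assert_allclose(tmm_factors(depth).factors, 1.0, atol=1e-9)


# --------------------------------------------------------- application


def test_apply_normalization_conventions(toy_counts):
    unit = rle_size_factors(
        _matrix(np.column_stack([[5, 9, 2, 7]] * 2), samples=["a", "b"])
    )
    assert np.allclose(unit.factors, 1.0)
    # rle with unit factors is the identity on counts
    cm = _matrix(np.column_stack([[5, 9, 2, 7]] * 2), samples=["a", "b"])
    np.testing.assert_array_equal(
        apply_normalization(cm, unit).data.to_numpy(), cm.data.to_numpy()
    )
    # halving one factor doubles that sample's values
    import pandas as pd

    from dirtnorm.normalize import SizeFactors

    halved = SizeFactors(pd.Series([1.0, 0.5], index=["a", "b"]), "rle")
    out = apply_normalization(cm, halved).data
    np.testing.assert_allclose(out["b"], 2.0 * cm.data["b"])


def test_tmm_normalization_of_identical_libraries_is_column_constant():
    a = np.array([30, 50, 200, 9, 120, 77])
    cm = _matrix(np.column_stack([a, a, a]))
    out = apply_normalization(cm, tmm_factors(cm)).data
    np.testing.assert_allclose(out["s0"], out["s1"])
    np.testing.assert_allclose(out["s0"], out["s2"])


def test_apply_normalization_missing_factor_errors(toy_counts):
    import pandas as pd

    from dirtnorm.normalize import SizeFactors

    partial = SizeFactors(pd.Series([1.0], index=["c1"]), "rle")
    with pytest.raises(DataError, match="c2"):
        apply_normalization(toy_counts, partial)
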
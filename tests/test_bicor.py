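"""Biweight midcorrelation: scalar formula, weights, matrix construction,
fallback policies and robustness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from bmkc import (
    BicorOptions,
    DegenerateVectorError,
    ExpressionMatrix,
    bicor,
    bicor_matrix,
    bicor_weights,
    mad,
    median,
)


def reference_bicor(x, y):
    """Independent transcription of the bicor formula, element by element."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    out = []
    for v in (x, y):
        med = np.median(v)
        m = np.median(np.abs(v - med))
        u = (v - med) / (9.0 * m)
        w = np.where(1.0 - np.abs(u) > 0.0, (1.0 - u**2) ** 2, 0.0)
        out.append((v - med) * w)
    xc, yc = out
    return float(np.sum(xc * yc) / (np.sqrt(np.sum(xc**2)) * np.sqrt(np.sum(yc**2))))


finite_vectors = arrays(
    np.float64,
    st.integers(min_value=5, max_value=30),
    elements=st.floats(min_value=-1e3, max_value=1e3, allow_nan=False, width=64),
)


def _nondegenerate(*vs) -> bool:
    try:
        return all(
            mad(v) > 0 and np.sum(((v - np.median(v)) * bicor_weights(v)) ** 2) > 0 for v in vs
        )
    except DegenerateVectorError:
        return False


@pytest.mark.parametrize(
    "v, expected",
    [
        ([1, 2, 3], 2.0),
        ([1, 2, 3, 4], 2.5),
        ([5, 5, 5], 5.0),
    ],
)
def test_median_examples(v, expected):
    assert median(np.array(v, float)) == expected


@pytest.mark.parametrize(
    "v, expected",
    [
        ([1, 2, 3], 1.0),
        ([5, 5, 5], 0.0),
        # sorted |v - med| = [0.5, 0.5, 1.5, 97.5] -> median 1.0
        ([1, 2, 3, 100], 1.0),
    ],
)
def test_mad_is_unscaled_median_of_deviations(v, expected):
    assert mad(np.array(v, float)) == expected


def test_median_and_mad_reject_empty_vectors():
    with pytest.raises(ValueError):
        median(np.array([]))
    with pytest.raises(ValueError):
        mad(np.array([]))


def test_weight_profile_around_median():
    # v = [1, 2, 3, 7]: median 2.5, MAD 1.0; the last element sits exactly
    # 4.5 MAD above the median, i.e. u = 0.5 and weight (1 - 0.25)^2.
    w = bicor_weights(np.array([1.0, 2.0, 3.0, 7.0]))
    assert w[-1] == pytest.approx(0.5625)
    assert np.all((0.0 <= w) & (w <= 1.0))


def test_weight_is_one_at_median_and_zero_beyond_cutoff():
    # median 2, MAD 1; last element sits 10 MAD above the median
    v = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 3.0, 4.0, 12.0])
    assert median(v) == 2.0 and mad(v) == 1.0
    w = bicor_weights(v)
    assert np.all(w[v == 2.0] == 1.0)  # at the median: weight exactly 1
    assert w[-1] == 0.0  # beyond the 9 MAD cutoff: weight exactly 0


def test_weights_raise_on_zero_mad():
    with pytest.raises(DegenerateVectorError):
        bicor_weights(np.array([5.0, 5.0, 5.0, 5.0]))


def test_max_p_outliers_caps_zero_weight_proportion():
    # One gross outlier on the high side among 10 points; with the cap at
    # 10% per side it may stay an outlier, but with mad-breaking leverage
    # spread over several points the rescaling must keep the zero-weight
    # fraction per side at or below the cap.
    v = np.concatenate([np.arange(10.0), [500.0, 600.0, 700.0]])
    capped = BicorOptions(max_p_outliers=0.1)
    w = bicor_weights(v, capped)
    high_side = v > np.median(v)
    frac_zero = np.mean(w[high_side] == 0.0)
    assert frac_zero <= 0.1 + 1.0 / high_side.sum()  # at most one boundary point over
    # capping never affects a vector with no outliers
    clean = np.arange(10.0)
    np.testing.assert_allclose(bicor_weights(clean, capped), bicor_weights(clean))


def test_options_validation():
    with pytest.raises(ValueError):
        BicorOptions(max_p_outliers=0.0)
    with pytest.raises(ValueError):
        BicorOptions(fallback_on_zero_mad="median")


def test_bicor_self_and_negated_self():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
    assert bicor(x, x) == pytest.approx(1.0, abs=1e-12)
    assert bicor(x, -x) == pytest.approx(-1.0, abs=1e-12)


def test_bicor_matches_reference_formula(rng):
    for _ in range(25):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        assert bicor(x, y) == pytest.approx(reference_bicor(x, y), abs=1e-12)


def test_bicor_is_robust_to_a_gross_outlier(rng):
    x = np.arange(1.0, 11.0)
    y = x + rng.normal(0, 0.1, size=10)
    clean = np.corrcoef(x, y)[0, 1]
    y_out = y.copy()
    y_out[-1] = 1000.0
    pearson_out = np.corrcoef(x, y_out)[0, 1]
    bicor_out = bicor(x, y_out)
    assert abs(bicor_out - clean) < abs(pearson_out - clean)


def test_bicor_input_validation():
    with pytest.raises(ValueError):
        bicor(np.arange(5.0), np.arange(6.0))
    with pytest.raises(ValueError):
        bicor(np.array([1.0]), np.array([2.0]))


@pytest.mark.parametrize(
    "policy, expected",
    [("zero", 0.0), ("pearson", pytest.approx(1.0))],
)
def test_zero_mad_fallback_policies(policy, expected):
    # constant x has zero MAD; pearson fallback on a constant is also
    # undefined, so pair the constant with a clean covariate via y
    x = np.array([1.0, 1.0, 1.0, 1.0, 2.0, 1.0, 1.0, 1.0])  # MAD 0, but Pearson defined
    y = x.copy()
    opts = BicorOptions(fallback_on_zero_mad=policy)
    with pytest.warns(UserWarning):
        assert bicor(x, y, opts) == expected


def test_zero_mad_error_policy_raises():
    x = np.array([3.0, 3.0, 3.0, 3.0])
    with pytest.raises(DegenerateVectorError):
        bicor(x, x, BicorOptions(fallback_on_zero_mad="error"))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(x=finite_vectors, data=st.data())
def test_bicor_bounded_and_symmetric(x, data):
    y = data.draw(
        arrays(
            np.float64,
            x.shape[0],
            elements=st.floats(min_value=-1e3, max_value=1e3, allow_nan=False, width=64),
        )
    )
    if not _nondegenerate(x, y):
        return
    r = bicor(x, y)
    assert -1.0 <= r <= 1.0
    assert r == pytest.approx(bicor(y, x), abs=1e-12)
    assert bicor(-x, y) == pytest.approx(-r, abs=1e-9)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    x=finite_vectors,
    a=st.floats(min_value=-50, max_value=50, allow_nan=False),
    b=st.floats(min_value=0.01, max_value=50, allow_nan=False),
    data=st.data(),
)
def test_bicor_invariant_under_positive_affine_transform(x, a, b, data):
    y = data.draw(
        arrays(
            np.float64,
            x.shape[0],
            elements=st.floats(min_value=-1e3, max_value=1e3, allow_nan=False, width=64),
        )
    )
    if not _nondegenerate(x, y, a + b * x):
        return
    assert bicor(a + b * x, y) == pytest.approx(bicor(x, y), rel=1e-6, abs=1e-9)
    np.testing.assert_allclose(bicor_weights(a + b * x), bicor_weights(x), atol=1e-9)


def _expr(values, condition=""):
    n_genes, n_samples = values.shape
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(n_genes)],
        [f"s{j}" for j in range(n_samples)],
        condition,
    )


def test_matrix_equals_pairwise_scalar_bicor(rng):
    x = _expr(rng.normal(size=(5, 30)))
    c = bicor_matrix(x)
    for i in range(5):
        for j in range(5):
            expected = 1.0 if i == j else bicor(x.values[i], x.values[j])
            assert c.values[i, j] == pytest.approx(expected, abs=1e-12)
    np.testing.assert_array_equal(c.values, c.values.T)


def test_matrix_of_collinear_genes_is_all_ones(rng):
    base = rng.normal(size=30)
    x = _expr(np.vstack([base, 2.0 * base + 1.0, 0.5 * base - 3.0]))
    c = bicor_matrix(x)
    np.testing.assert_allclose(c.values, 1.0, atol=1e-9)


def test_matrix_constant_gene_zero_fallback(rng):
    values = rng.normal(size=(4, 20))
    values[2] = 7.0
    with pytest.warns(UserWarning):
        c = bicor_matrix(_expr(values))
    np.testing.assert_array_equal(c.values[2], 0.0)
    np.testing.assert_array_equal(c.values[:, 2], 0.0)
    assert c.values[0, 0] == 1.0


def test_matrix_constant_gene_error_fallback(rng):
    values = rng.normal(size=(3, 10))
    values[0] = 1.0
    with pytest.raises(DegenerateVectorError):
        bicor_matrix(_expr(values), BicorOptions(fallback_on_zero_mad="error"))


def test_expression_matrix_rejects_duplicates_and_nans(rng):
    with pytest.raises(ValueError):
        ExpressionMatrix(rng.normal(size=(2, 3)), ["g", "g"], ["a", "b", "c"])
    bad = rng.normal(size=(2, 3))
    bad[0, 1] = np.nan
    with pytest.raises(ValueError):
        ExpressionMatrix(bad, ["g1", "g2"], ["a", "b", "c"])
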
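import numpy as np
import pandas as pd
import pytest

from dimr.attributes import AttributeMeta, AttributeTable, \
    CategoricalFrequencies
from dimr.errors import ConfigurationError, DataError
from dimr.similarity import (build_matrix, combine, dimrs_pair, gower_pair,
                             null_matrix, randomize_attributes, wilson_pair)

from _oracles import oracle_matrix


def cont_meta(vmin, vmax, sd=1.0):
    return AttributeMeta(name="c", type="continuous", vmin=vmin, vmax=vmax,
                         sd=sd, degenerate=(vmin == vmax))


def cat_meta(counts, zero_level=None):
    n_obs = sum(counts.values())
    return AttributeMeta(name="a", type="categorical",
                         frequencies=CategoricalFrequencies(counts, n_obs),
                         zero_level=zero_level)


class TestPairKernels:
    @pytest.mark.parametrize("a,b,meta,expected", [
        (3.0, 7.0, cont_meta(0, 10), 0.6),       # range-normalised Manhattan
        (4.2, 4.2, cont_meta(0, 10), 1.0),       # zero distance
        ("x", "x", cat_meta({"x": 3, "y": 2}), 1.0),
        ("x", "y", cat_meta({"x": 3, "y": 2}), 0.0),
    ])
    def test_gower_defined_values(self, a, b, meta, expected):
        s, defined = gower_pair(a, b, meta)
        assert defined
        assert s == pytest.approx(expected, abs=1e-12)

    def test_gower_double_zero_excluded_is_undefined(self):
        meta = cat_meta({False: 8, True: 2}, zero_level=False)
        s, defined = gower_pair(False, False, meta, include_double_zero=False)
        assert not defined
        # included, the FALSE/FALSE pair is an ordinary match
        s, defined = gower_pair(False, False, meta, include_double_zero=True)
        assert defined and s == 1.0

    def test_gower_missing_is_undefined(self):
        s, defined = gower_pair(float("nan"), 3.0, cont_meta(0, 10))
        assert (s, defined) == (0.0, False)

    @pytest.mark.parametrize("a,b,meta,n,expected", [
        ("x", "x", cat_meta({"x": 2, "y": 8}), 10, 1.0),
        ("x", "y", cat_meta({"x": 2, "y": 8}), 10, 0.4),  # 1 - |2-8|/10
        (1.0, 5.0, cont_meta(0, 10, sd=2.0), 10, 0.5),    # 1 - 4/(4*2)
    ])
    def test_wilson_values(self, a, b, meta, n, expected):
        s, defined = wilson_pair(a, b, meta, n)
        assert defined
        assert s == pytest.approx(expected, abs=1e-12)

    def test_wilson_missing_scores_zero_but_counts(self):
        s, defined = wilson_pair(float("nan"), 1.0, cont_meta(0, 10), 10)
        assert (s, defined) == (0.0, True)

    def test_wilson_continuous_clipped_at_zero(self):
        s, _ = wilson_pair(0.0, 100.0, cont_meta(0, 100, sd=2.0), 10)
        assert s == 0.0

    def test_wilson_degenerate_sd_raises(self):
        with pytest.raises(DataError):
            wilson_pair(1.0, 1.0, cont_meta(1, 1, sd=0.0), 10)

    @pytest.mark.parametrize("a,b,counts,n,expected", [
        ("x", "x", {"x": 2, "y": 8}, 10, 1 - 2 * 1 / 90),   # rare match
        ("y", "y", {"x": 2, "y": 8}, 10, 1 - 8 * 7 / 90),   # frequent match
        ("x", "y", {"x": 2, "y": 8}, 10, 0.0),              # mismatch
    ])
    def test_dimrs_categorical(self, a, b, counts, n, expected):
        s, defined = dimrs_pair(a, b, cat_meta(counts), n)
        assert defined
        assert s == pytest.approx(expected, abs=1e-12)

    def test_dimrs_rare_match_beats_frequent_match(self):
        meta = cat_meta({"x": 2, "y": 8})
        rare, _ = dimrs_pair("x", "x", meta, 10)
        freq, _ = dimrs_pair("y", "y", meta, 10)
        assert rare > freq

    def test_dimrs_missing_undefined_and_small_n_rejected(self):
        assert dimrs_pair(float("nan"), "x", cat_meta({"x": 1}), 10) \
            == (0.0, False)
        with pytest.raises(DataError):
            dimrs_pair("x", "x", cat_meta({"x": 1}), 1)


class TestCombine:
    @pytest.mark.parametrize("sims,defined,expected", [
        ([1.0, 0.5], [True, True], 0.75),
        ([0.9, 0.4], [True, False], 0.9),
        ([0.3, 0.7], [False, False], 0.0),   # no evidence -> 0
    ])
    def test_weighted_mean_over_defined(self, sims, defined, expected):
        assert combine(sims, defined) == pytest.approx(expected)


class TestBuildMatrix:
    def test_single_category_everywhere_gives_zero_offdiag_dimrs(self):
        # n_A = n makes the frequency-aware similarity exactly 0
        values = pd.DataFrame({"a": ["x"] * 6},
                              index=[f"g{i}" for i in range(6)])
        table = AttributeTable(values, types={"a": "categorical"})
        S = build_matrix(table, "dimrs").S
        off = S[~np.eye(6, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_null_measure_zero_offdiag(self):
        values = pd.DataFrame({"a": ["x", "y", "z"]}, index=list("abc"))
        table = AttributeTable(values, types={"a": "categorical"})
        S = null_matrix(3).S
        assert np.allclose(S, np.eye(3))
        S2 = build_matrix(table, "null").S
        assert np.allclose(S2, np.eye(3))

    def test_identical_continuous_attribute_all_ones(self):
        values = pd.DataFrame({"a": [2.5] * 5},
                              index=[f"g{i}" for i in range(5)])
        table = AttributeTable(values, types={"a": "continuous"})
        S = build_matrix(table, "gower").S
        assert np.allclose(S, 1.0)

    def test_unknown_measure_and_empty_subset_rejected(self):
        values = pd.DataFrame({"a": [1.0, 2.0]}, index=["g0", "g1"])
        table = AttributeTable(values)
        with pytest.raises(ConfigurationError):
            build_matrix(table, "cosine")
        with pytest.raises(ConfigurationError):
            build_matrix(table, "gower", [])

    def test_gower_equals_dimrs_on_continuous_only(self, rng):
        values = pd.DataFrame({"a": rng.normal(size=7),
                               "b": rng.uniform(size=7)},
                              index=[f"g{i}" for i in range(7)])
        table = AttributeTable(values)
        Sg = build_matrix(table, "gower").S
        Sd = build_matrix(table, "dimrs").S
        np.testing.assert_allclose(Sg, Sd, atol=1e-15)


class TestOracleEquivalence:
    @pytest.mark.parametrize("measure", ["gower", "wilson", "dimrs"])
    def test_matches_naive_recomputation(self, measure):
        from conftest import random_mixed_table
        rng = np.random.default_rng(7)
        for _ in range(25):
            table, rows, types, zl = random_mixed_table(rng)
            S = build_matrix(table, measure).S
            S_ref = oracle_matrix(rows, types, measure, zero_levels=zl)
            np.testing.assert_allclose(S, S_ref, atol=1e-12,
                                       err_msg=f"measure={measure}")


class TestRandomize:
    def test_permutation_preserves_marginals(self, rng):
        from conftest import random_mixed_table
        table, *_ = random_mixed_table(rng, n=8, m=3)
        shuffled = randomize_attributes(table, seed=5)
        for col in table.attribute_names:
            a = table.values[col].dropna().value_counts().sort_index()
            b = shuffled.values[col].dropna().value_counts().sort_index()
            pd.testing.assert_series_equal(a, b)
        assert table.missing.sum().tolist() == shuffled.missing.sum().tolist()

    def test_seeds_differ_and_invariants_hold(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame({"a": [f"L{i}" for i in range(12)]},
                              index=[f"g{i}" for i in range(12)])
        table = AttributeTable(values, types={"a": "categorical"})
        r1 = randomize_attributes(table, seed=1)
        r2 = randomize_attributes(table, seed=2)
        assert not r1.values.equals(r2.values)
        S = build_matrix(r1, "dimrs").S
        assert np.allclose(S, S.T)
        assert S.min() >= 0.0 and S.max() <= 1.0


@pytest.mark.parametrize("measure", ["gower", "wilson", "dimrs"])
def test_symmetry_and_bounds_random_tables(measure):
    from conftest import random_mixed_table
    rng = np.random.default_rng(99)
    for _ in range(15):
        table, *_ = random_mixed_table(rng)
        S = build_matrix(table, measure).S
        np.testing.assert_allclose(S, S.T, atol=0)
        assert S.min() >= 0.0 and S.max() <= 1.0 + 1e-15


def test_rare_category_monotonicity_random_tables():
    """Two genes sharing a rarer category are strictly more similar than
    two sharing a more frequent one, per categorical attribute."""
    rng = np.random.default_rng(3)
    for _ in range(15):
        from conftest import random_mixed_table
        table, *_ = random_mixed_table(rng, missing_rate=0.0)
        n = table.n
        for col, t in table.types.items():
            if t != "categorical":
                continue
            freq = table.frequencies(col)
            pairs = sorted(freq.counts.items(), key=lambda kv: kv[1])
            for (ca, na), (cb, nb) in zip(pairs, pairs[1:]):
                if na == nb:
                    continue
                meta = table.meta(col)
                sa, _ = dimrs_pair(ca, ca, meta, n)
                sb, _ = dimrs_pair(cb, cb, meta, n)
                assert sa > sb


# ---------------------------------------------------------------------
# property-based checks
# ---------------------------------------------------------------------

from hypothesis import given, settings, strategies as st  # noqa: E402


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(0.0, 1.0), st.booleans()),
                min_size=1, max_size=8))
def test_combine_is_a_mean_over_defined_attributes(items):
    sims = [s for s, _ in items]
    defined = [d for _, d in items]
    v = combine(sims, defined)
    assert 0.0 <= v <= 1.0
    if not any(defined):
        assert v == 0.0
    else:
        used = [s for s, d in items if d]
        assert min(used) - 1e-12 <= v <= max(used) + 1e-12
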
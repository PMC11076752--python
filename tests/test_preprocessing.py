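"""Preprocessing: token normalization, typing, encoding, pre-imputation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from boostfill.preprocessing import (
    MISSING_TOKEN_ALIASES,
    ColumnTypingError,
    classify_column,
    decode_categorical,
    encode_categorical,
    normalize_missing_tokens,
    pre_impute,
    preprocess,
    zeros_to_missing,
)
from boostfill.pipeline import ImputationConfig


def _isnan(v):
    return isinstance(v, float) and math.isnan(v)


class TestNormalizeMissingTokens:
    @pytest.mark.parametrize("token", sorted(MISSING_TOKEN_ALIASES) + ["", "   ", "  NA  "])
    def test_alias_becomes_missing(self, token):
        df = pd.DataFrame({"c": [token, "1.5"]})
        out = normalize_missing_tokens(df)
        assert _isnan(out["c"].iloc[0])
        assert out["c"].iloc[1] == "1.5"

    @pytest.mark.parametrize("value", ["1.5", "na_", "Na", "text", "0"])
    def test_non_alias_unchanged(self, value):
        df = pd.DataFrame({"c": [value]})
        assert normalize_missing_tokens(df)["c"].iloc[0] == value

    @given(
        st.lists(
            st.one_of(
                st.sampled_from(sorted(MISSING_TOKEN_ALIASES)),
                st.text(alphabet="abc0123456789. ", max_size=8),
            ),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, cells):
        df = pd.DataFrame({"c": cells})
        once = normalize_missing_tokens(df)
        twice = normalize_missing_tokens(once)
        for a, b in zip(once["c"], twice["c"]):
            assert (a == b) or (_isnan(a) and _isnan(b))


class TestZerosToMissing:
    def test_enabled_converts_zero_forms(self):
        df = pd.DataFrame({"c": ["0", 0.0, "0.001", "x"]})
        out = zeros_to_missing(df, enabled=True)
        assert _isnan(out["c"].iloc[0]) and _isnan(out["c"].iloc[1])
        assert out["c"].iloc[2] == "0.001" and out["c"].iloc[3] == "x"

    def test_disabled_is_identity(self):
        df = pd.DataFrame({"c": ["0", "1"]})
        assert zeros_to_missing(df, enabled=False).equals(df)


class TestClassifyColumn:
    @pytest.mark.parametrize(
        "n_text,n_num,expected,coerced",
        [
            (8, 2, "categorical", 2),
            (0, 10, "continuous", 0),
            (6, 4, "excluded", 0),  # exactly 60% text fails the strict rule
            (2, 8, "continuous", 2),
            (7, 3, "categorical", 3),
        ],
    )
    def test_strict_majority_rule(self, n_text, n_num, expected, coerced):
        values = np.array(["t%d" % i for i in range(n_text)] + [str(i) for i in range(n_num)], dtype=object)
        profile, cleaned = classify_column("c", values)
        assert profile.inferred_type == expected
        assert profile.n_coerced == coerced
        if expected == "excluded":
            assert list(cleaned) == list(values)  # untouched

    def test_boolean_tokens_are_categorical(self):
        values = np.array(["True", "False", "True", "False"], dtype=object)
        profile, _ = classify_column("c", values)
        assert profile.inferred_type == "categorical"

    def test_all_missing_is_excluded(self):
        profile, _ = classify_column("c", np.array([np.nan, np.nan], dtype=object))
        assert profile.inferred_type == "excluded"

    def test_fractions_over_nonmissing_cells(self):
        # 7 numeric, 2 text, 11 missing: 7/9 > 0.6 -> continuous
        values = np.array([str(i) for i in range(7)] + ["a", "b"] + [np.nan] * 11, dtype=object)
        profile, _ = classify_column("c", values)
        assert profile.inferred_type == "continuous"

    @given(st.lists(st.sampled_from(["1.0", "tok", np.nan]), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_type_depends_only_on_kind_counts(self, cells):
        """The inferred type is a deterministic function of the kind multiset."""
        values = np.array(cells, dtype=object)
        p1, _ = classify_column("c", values)
        rng = np.random.default_rng(0)
        p2, _ = classify_column("c", rng.permutation(values))
        assert p1.inferred_type == p2.inferred_type


class TestEncodeDecode:
    def test_lexicographic_codes(self):
        col = np.array(["b", "a", "b", np.nan], dtype=object)
        profile, cleaned = classify_column("c", col)
        encoded = encode_categorical(cleaned, profile)
        assert profile.category_map == {"a": 0, "b": 1}
        assert [encoded[0], encoded[1], encoded[2]] == [1.0, 0.0, 1.0]
        assert _isnan(encoded[3])

    def test_round_trip_identity(self):
        col = np.array(["z", "m", "a", "m", np.nan], dtype=object)
        profile, cleaned = classify_column("c", col)
        decoded = decode_categorical(encode_categorical(cleaned, profile), profile)
        for orig, back in zip(cleaned, decoded):
            assert (orig == back) or (_isnan(orig) and _isnan(back))

    def test_single_category(self):
        col = np.array(["x", "x"], dtype=object)
        profile, cleaned = classify_column("c", col)
        assert list(encode_categorical(cleaned, profile)) == [0.0, 0.0]

    def test_unknown_code_errors_with_column_name(self):
        col = np.array(["a", "b"], dtype=object)
        profile, cleaned = classify_column("grp", col)
        encode_categorical(cleaned, profile)
        with pytest.raises(KeyError, match="grp"):
            decode_categorical(np.array([5.0]), profile)


def _profiles_for(encoded: pd.DataFrame, kinds: dict[str, str]):
    from boostfill.preprocessing import ColumnProfile

    profiles = {}
    for col, kind in kinds.items():
        vals = encoded[col].to_numpy(dtype=float)
        profiles[col] = ColumnProfile(col, kind, np.isnan(vals))
    return profiles


class TestPreImpute:
    def test_column_mean_fill(self):
        df = pd.DataFrame({"x": [1.0, 2.0, np.nan, 3.0]})
        out = pre_impute(df, _profiles_for(df, {"x": "continuous"}), "column_mean")
        assert out["x"].iloc[2] == pytest.approx(2.0)

    def test_modal_fill_tie_breaks_to_smallest_code(self):
        df = pd.DataFrame({"g": [0.0, 0.0, 1.0, np.nan], "h": [1.0, 1.0, 0.0, 0.0]})
        kinds = {"g": "categorical", "h": "categorical"}
        out = pre_impute(df, _profiles_for(df, kinds), "column_mean")
        assert out["g"].iloc[3] == 0.0
        df2 = pd.DataFrame({"g": [0.0, 1.0, np.nan]})  # tie between 0 and 1
        out2 = pre_impute(df2, _profiles_for(df2, {"g": "categorical"}), "column_mean")
        assert out2["g"].iloc[2] == 0.0

    def test_knn_matches_brute_force_oracle(self):
        df = pd.DataFrame(
            {
                "a": [0.0, 1.0, 10.0, 11.0],
                "b": [0.5, np.nan, 10.5, 11.5],
            }
        )
        kinds = {"a": "continuous", "b": "continuous"}
        out = pre_impute(df, _profiles_for(df, kinds), "knn", k=2)

        # oracle: exhaustive pairwise distances on the mean-filled scaled matrix
        filled = df.to_numpy(dtype=float).copy()
        filled[1, 1] = np.nanmean(df["b"])
        scaled = (filled - filled.min(0)) / (filled.max(0) - filled.min(0))
        d = [np.inf if i == 1 else np.linalg.norm(scaled[1] - scaled[i]) for i in range(4)]
        donors = [i for i in np.argsort(d) if i != 1 and not np.isnan(df["b"].iloc[i])][:2]
        expected = df["b"].iloc[donors].mean()
        assert out["b"].iloc[1] == pytest.approx(expected)

    def test_mix_type_routes_by_kind(self):
        df = pd.DataFrame(
            {
                "x": [1.0, 2.0, np.nan, 3.0],
                "g": [0.0, 0.0, 1.0, np.nan],
            }
        )
        kinds = {"x": "continuous", "g": "categorical"}
        out = pre_impute(df, _profiles_for(df, kinds), "mix_type", k=2)
        assert out["x"].iloc[2] == pytest.approx(2.0)  # mean path
        assert out["g"].iloc[3] in (0.0, 1.0)  # knn majority path

    def test_observed_cells_never_modified(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.uniform(size=(20, 4)), columns=list("abcd"))
        df[df < 0.2] = np.nan
        kinds = {c: "continuous" for c in df.columns}
        for strategy in ("column_mean", "knn", "mix_type"):
            out = pre_impute(df, _profiles_for(df, kinds), strategy, k=3)
            obs = ~df.isna()
            assert np.array_equal(out.to_numpy()[obs.to_numpy()], df.to_numpy()[obs.to_numpy()])

    def test_empty_column_errors_with_name(self):
        df = pd.DataFrame({"void": [np.nan, np.nan]})
        with pytest.raises(ColumnTypingError, match="void"):
            pre_impute(df, _profiles_for(df, {"void": "continuous"}), "column_mean")


class TestPreprocess:
    def test_three_aligned_tables(self, toy_raw):
        res = preprocess(toy_raw, ImputationConfig())
        assert res.clean.shape == res.encoded.shape == res.pre_imputed.shape == toy_raw.shape
        assert list(res.clean.columns) == list(toy_raw.columns)
        assert list(res.clean.index) == list(toy_raw.index)

    def test_mixed_column_excluded_everywhere(self, toy_raw):
        res = preprocess(toy_raw, ImputationConfig())
        assert res.profiles["mixed"].inferred_type == "excluded"
        for table in (res.clean, res.encoded, res.pre_imputed):
            assert list(table["mixed"]) == list(toy_raw["mixed"])

    def test_typed_columns_complete_after_pre_impute(self, toy_raw):
        res = preprocess(toy_raw, ImputationConfig())
        for col in res.typed_columns:
            assert not res.pre_imputed[col].isna().any()

    def test_no_missing_input_passthrough(self):
        df = pd.DataFrame({"x": ["1", "2", "3"], "g": ["a", "b", "a"]})
        res = preprocess(df, ImputationConfig())
        assert not res.clean.isna().any().any()
        assert np.array_equal(
            res.pre_imputed.to_numpy(dtype=float), res.encoded.to_numpy(dtype=float)
        )

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            preprocess(pd.DataFrame(), ImputationConfig())
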
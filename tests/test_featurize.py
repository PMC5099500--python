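"""Tokenization, n-grams, chi-square selection and tf-idf weighting."""

import math
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from tweetsift.featurize import (FeatureSpace, build_feature_space,
                                 chi_square_scores, extract_ngrams,
                                 select_features, tokenize, vectorize)


class TestTokenize:
    def test_lowercases_and_retains_stop_words(self):
        assert tokenize("Marijuana is GREAT") == ["marijuana", "is", "great"]

    def test_empty_text(self):
        assert tokenize("") == []

    def test_mentions_hashtags_urls(self):
        # mentions anonymized, '#' stripped, URLs removed, apostrophes kept
        toks = tokenize("@GovChristie very ignorant to not see the value of cannabis")
        assert toks == ["@user", "very", "ignorant", "to", "not", "see",
                        "the", "value", "of", "cannabis"]
        assert tokenize("#faded rn https://t.co/abc don't care") == [
            "faded", "rn", "don't", "care"]


class TestNgrams:
    def test_unigrams_plus_adjacent_bigram(self):
        assert extract_ngrams(["smoking", "dabs"]) == Counter(
            {"smoking": 1, "dabs": 1, "smoking dabs": 1}
        )

    def test_single_token_has_no_bigram(self):
        assert extract_ngrams(["cannabis"]) == Counter({"cannabis": 1})

    def test_multiplicities(self):
        grams = extract_ngrams(["a", "b", "a", "b"])
        assert grams == Counter({"a": 2, "b": 2, "a b": 2, "b a": 1})


def brute_force_chi2(docs, labels, feature):
    """Independent oracle: max over classes of the 2x2 contingency chi2."""
    best = 0.0
    for cls in sorted(set(labels)):
        a = sum(1 for d, l in zip(docs, labels) if feature in d and l == cls)
        b = sum(1 for d, l in zip(docs, labels) if feature in d and l != cls)
        c = sum(1 for d, l in zip(docs, labels) if feature not in d and l == cls)
        d_ = sum(1 for d, l in zip(docs, labels) if feature not in d and l != cls)
        table = [[a, b], [c, d_]]
        if min(a + b, c + d_) == 0 or min(a + c, b + d_) == 0:
            continue  # degenerate margin: statistic is 0 by convention
        stat = chi2_contingency(table, correction=False)[0]
        best = max(best, stat)
    return best


class TestChiSquare:
    def test_perfectly_associated_feature_balanced_20(self):
        docs = [{"x"}] * 10 + [set()] * 10
        labels = ["A"] * 10 + ["B"] * 10
        scores = chi_square_scores(docs, labels)
        assert scores["x"] == pytest.approx(20.0, abs=1e-9)

    def test_uninformative_feature_scores_zero(self):
        docs = [{"x"}, {"x"}, {"x"}, {"x"}]
        labels = ["A", "A", "B", "B"]
        assert chi_square_scores(docs, labels)["x"] == pytest.approx(0.0, abs=1e-12)

    def test_associated_feature_outranks_independent(self):
        docs = [{"sig", "noise"}, {"sig"}, {"noise"}, set()]
        labels = ["A", "A", "B", "B"]
        scores = chi_square_scores(docs, labels)
        assert scores["sig"] > scores["noise"]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            chi_square_scores([{"x"}, {"y"}], ["A", "A"])

    def test_invariant_to_label_renaming(self):
        docs = [{"x"}, {"x", "y"}, {"y"}, set(), {"x"}, {"y"}]
        labels = ["A", "A", "B", "B", "C", "C"]
        renamed = {"A": "zz", "B": "qq", "C": "aa"}
        s1 = chi_square_scores(docs, labels)
        s2 = chi_square_scores(docs, [renamed[l] for l in labels])
        assert s1 == s2

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.sets(st.sampled_from("abcdefgh"), max_size=5),
                st.sampled_from(["X", "Y", "Z"]),
            ),
            min_size=4,
            max_size=20,
        )
    )
    def test_matches_contingency_table_oracle(self, data):
        """Vectorized scores equal an independent per-feature 2x2 computation."""
        docs = [d for d, _ in data]
        labels = [l for _, l in data]
        if len(set(labels)) < 2 or not any(docs):
            return
        scores = chi_square_scores(docs, labels)
        for feature in scores:
            assert scores[feature] == pytest.approx(
                brute_force_chi2(docs, labels, feature), abs=1e-9
            )


class TestSelection:
    def test_cap_exactly_k(self):
        scores = {f"f{i:04d}": float(i) for i in range(2000)}
        df = {f: 1 for f in scores}
        space = select_features(scores, 500, df=df, N=10000)
        assert len(space.features) == 500

    def test_fewer_candidates_than_cap(self):
        scores = {f"f{i}": float(i) for i in range(300)}
        space = select_features(scores, 500, df={f: 1 for f in scores}, N=300)
        assert len(space.features) == 300

    def test_boundary_tie_broken_lexicographically(self):
        scores = {"zebra": 5.0, "apple": 5.0, "top": 9.0}
        space = select_features(scores, 2, df={f: 1 for f in scores}, N=10)
        assert space.features == ("top", "apple")

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            select_features({"a": 1.0}, 0, df={"a": 1}, N=1)

    def test_tsv_round_trip(self, tmp_path):
        docs = [Counter(["a", "b"]), Counter(["a"]), Counter(["c"])]
        space = build_feature_space(docs, ["X", "X", "Y"], k=10)
        path = tmp_path / "space.tsv"
        space.to_tsv(path)
        back = FeatureSpace.from_tsv(path)
        assert back.features == space.features
        assert back.df == space.df
        assert back.N == space.N and back.k == space.k


class TestVectorize:
    def _space(self, df, N):
        return FeatureSpace(
            features=tuple(df), df=df, chi2={f: 1.0 for f in df}, N=N, k=len(df)
        )

    def test_printed_formula_natural_log(self):
        space = self._space({"x": 5}, N=10)
        vec = vectorize(Counter({"x": 2}), space)
        assert vec.weights["x"] == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_df_equals_N_gives_zero_weight(self):
        space = self._space({"x": 10}, N=10)
        assert vectorize(Counter({"x": 7}), space).weights == {}

    def test_no_selected_features_gives_empty_vector(self):
        space = self._space({"x": 2}, N=10)
        assert vectorize(Counter({"other": 3}), space).weights == {}

    def test_linear_in_term_frequency(self):
        space = self._space({"x": 3, "y": 4}, N=12)
        v1 = vectorize(Counter({"x": 1, "y": 2}), space)
        v2 = vectorize(Counter({"x": 2, "y": 4}), space)
        for f in v1.weights:
            assert v2.weights[f] == pytest.approx(2 * v1.weights[f], rel=1e-12)

    def test_df_zero_feature_is_invariant_breach(self):
        with pytest.raises(ValueError, match="df"):
            self._space({"x": 0}, N=10)
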
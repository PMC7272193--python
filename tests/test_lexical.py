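"""Lexical decision: OLD, neighbourhoods, features, RT models, comparison."""

import itertools
import string

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lettercode import lexical, synth
from lettercode.lexical import (
    LexicalNorms,
    RTModelSpec,
    crossval_compare,
    fit_rt_model,
    lexical_features,
    nonword_distance,
    old_distance,
    orthographic_neighbors,
    transposition_substitution_summary,
)
from lettercode.letters import LetterCode
from lettercode.strings import SpatialWeights


def lcs_length(s: str, t: str) -> int:
    """Brute-force longest-common-subsequence oracle."""
    L = np.zeros((len(s) + 1, len(t) + 1), dtype=int)
    for i in range(1, len(s) + 1):
        for j in range(1, len(t) + 1):
            L[i, j] = L[i - 1, j - 1] + 1 if s[i - 1] == t[j - 1] \
                else max(L[i - 1, j], L[i, j - 1])
    return int(L[-1, -1])


short_strings = st.text(alphabet=string.ascii_uppercase[:6], min_size=0, max_size=8)


class TestOldDistance:
    @pytest.mark.parametrize("s,t,expected", [
        ("FORGET", "FORGET", 0),
        ("FORGET", "FOGRET", 2),
        ("AB", "", 2),
        ("", "", 0),
        ("A", "B", 2),       # substitution cost 2 == delete + insert
    ])
    def test_known_distances(self, s, t, expected):
        assert old_distance(s, t) == expected

    @given(short_strings, short_strings)
    def test_lcs_identity_at_substitution_cost_two(self, s, t):
        """With substitution cost >= 2 indels, OLD(s,t) = |s|+|t| - 2 LCS(s,t)."""
        assert old_distance(s, t, sub_cost=2) == len(s) + len(t) - 2 * lcs_length(s, t)

    @given(short_strings, short_strings, short_strings)
    def test_metric_axioms(self, s, t, u):
        dst = old_distance(s, t)
        assert dst == old_distance(t, s)
        assert (dst == 0) == (s == t)
        assert old_distance(s, u) <= dst + old_distance(t, u)

    def test_damerau_variant_charges_one_for_adjacent_swap(self):
        assert old_distance("FORGET", "FOGRET", transpositions=True) == 1
        assert old_distance("AB", "BA", transpositions=True) == 1

    def test_negative_costs_rejected(self):
        with pytest.raises(ValueError):
            old_distance("A", "B", sub_cost=-1)


class TestNeighbors:
    def test_enumeration_oracle(self):
        assert orthographic_neighbors("CAT", ["CAT", "BAT", "CAR", "DOG"]) == 2

    def test_no_same_length_words(self):
        assert orthographic_neighbors("CAT", ["MOUSE", "OX"]) == 0

    def test_word_does_not_count_itself(self):
        assert orthographic_neighbors("CAT", ["CAT"]) == 0

    def test_empty_lexicon(self):
        assert orthographic_neighbors("CAT", []) == 0


@pytest.fixture(scope="module")
def norms():
    return LexicalNorms.from_lexicon(["CAT", "CAR", "DOG"], [8.0, 4.0, 2.0])


class TestLexicalFeatures:

    def test_hand_computed_features(self, norms):
        f = lexical_features(["CAT"], norms)
        assert f.loc["CAT", "log_word_freq"] == pytest.approx(np.log(8))
        # bigrams CA (8+4=12) and AT (8)
        assert f.loc["CAT", "mean_log_bigram_freq"] == pytest.approx(
            (np.log(12) + np.log(8)) / 2)
        # letters C (12), A (12), T (8)
        assert f.loc["CAT", "mean_log_letter_freq"] == pytest.approx(
            (np.log(12) + np.log(12) + np.log(8)) / 3)
        assert f.loc["CAT", "n_neighbors"] == 1

    def test_nonword_has_nan_word_freq(self, norms):
        f = lexical_features(["CXT"], norms)
        assert np.isnan(f.loc["CXT", "log_word_freq"])

    def test_single_letter_bigram_missing_not_zero(self, norms):
        f = lexical_features(["C"], norms)
        assert np.isnan(f.loc["C", "mean_log_bigram_freq"])
        assert np.isfinite(f.loc["C", "mean_log_letter_freq"])

    def test_uniform_norms_identical_features(self):
        norms = LexicalNorms.from_lexicon(["AB", "BA"], [1.0, 1.0])
        f = lexical_features(["AB", "BA"], norms)
        assert f.loc["AB", "mean_log_letter_freq"] == f.loc["BA", "mean_log_letter_freq"]

    def test_empty_string_error(self, norms):
        with pytest.raises(ValueError):
            lexical_features([""], norms)

    def test_unseen_tokens_floored(self, norms):
        f = lexical_features(["ZZZ"], norms)
        assert np.isfinite(f.loc["ZZZ", "mean_log_bigram_freq"])


@pytest.fixture(scope="module")
def code6():
    rng = np.random.default_rng(0)
    return LetterCode(letters=tuple("CEILNP"), responses=rng.standard_normal((4, 6)))


class TestNonwordDistance:

    def test_word_itself_zero(self, code6):
        w = {6: SpatialWeights(np.ones((4, 6)))}
        d, nearest = nonword_distance("PENCIL", ["PENCIL"], code6, w)
        assert d == 0.0 and nearest == "PENCIL"

    def test_single_candidate(self, code6):
        w = {6: SpatialWeights(np.random.default_rng(1).uniform(0.5, 1.5, (4, 6)))}
        d, nearest = nonword_distance("PENICL", ["PENCIL"], code6, w)
        assert nearest == "PENCIL" and d > 0

    def test_middle_transposition_nearer_than_edge_under_edge_weights(self, code6):
        """Edge-weighted summation makes PENICL (middle swap) closer to
        PENCIL than EPNCIL (edge swap) — the slower-rejection prediction."""
        w_arr = np.ones((4, 6))
        w_arr[:, 0] = 5.0
        w = {6: SpatialWeights(w_arr)}
        d_mid, _ = nonword_distance("PENICL", ["PENCIL"], code6, w)
        d_edge, _ = nonword_distance("EPNCIL", ["PENCIL"], code6, w)
        assert d_mid < d_edge

    def test_monotone_in_lexicon_growth(self, code6):
        w = {6: SpatialWeights(np.random.default_rng(2).uniform(0.5, 1.5, (4, 6)))}
        lex = ["PENCIL"]
        d1, _ = nonword_distance("LICNEP", lex, code6, w)
        d2, _ = nonword_distance("LICNEP", lex + ["NICELP"], code6, w)
        assert d2 <= d1

    def test_missing_length_errors(self, code6):
        w = {6: SpatialWeights(np.ones((4, 6)))}
        with pytest.raises(ValueError):
            nonword_distance("PEN", ["PENCIL"], code6, w)


class TestFitRTModel:
    def test_word_model_exact_linear_recovery(self):
        """RT = a - b log f recovered exactly from noiseless data."""
        rng = np.random.default_rng(0)
        freqs = rng.uniform(1, 100, 30)
        feats = pd.DataFrame({"log_word_freq": np.log(freqs)},
                             index=[f"W{i}" for i in range(30)])
        rts = pd.Series(0.9 - 0.05 * np.log(freqs), index=feats.index)
        fit = fit_rt_model(feats, rts, RTModelSpec(("log_word_freq",), "rt"))
        assert fit.coef["log_word_freq"] == pytest.approx(-0.05, abs=1e-8)
        assert fit.intercept == pytest.approx(0.9, abs=1e-8)

    def test_nonword_reciprocal_model_recovery(self):
        """RT = 1/(alpha d + beta): regressing 1/RT on d recovers alpha,
        beta exactly and fits with r > 0.99."""
        rng = np.random.default_rng(1)
        d = rng.uniform(0.2, 3.0, 40)
        rts = pd.Series(1.0 / (0.7 * d + 0.4), index=[f"N{i}" for i in range(40)])
        feats = pd.DataFrame({"model_distance": d}, index=rts.index)
        fit = fit_rt_model(feats, rts, RTModelSpec(("model_distance",), "reciprocal_rt"))
        assert fit.coef["model_distance"] == pytest.approx(0.7, abs=1e-8)
        assert fit.intercept == pytest.approx(0.4, abs=1e-8)
        assert fit.r > 0.99

    def test_collinear_predictors_raise(self):
        feats = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]},
                             index=list("wxyz"))
        rts = pd.Series([1.0, 2, 3, 4], index=feats.index)
        with pytest.raises(np.linalg.LinAlgError):
            fit_rt_model(feats, rts, RTModelSpec(("a", "b"), "rt"))

    def test_missing_values_rejected(self):
        feats = pd.DataFrame({"a": [1.0, np.nan]}, index=["w", "x"])
        rts = pd.Series([1.0, 2.0], index=feats.index)
        with pytest.raises(ValueError, match="missing"):
            fit_rt_model(feats, rts, RTModelSpec(("a",), "rt"))


def _lexical_study(noise_sd=0.02, n_subjects=8, seed=0, edge_bias=2.0):
    """Small end-to-end synthetic lexical-decision study."""
    lx = synth.make_lexicon(25, 5, "ABCDEFGHIJ", 1.0, seed=seed)
    code = synth.make_letter_code(6, lx.alphabet, seed=seed + 1)
    w = synth.make_weights(6, 5, seed=seed + 2, edge_bias=edge_bias)
    gt = synth.GroundTruth(code, w, noise_sigma=0.0)
    scheme = {"edge_transposition": {5: 5}, "middle_transposition": {5: 5},
              "edge_substitution": {5: 5}, "middle_substitution": {5: 5}}
    nonwords = synth.make_nonwords(lx, scheme, seed=seed + 3)
    trials = synth.simulate_lexical_trials(
        gt, lx, nonwords, synth.LexicalRTParams(noise_sd=noise_sd),
        n_subjects, seed=seed + 4)
    return lx, code, gt, nonwords, trials


@pytest.fixture(scope="module")
def study():
    # dense lexicon (3-letter words over 5 letters) so orthographic
    # neighbourhood sizes vary across words
    lx = synth.make_lexicon(40, 3, "ABCDE", 1.0, seed=0)
    code = synth.make_letter_code(4, lx.alphabet, seed=1)
    gt = synth.GroundTruth(code, synth.make_weights(4, 3, seed=2),
                           noise_sigma=0.0)
    nonwords = synth.make_nonwords(lx, {"edge_transposition": {3: 4}}, seed=3)
    trials = synth.simulate_lexical_trials(
        gt, lx, nonwords, synth.LexicalRTParams(noise_sd=0.02), 8, seed=4)
    norms_ = LexicalNorms.from_lexicon(lx.words, lx.frequencies)
    word_trials = trials[trials["is_word"] == 1]
    feats = lexical_features(lx.words, norms_)
    assert feats["n_neighbors"].nunique() > 1
    return word_trials, feats


class TestCrossvalCompare:

    def test_identical_specs_calibrated_at_half(self, study):
        """Two copies of the same model spec: exceedance p ~ 0.5."""
        trials, feats = study
        specs = [RTModelSpec(("log_word_freq",), "rt", "m1"),
                 RTModelSpec(("log_word_freq",), "rt", "m2")]
        summary, p = crossval_compare(specs, trials, feats, n_boot=400, seed=0)
        assert 0.4 <= p.loc["m1", "m2"] <= 0.6

    def test_generating_model_beats_mismatched_model(self, study):
        """Word RTs generated from log frequency: the frequency model beats
        the neighbour-count model out of sample."""
        trials, feats = study
        specs = [RTModelSpec(("log_word_freq",), "rt", "freq"),
                 RTModelSpec(("n_neighbors",), "rt", "neigh")]
        summary, p = crossval_compare(specs, trials, feats, n_boot=300, seed=1)
        assert summary.loc["freq", "r_mean"] > summary.loc["neigh", "r_mean"]
        assert p.loc["freq", "neigh"] < 0.05   # freq rarely loses

    def test_deterministic_by_seed(self, study):
        trials, feats = study
        specs = [RTModelSpec(("log_word_freq",), "rt", "a"),
                 RTModelSpec(("n_neighbors",), "rt", "b")]
        s1, p1 = crossval_compare(specs, trials, feats, n_boot=50, seed=9)
        s2, p2 = crossval_compare(specs, trials, feats, n_boot=50, seed=9)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(p1, p2)

    def test_too_few_subjects(self, study):
        trials, feats = study
        few = trials[trials["subject_id"].isin(["s00", "s01"])]
        with pytest.raises(ValueError):
            crossval_compare([RTModelSpec(("log_word_freq",), "rt")], few, feats,
                             n_boot=5, seed=0)


class TestTranspositionSubstitutionSummary:
    def test_zero_change_when_rts_equal(self):
        lx, code, gt, nonwords, trials = _lexical_study(noise_sd=0.0, n_subjects=1)
        flat = trials.copy()
        flat["rt_s"] = 1.0
        summary, _ = transposition_substitution_summary(flat, nonwords)
        assert np.allclose(summary["mean_pct_change"], 0.0)
        assert len(summary) == nonwords["category"].nunique()

    def test_edge_weighted_ground_truth_ordering(self):
        """Under edge-weighted summation, middle manipulations leave nonwords
        closer to their source word, so middle transpositions produce the
        largest RT slow-down; transpositions exceed substitutions."""
        lx, code, gt, nonwords, trials = _lexical_study(noise_sd=0.0, n_subjects=2,
                                                        edge_bias=3.0)
        summary, p = transposition_substitution_summary(trials, nonwords)
        m = summary["mean_pct_change"]
        assert m["middle_transposition"] > m["edge_transposition"]
        assert m["middle_transposition"] > m["middle_substitution"]

    def test_small_category_excluded_with_warning(self):
        lx, code, gt, nonwords, trials = _lexical_study(n_subjects=1)
        one = nonwords.iloc[:1].copy()
        one.loc[:, "category"] = "lonely"
        nw = pd.concat([nonwords.iloc[1:], one], ignore_index=True)
        with pytest.warns(UserWarning, match="lonely"):
            summary, _ = transposition_substitution_summary(trials, nw)
        assert "lonely" not in summary.index


def test_exclude_low_accuracy():
    trials = pd.DataFrame({
        "subject_id": ["s0"] * 10,
        "string": ["GOOD"] * 5 + ["BADD"] * 5,
        "is_word": 0, "rt_s": 1.0,
        "correct": [1] * 5 + [0] * 5,
    })
    kept, removed = lexical.exclude_low_accuracy(trials, threshold=0.2)
    assert removed == ["BADD"]
    assert set(kept["string"]) == {"GOOD"}
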
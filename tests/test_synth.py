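"""Synthetic-study generator: determinism, design counts, noiseless identities."""

import numpy as np
import pandas as pd
import pytest

from lettercode import preprocess, synth
from lettercode._util import all_pairs
from lettercode.strings import SpatialWeights, predict_dissimilarities


class TestMakeLetterCode:
    def test_deterministic_by_seed(self):
        a = synth.make_letter_code(10, "ABCDEFGHIJKLMNOPQRSTUVWXYZ", seed=1)
        b = synth.make_letter_code(10, "ABCDEFGHIJKLMNOPQRSTUVWXYZ", seed=1)
        assert a.responses.shape == (10, 26)
        np.testing.assert_array_equal(a.responses, b.responses)

    def test_seed_sensitivity(self):
        a = synth.make_letter_code(10, "ABCDEFGHIJKLMNOPQRSTUVWXYZ", seed=1)
        c = synth.make_letter_code(10, "ABCDEFGHIJKLMNOPQRSTUVWXYZ", seed=2)
        assert np.any(a.responses != c.responses)

    def test_per_neuron_variance_nonzero(self):
        code = synth.make_letter_code(5, "ABCDEFG", seed=0)
        assert np.all(code.responses.std(axis=1) > 0)

    @pytest.mark.parametrize("n_neurons,alphabet", [(1, "A"), (0, "AB"), (3, "")])
    def test_degenerate_inputs_rejected(self, n_neurons, alphabet):
        with pytest.raises(ValueError):
            synth.make_letter_code(n_neurons, alphabet, seed=1)


class TestSimulateSearchTrials:
    def test_full_letter_design_row_count(self):
        """62 stimuli x all pairs x 2 reps x 1 subject = 3782 trials."""
        import string
        stimuli = list(string.ascii_uppercase + string.ascii_lowercase + string.digits)
        assert len(stimuli) == 62
        code = synth.make_letter_code(5, stimuli, seed=4)
        gt = synth.GroundTruth(code, synth.make_weights(5, 1, 0), noise_sigma=0.0)
        trials = synth.simulate_search_trials(gt, all_pairs(stimuli), 1, 2, seed=0)
        assert len(trials) == 3782

    def test_bigram_design_row_count(self, ground_truth, bigram_pairs):
        """49 bigrams -> 1176 pairs x 2 reps = 2352 trials per subject."""
        trials = synth.simulate_search_trials(ground_truth, bigram_pairs, 1, 2, seed=0)
        assert len(trials) == 2352

    def test_target_balanced_across_reps(self, ground_truth, bigram_pairs):
        trials = synth.simulate_search_trials(ground_truth, bigram_pairs[:10], 2, 4, seed=0)
        per_pair = trials.groupby(["subject_id", "item_a", "item_b"])["target_is_a"].mean()
        assert (per_pair == 0.5).all()

    def test_noiseless_reciprocal_rt_recovers_ground_truth(self, ground_truth, bigram_pairs):
        """With zero noise, 1/mean(RT) is exactly proportional to the
        ground-truth model dissimilarity (single global scale)."""
        trials = synth.simulate_search_trials(ground_truth, bigram_pairs, 2, 2, seed=0)
        dis = preprocess.dissimilarity_from_trials(trials)
        d_true = predict_dissimilarities(
            ground_truth.letter_code, ground_truth.weights,
            list(zip(dis["item_a"], dis["item_b"])))
        ratio = dis["d"].to_numpy() / d_true
        assert np.max(np.abs(ratio / ratio[0] - 1)) < 1e-10

    def test_zero_dissimilarity_pair_rejected(self, letter_code):
        equal_w = synth.GroundTruth(letter_code, SpatialWeights(np.ones((10, 2))),
                                    noise_sigma=0.0)
        with pytest.raises(ValueError, match="zero model dissimilarity"):
            synth.simulate_search_trials(equal_w, [("AD", "DA")], 1, 2, seed=0)

    def test_rts_positive_with_noise(self, letter_code, bigram_weights, bigram_pairs):
        gt = synth.GroundTruth(letter_code, bigram_weights, noise_sigma=0.5)
        trials = synth.simulate_search_trials(gt, bigram_pairs[:50], 2, 2, seed=0)
        assert (trials["rt_s"] > 0).all()


class TestMakeLexicon:
    def test_unique_words_counts(self):
        lx = synth.make_lexicon(32, 5, "ABCDEFGHIJ", 1.0, seed=3)
        assert len(lx.words) == 32 and len(set(lx.words)) == 32
        assert all(len(w) == 5 for w in lx.words)

    def test_zipf_frequencies(self):
        lx = synth.make_lexicon(10, 3, "ABCDE", zipf_exponent=1.0, seed=0)
        np.testing.assert_allclose(lx.frequencies, 1 / np.arange(1, 11))
        flat = synth.make_lexicon(10, 3, "ABCDE", zipf_exponent=0.0, seed=0)
        assert np.all(flat.frequencies == flat.frequencies[0])

    def test_exhaustive_two_word_case(self):
        """Requesting every possible string must yield exactly that set."""
        for seed in range(5):
            lx = synth.make_lexicon(2, 1, "AB", 1.0, seed=seed)
            assert sorted(lx.words) == ["A", "B"]

    def test_alphabet_too_small(self):
        with pytest.raises(ValueError):
            synth.make_lexicon(10, 1, "AB", 1.0, seed=0)


class TestMakeNonwords:
    def test_table_scheme_counts(self, pooled_lexicon):
        """The standard category plan on a 100/150/200 pool gives 450
        nonwords with per-category totals 50,50,50,50,100,50,50,50."""
        nw = synth.make_nonwords(pooled_lexicon, synth.STANDARD_NONWORD_SCHEME, seed=5)
        assert len(nw) == 450
        counts = nw.groupby("category").size()
        expected = {cat: sum(v.values()) for cat, v in synth.STANDARD_NONWORD_SCHEME.items()}
        assert counts.to_dict() == expected
        by_len = nw.groupby("length").size().to_dict()
        assert by_len == {4: 100, 5: 150, 6: 200}

    def test_edge_transposition_enumeration(self):
        lx = synth.SyntheticLexicon(words=["PENCIL"], frequencies=[1.0],
                                    alphabet=list("PENCIL"))
        seen = set()
        for seed in range(12):
            nw = synth.make_nonwords(lx, {"edge_transposition": {6: 1}}, seed=seed)
            seen.add(nw["nonword"].iloc[0])
        assert seen <= {"EPNCIL", "PENCLI"}
        assert len(seen) == 2   # both allowed outputs occur over seeds

    def test_categories_differ_as_prescribed(self, pooled_lexicon):
        nw = synth.make_nonwords(pooled_lexicon, synth.STANDARD_NONWORD_SCHEME, seed=7)
        words = set(pooled_lexicon.words)
        for row in nw.itertuples(index=False):
            assert row.nonword not in words
            assert row.nonword != row.source
            if row.category in synth.TRANSPOSITION_CATEGORIES:
                assert sorted(row.nonword) == sorted(row.source)
            if row.category in {"edge_substitution", "middle_substitution"}:
                diffs = [i for i, (a, b) in enumerate(zip(row.nonword, row.source))
                         if a != b]
                assert 1 <= len(diffs) <= 2
                assert max(diffs) - min(diffs) <= 1   # adjacent positions
                if row.category == "middle_substitution":
                    assert 0 not in diffs and len(row.source) - 1 not in diffs

    def test_two_step_impossible_for_four_letter_words(self, pooled_lexicon):
        with pytest.raises(ValueError, match="impossible"):
            synth.make_nonwords(pooled_lexicon,
                                {"two_step_middle_transposition": {4: 5}}, seed=0)

    def test_deterministic_by_seed(self, pooled_lexicon):
        a = synth.make_nonwords(pooled_lexicon, synth.STANDARD_NONWORD_SCHEME, seed=9)
        b = synth.make_nonwords(pooled_lexicon, synth.STANDARD_NONWORD_SCHEME, seed=9)
        pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def lexical_setup(small_lexicon):
    code = synth.make_letter_code(6, small_lexicon.alphabet, seed=1)
    gt = synth.GroundTruth(code, synth.make_weights(6, 5, 2), noise_sigma=0.0)
    nw = synth.make_nonwords(small_lexicon,
                             {"edge_transposition": {5: 3},
                              "middle_substitution": {5: 3}}, seed=3)
    return gt, small_lexicon, nw


class TestSimulateLexicalTrials:
    def test_word_rt_monotone_in_frequency(self, lexical_setup):
        gt, lx, nw = lexical_setup
        trials = synth.simulate_lexical_trials(
            gt, lx, nw, synth.LexicalRTParams(noise_sd=0.0), 1, seed=0)
        words = trials[trials["is_word"] == 1].set_index("string")["rt_s"]
        freqs = {w: lx.freq(w) for w in words.index}
        ordered = sorted(words.index, key=lambda w: -freqs[w])
        rts = [words[w] for w in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(rts, rts[1:]))

    def test_nonword_rt_monotone_in_distance(self, lexical_setup):
        gt, lx, nw = lexical_setup
        trials = synth.simulate_lexical_trials(
            gt, lx, nw, synth.LexicalRTParams(noise_sd=0.0), 1, seed=0)
        nws = trials[trials["is_word"] == 0].set_index("string")["rt_s"]
        dist = {n: synth.nearest_word_distance(gt, n, lx)[0] for n in nws.index}
        ordered = sorted(nws.index, key=lambda n: dist[n])
        rts = [nws[n] for n in ordered]
        assert all(a >= b - 1e-12 for a, b in zip(rts, rts[1:]))

    def test_deterministic_by_seed(self, lexical_setup):
        gt, lx, nw = lexical_setup
        p = synth.LexicalRTParams(noise_sd=0.05)
        a = synth.simulate_lexical_trials(gt, lx, nw, p, 4, seed=11)
        b = synth.simulate_lexical_trials(gt, lx, nw, p, 4, seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestVoxelPatternsAndEmbeddings:
    def test_pattern_shape_and_noiseless_identity(self):
        means = np.arange(74 * 5, dtype=float).reshape(74, 5)
        pat = synth.simulate_voxel_patterns(means, 8, 0.0, seed=0)
        assert pat.data.shape == (8, 74, 5)
        for run in pat.data:
            np.testing.assert_array_equal(run, means)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_voxel_patterns(np.ones((3, 4)), 1, 0.1, seed=0)

    def test_embedding_cluster_structure(self):
        from lettercode.rsa import semantic_dissimilarity
        words = [f"W{i}" for i in range(8)]
        one = synth.make_embeddings(words, 6, 1, seed=0, noise_sd=0.0)
        for a in words[1:]:
            assert semantic_dissimilarity(one, words[0], a) == pytest.approx(0, abs=1e-12)
        two = synth.make_embeddings(words, 6, 2, seed=0, noise_sd=0.0)
        # round-robin assignment: even indices cluster 0, odd cluster 1
        assert semantic_dissimilarity(two, words[0], words[1]) == pytest.approx(1, abs=1e-12)
        assert semantic_dissimilarity(two, words[0], words[2]) == pytest.approx(0, abs=1e-12)

    def test_embedding_errors(self):
        with pytest.raises(ValueError):
            synth.make_embeddings(["A", "B"], 4, 3, seed=0)
        with pytest.raises(ValueError):
            synth.make_embeddings(["A"], 1, 1, seed=0)
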
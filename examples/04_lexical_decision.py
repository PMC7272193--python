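"""Model lexical-decision times for words and nonwords.

Word RTs fall with log word frequency; nonword RTs are inversely related
to the string's letter-model distance to its nearest word.  Models with
different parameter counts are compared by subject-split cross-validation,
and transposition/substitution nonword categories are summarised as
percent RT change relative to their source words.
"""

import numpy as np

from lettercode import lexical, synth

lx = synth.make_lexicon(50, 5, "ABCDEFGHIJ", zipf_exponent=1.0, seed=31)
code = synth.make_letter_code(10, lx.alphabet, seed=11)
weights = synth.make_weights(10, 5, seed=12, edge_bias=2.0)   # edge letters dominate
gt = synth.GroundTruth(code, weights, noise_sigma=0.0)

scheme = {c: {5: 10} for c in ("edge_transposition", "middle_transposition",
                               "edge_substitution", "middle_substitution")}
nonwords = synth.make_nonwords(lx, scheme, seed=32)
trials = synth.simulate_lexical_trials(gt, lx, nonwords,
                                       synth.LexicalRTParams(noise_sd=0.03),
                                       n_subjects=8, seed=41)
print(f"{len(lx.words)} words, {len(nonwords)} nonwords, "
      f"{trials['subject_id'].nunique()} subjects, {len(trials)} trials")

norms = lexical.LexicalNorms.from_lexicon(lx.words, lx.frequencies)
feats = lexical.lexical_features(list(trials['string'].unique()), norms)

# letter-model and edit distances for the nonwords
wbl = {5: weights}
for nw in nonwords["nonword"]:
    feats.loc[nw, "model_distance"] = lexical.nonword_distance(
        nw, lx.words, code, wbl)[0]
    feats.loc[nw, "old_distance"] = min(lexical.old_distance(nw, w_) for w_ in lx.words)

nw_trials = trials[trials["is_word"] == 0]
specs = [lexical.RTModelSpec(("model_distance",), "reciprocal_rt", "letter_model"),
         lexical.RTModelSpec(("old_distance",), "reciprocal_rt", "OLD")]
summary, p = lexical.crossval_compare(specs, nw_trials, feats, n_boot=500, seed=5)
print("\ncross-validated nonword RT models (mean +/- sd of r over 500 splits):")
for name, row in summary.iterrows():
    print(f"  {name:>12}: r = {row['r_mean']:.3f} +/- {row['r_sd']:.3f}")
print(f"p(letter_model < OLD) = {p.loc['letter_model', 'OLD']:.3f} "
      "(fraction of splits where the letter model lost)")

cat, _ = lexical.transposition_substitution_summary(trials, nonwords)
print("\npercent RT change, nonword vs. source word, by category:")
print(cat[["mean_pct_change", "sem_pct_change", "n"]].round(2).to_string())
# middle transpositions stay closest to the source word in the edge-weighted
# code, so they take longest to reject (largest percent change)
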
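"""Build artificial letter-tuned neurons from oddball-search times.

Simulates single-letter searches, converts RTs to 1/RT dissimilarities
with outlier filtering, and embeds the letters with classical MDS: each
embedding dimension is one model neuron's letter tuning.
"""

import numpy as np

from lettercode import letters, preprocess, synth
from lettercode._util import all_pairs

ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

code_true = synth.make_letter_code(10, ALPHABET, seed=11)
gt = synth.GroundTruth(code_true, synth.make_weights(10, 1, 0), noise_sigma=0.1)
trials = synth.simulate_search_trials(gt, all_pairs(list(ALPHABET)),
                                      n_subjects=6, n_reps=2, seed=21)
print(f"simulated {len(trials)} search trials "
      f"({len(all_pairs(list(ALPHABET)))} letter pairs x 2 reps x 6 subjects)")

filtered, report = preprocess.filter_outliers(trials, k=3)
print(f"outlier filtering removed {report['removed_fraction']:.1%} of correct trials")

dis = preprocess.dissimilarity_from_trials(filtered)
stats = preprocess.split_half_consistency(filtered, n_splits=50, seed=1)
print(f"split-half reliability r_sh = {stats.r_sh:.3f} +/- {stats.r_sh_sd:.3f}; "
      f"Spearman-Brown full-data bound r_data = {stats.r_data:.3f}")
# r_data is the ceiling any model fit to these dissimilarities can reach

code = letters.embed_mds(dis, n_dims=10)
curve = letters.variance_explained_curve(dis, max_dims=15)
r10 = curve.loc[curve["dims"] == 10, "r"].iloc[0]
print(f"10-D embedding: distance correlation with data r = {r10:.3f} "
      f"(cumulative eigenvalue share "
      f"{curve.loc[curve['dims'] == 10, 'cum_eigenvalue_share'].iloc[0]:.3f})")

tuning = letters.neuron_tuning(code, 0)
print(f"neuron 0 prefers {tuning.preferred!r} "
      f"(response {tuning.responses[tuning.preferred]:+.3f}) and responds least to "
      f"{tuning.anti_preferred!r} ({tuning.responses[tuning.anti_preferred]:+.3f})")
# the sign/orientation of each axis is arbitrary: only distances are meaningful
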
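"""The linear part-sum alternative to the nonlinear string model.

String-pair dissimilarity is modelled as a weighted sum of single-letter
dissimilarities across location pairs, so the coefficients come from
ordinary least squares; a reduced variant ties coefficients by location
separation |i-j|.
"""

import itertools

import numpy as np

from lettercode import partsum, synth
from lettercode._util import all_pairs, dissim_table
from lettercode.strings import predict_dissimilarities

LETTERS = "ADHIMNT"

code = synth.make_letter_code(10, LETTERS, seed=11)
w = synth.make_weights(10, 2, seed=12)
bigrams = ["".join(p) for p in itertools.product(LETTERS, repeat=2)]
pairs = all_pairs(bigrams)
observed = predict_dissimilarities(code, w, pairs)   # letter-model dissimilarities

letter_pairs = all_pairs(list(LETTERS))
letter_d = dissim_table(letter_pairs,
                        np.array([predict_dissimilarities(
                            code, synth.make_weights(10, 1, 0), [(a, b)])[0]
                            for a, b in letter_pairs]))

X, cols = partsum.build_design(letter_d, pairs)
print(f"design: {X.shape[0]} bigram pairs x {X.shape[1]} location-pair coefficients")

full = partsum.fit_part_sum(X, observed)
red = partsum.reduce_model(full.model, X, observed)
print(f"full model ({full.model.n_free_params} params): r = {full.r:.3f}")
print(f"reduced, tied by |i-j| ({red.model.n_free_params} params): r = {red.r:.3f}")
print("coefficients (i, j) -> weight:")
for (i, j), c in sorted(full.model.coeffs.items()):
    print(f"  ({i}, {j}): {c:+.3f}")
# corresponding-location terms (0,0), (1,1) dominate: most of a string pair's
# dissimilarity comes from letters compared at the same position
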
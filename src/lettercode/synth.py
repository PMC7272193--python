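"""Synthetic study generator.

Produces every input the pipeline consumes, with the statistical structure
the analyses assume, so the whole pipeline is testable without any
download:

- oddball-search trial tables whose reciprocal RT is linear in a
  ground-truth compositional-model dissimilarity, with multiplicative
  lognormal trial noise (RTs are positive and right-skewed);
- Zipf-distributed lexica and a nonword generator implementing the
  standard transposition/substitution category plan (edge/middle/two-step/
  random transpositions, edge/middle/random substitutions), one nonword
  per source word;
- lexical-decision trials where word RT falls with log word frequency and
  nonword RT is inversely related to the distance from the nonword to its
  nearest word in the ground-truth string model;
- multi-run voxel patterns (condition means + i.i.d. Gaussian noise) for
  the crossnobis stage, and cluster-structured word embeddings for the
  semantic stage.

Every generator is a pure function of its inputs and seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from lettercode.letters import LetterCode
from lettercode.strings import SpatialWeights, model_dissimilarity, predict_dissimilarities

SEARCH_COLUMNS = ["subject_id", "item_a", "item_b", "target_is_a", "rt_s", "correct", "block"]
LEXICAL_COLUMNS = ["subject_id", "string", "is_word", "rt_s", "correct"]


@dataclass
class GroundTruth:
    """The simulated observer: a letter code, summation weights, and an RT law.

    RT for a search pair = rt_scale / d(pair) x lognormal(0, noise_sigma),
    i.e. 1/RT = d / rt_scale + baseline (baseline 0 by default), so the
    reciprocal of mean search time recovers the model dissimilarity up to
    a global scale.
    """

    letter_code: LetterCode
    weights: SpatialWeights
    rt_scale: float = 1.0
    noise_sigma: float = 0.1
    baseline: float = 0.0   # optional additive offset t0 in 1/RT = d/rt_scale + t0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rt_scale <= 0:
            raise ValueError("rt_scale must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if np.any(np.all(self.letter_code.responses == 0, axis=1)):
            raise ValueError("letter code has an all-zero neuron row")

    def dissimilarity(self, s: str, t: str, metric: str = "euclidean") -> float:
        return model_dissimilarity(self.letter_code, self.weights, s, t, metric)


def make_letter_code(n_neurons: int, alphabet: Sequence[str], seed: int) -> LetterCode:
    """Random letter code: uniform [0,1] responses, mean-centred per neuron.

    Any distribution with per-neuron variance across letters would do;
    centring keeps responses balanced around zero like MDS coordinates.
    """
    alphabet = list(alphabet)
    if len(alphabet) == 0:
        raise ValueError("alphabet must be non-empty")
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if len(alphabet) < 2:
        raise ValueError("alphabet needs >= 2 letters for nonzero per-neuron variance")
    rng = np.random.default_rng(seed)
    resp = rng.uniform(0.0, 1.0, size=(n_neurons, len(alphabet)))
    resp -= resp.mean(axis=1, keepdims=True)
    # zero-variance rows have probability zero but would break downstream
    if np.any(resp.std(axis=1) == 0):
        raise RuntimeError("degenerate draw: a neuron has zero variance across letters")
    return LetterCode(letters=tuple(alphabet), responses=resp)


def make_weights(n_neurons: int, string_length: int, seed: int,
                 edge_bias: float = 0.0) -> SpatialWeights:
    """Random positive summation weights, optionally favouring edge positions.

    ``edge_bias`` applies an exponential U-shaped profile across positions,
    exp(edge_bias * |p - centre| / centre): outer letters are weighted
    multiplicatively more, and — because the profile is convex — the
    weight *difference* between adjacent positions is concentrated at the
    edges.  That convexity is what makes edge manipulations of a string
    change the model response more than middle manipulations (the
    first/last-letter advantage in reading).
    """
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.5, 1.5, size=(n_neurons, string_length))
    if edge_bias != 0.0 and string_length > 1:
        pos = np.arange(string_length)
        centre = (string_length - 1) / 2
        profile = np.exp(edge_bias * np.abs(pos - centre) / centre)
        w = w * profile
    return SpatialWeights(w=w, fit_meta={"seed": seed, "edge_bias": edge_bias})


def simulate_search_trials(gt: GroundTruth, pairs: Sequence[tuple[str, str]],
                           n_subjects: int, n_reps: int, seed: int,
                           metric: str = "euclidean") -> pd.DataFrame:
    """Simulate oddball-search trials for the given stimulus pairs.

    Each pair appears ``n_reps`` times per subject, the target being
    either member equally often (alternating across reps).  RT =
    rt_scale / d x exp(noise_sigma * z); a pair with zero ground-truth
    dissimilarity has infinite search time and is rejected.
    """
    if n_subjects < 1 or n_reps < 1:
        raise ValueError("n_subjects and n_reps must be >= 1")
    pairs = [tuple(p) for p in pairs]
    length = len(pairs[0][0])
    d = predict_dissimilarities(gt.letter_code, gt.weights, pairs, metric)
    zero = [pairs[i] for i in np.nonzero(d == 0)[0]]
    if zero:
        raise ValueError(f"pair(s) with zero model dissimilarity (infinite RT): {zero[:10]}")
    inv_rt_clean = d / gt.rt_scale + gt.baseline
    rt_clean = 1.0 / inv_rt_clean
    rng = np.random.default_rng(seed)
    rows = []
    for subj in range(n_subjects):
        for i, (a, b) in enumerate(pairs):
            for rep in range(n_reps):
                target_is_a = (rep + i) % 2 == 0 if n_reps % 2 else rep % 2 == 0
                noise = np.exp(gt.noise_sigma * rng.standard_normal()) if gt.noise_sigma else 1.0
                rows.append((f"s{subj:02d}", a, b, int(target_is_a),
                             rt_clean[i] * noise, 1, rep))
    return pd.DataFrame(rows, columns=SEARCH_COLUMNS)


# ---------------------------------------------------------------------------
# lexicon + nonwords


@dataclass
class SyntheticLexicon:
    words: list[str]
    frequencies: np.ndarray
    alphabet: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(set(self.words)) != len(self.words):
            raise ValueError("lexicon words must be unique")
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be strictly positive")
        if not self.alphabet:
            self.alphabet = sorted({c for w in self.words for c in w})
        bad = {c for w in self.words for c in w} - set(self.alphabet)
        if bad:
            raise ValueError(f"word characters {sorted(bad)} not in alphabet")

    def freq(self, word: str) -> float:
        return float(self.frequencies[self.words.index(word)])

    def words_of_length(self, n: int) -> list[str]:
        return [w for w in self.words if len(w) == n]


def make_lexicon(n_words: int, length: int, alphabet: Sequence[str],
                 zipf_exponent: float = 1.0, seed: int = 0) -> SyntheticLexicon:
    """Random unique words with Zipf-like frequencies, freq ~ rank^(-exponent)."""
    alphabet = list(alphabet)
    if len(alphabet) ** length < n_words:
        raise ValueError(
            f"alphabet of {len(alphabet)} cannot form {n_words} unique length-{length} strings")
    rng = np.random.default_rng(seed)
    words: list[str] = []
    seen = set()
    # rejection-sample unique strings; switch to exhaustive enumeration when dense
    if n_words > 0.5 * len(alphabet) ** length:
        universe = ["".join(p) for p in itertools.product(alphabet, repeat=length)]
        idx = rng.choice(len(universe), size=n_words, replace=False)
        words = [universe[i] for i in idx]
    else:
        while len(words) < n_words:
            w = "".join(rng.choice(alphabet, size=length))
            if w not in seen:
                seen.add(w)
                words.append(w)
    ranks = np.arange(1, n_words + 1, dtype=float)
    freqs = ranks ** (-zipf_exponent)
    return SyntheticLexicon(words=words, frequencies=freqs, alphabet=alphabet)


def merge_lexica(lexica: Sequence[SyntheticLexicon]) -> SyntheticLexicon:
    """Pool words of several lexica (e.g. one per word length)."""
    words = [w for lx in lexica for w in lx.words]
    freqs = np.concatenate([lx.frequencies for lx in lexica])
    alphabet = sorted(set().union(*(lx.alphabet for lx in lexica)))
    return SyntheticLexicon(words=words, frequencies=freqs, alphabet=alphabet)


# the standard category plan for nonword construction: per category, the
# number of nonwords to build from 4-, 5- and 6-letter source words
STANDARD_NONWORD_SCHEME: dict[str, dict[int, int]] = {
    "edge_transposition": {4: 15, 5: 15, 6: 20},
    "middle_transposition": {4: 15, 5: 15, 6: 20},
    "two_step_edge_transposition": {4: 0, 5: 20, 6: 30},
    "two_step_middle_transposition": {4: 0, 5: 20, 6: 30},
    "random_transposition": {4: 25, 5: 35, 6: 40},
    "edge_substitution": {4: 15, 5: 15, 6: 20},
    "middle_substitution": {4: 15, 5: 15, 6: 20},
    "random_substitution": {4: 15, 5: 15, 6: 20},
}

TRANSPOSITION_CATEGORIES = {
    "edge_transposition", "middle_transposition",
    "two_step_edge_transposition", "two_step_middle_transposition",
    "random_transposition",
}
SUBSTITUTION_CATEGORIES = {"edge_substitution", "middle_substitution", "random_substitution"}


def _swap(word: str, i: int, j: int) -> str:
    chars = list(word)
    chars[i], chars[j] = chars[j], chars[i]
    return "".join(chars)


def _swap_positions(category: str, length: int) -> list[tuple[int, int]]:
    """Allowed swap index pairs for the structured transposition categories."""
    if category == "edge_transposition":
        return [(0, 1), (length - 2, length - 1)]
    if category == "middle_transposition":
        if length < 4:
            raise ValueError("middle transposition needs length >= 4")
        return [(i, i + 1) for i in range(1, length - 2)]
    if category == "two_step_edge_transposition":
        if length < 5:
            raise ValueError(
                "two-step edge transposition needs length >= 5 (count must be 0 for 4-letter words)")
        return [(0, 2), (length - 3, length - 1)]
    if category == "two_step_middle_transposition":
        if length < 5:
            raise ValueError(
                "two-step middle transposition needs length >= 5 (count must be 0 for 4-letter words)")
        return [(i, i + 2) for i in range(1, length - 3)] or [(1, 3)]
    raise ValueError(f"no structured swaps for category {category!r}")


def _candidates(word: str, category: str, alphabet: Sequence[str],
                rng: np.random.Generator) -> list[str]:
    """Candidate nonwords for a word under a category (pre lexicon-exclusion)."""
    L = len(word)
    if category in {"edge_transposition", "middle_transposition",
                    "two_step_edge_transposition", "two_step_middle_transposition"}:
        return sorted({_swap(word, i, j) for i, j in _swap_positions(category, L)
                       if _swap(word, i, j) != word})
    if category == "random_transposition":
        perms = {"".join(p) for p in itertools.permutations(word)} - {word}
        return sorted(perms)
    others = [c for c in alphabet]
    if category == "edge_substitution":
        position_sets = [(0, 1), (L - 2, L - 1)]
    elif category == "middle_substitution":
        if L < 4:
            raise ValueError("middle substitution needs length >= 4")
        position_sets = [(i, i + 1) for i in range(1, L - 2)]
    elif category == "random_substitution":
        # permute, then substitute two random positions
        out = []
        for _ in range(20):
            perm = "".join(rng.permutation(list(word)))
            pos = rng.choice(L, size=2, replace=False)
            chars = list(perm)
            for p in pos:
                repl = [c for c in others if c != chars[p]]
                chars[p] = repl[rng.integers(len(repl))]
            cand = "".join(chars)
            if cand != word:
                out.append(cand)
        return out
    else:
        raise ValueError(f"unknown nonword category {category!r}")
    out = []
    for pos in position_sets:
        for _ in range(10):   # a few random letter draws per position set
            chars = list(word)
            for p in pos:
                repl = [c for c in others if c != chars[p]]
                chars[p] = repl[rng.integers(len(repl))]
            out.append("".join(chars))
    return out


def make_nonwords(lexicon: SyntheticLexicon,
                  scheme: Mapping[str, Mapping[int, int]] = STANDARD_NONWORD_SCHEME,
                  seed: int = 0) -> pd.DataFrame:
    """Build nonwords from lexicon words following a category plan.

    ``scheme`` maps category -> {word length: count}.  Each nonword is
    built from a distinct source word of the required length, differs from
    it exactly as the category prescribes, and is guaranteed not to be a
    word itself.  Returns a DataFrame (nonword, source, category, length).
    """
    rng = np.random.default_rng(seed)
    word_set = set(lexicon.words)
    by_len: dict[int, list[str]] = {}
    for w in lexicon.words:
        by_len.setdefault(len(w), []).append(w)
    # validate impossible category/length requests up front
    for cat, counts in scheme.items():
        for L, cnt in counts.items():
            if cnt > 0 and cat in {"two_step_edge_transposition",
                                   "two_step_middle_transposition"} and L < 5:
                raise ValueError(
                    f"category {cat!r} impossible for {L}-letter words (count must be 0)")
            if cnt > len(by_len.get(L, [])):
                raise ValueError(
                    f"scheme wants {cnt} nonwords of length {L} for {cat!r} but only "
                    f"{len(by_len.get(L, []))} words of that length remain in the pool")
    available = {L: list(rng.permutation(ws)) for L, ws in by_len.items()}
    rows = []
    used_nonwords: set[str] = set()
    for cat in scheme:
        for L, cnt in sorted(scheme[cat].items()):
            made = 0
            attempts = 0
            while made < cnt:
                if not available.get(L):
                    raise ValueError(f"ran out of length-{L} source words for {cat!r}")
                word = available[L].pop()
                cands = [c for c in _candidates(word, cat, lexicon.alphabet, rng)
                         if c not in word_set and c not in used_nonwords]
                if not cands:
                    attempts += 1
                    if attempts > 5 * cnt + 50:
                        raise ValueError(
                            f"cannot satisfy {cat!r} at length {L}: too many words "
                            "without valid manipulations")
                    available[L].insert(0, word)   # recycle word to the back
                    continue
                nw = cands[rng.integers(len(cands))]
                used_nonwords.add(nw)
                rows.append((nw, word, cat, L))
                made += 1
    return pd.DataFrame(rows, columns=["nonword", "source", "category", "length"])


# ---------------------------------------------------------------------------
# lexical-decision trials


@dataclass
class LexicalRTParams:
    """Generative RT law for lexical decision.

    word RT = word_intercept - word_slope * log(frequency) + N(0, noise_sd)
    nonword RT = scale / (alpha * d_nearest + beta) + N(0, noise_sd)

    RTs are truncated at ``min_rt`` to stay positive.
    """

    word_intercept: float = 0.9
    word_slope: float = 0.05
    alpha: float = 1.0
    beta: float = 0.5
    scale: float = 1.0
    noise_sd: float = 0.05
    min_rt: float = 0.05

    def __post_init__(self) -> None:
        for name in ("word_intercept", "word_slope", "alpha", "beta", "scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def nearest_word_distance(gt: GroundTruth, nonword: str, lexicon: SyntheticLexicon,
                          weights_by_length: Mapping[int, SpatialWeights] | None = None,
                          metric: str = "euclidean") -> tuple[float, str]:
    """Ground-truth distance from a nonword to its nearest same-length word."""
    candidates = sorted(lexicon.words_of_length(len(nonword)))
    if not candidates:
        raise ValueError(f"no length-{len(nonword)} words in lexicon for {nonword!r}")
    weights = (weights_by_length or {}).get(len(nonword), gt.weights)
    best_d, best_w = np.inf, None
    for w in candidates:
        d = model_dissimilarity(gt.letter_code, weights, nonword, w, metric)
        if d < best_d:
            best_d, best_w = d, w
    return float(best_d), best_w


def simulate_lexical_trials(gt: GroundTruth, lexicon: SyntheticLexicon,
                            nonwords: pd.DataFrame, rt_params: LexicalRTParams,
                            n_subjects: int, seed: int,
                            weights_by_length: Mapping[int, SpatialWeights] | None = None,
                            ) -> pd.DataFrame:
    """Simulate lexical-decision trials: one trial per string per subject.

    Word RTs fall with log frequency; nonword RTs are inversely related to
    the ground-truth distance from the nonword to its nearest word.
    """
    rng = np.random.default_rng(seed)
    word_rt = {w: rt_params.word_intercept - rt_params.word_slope * np.log(lexicon.freq(w))
               for w in lexicon.words}
    if min(word_rt.values()) <= 0:
        raise ValueError("word RT law yields nonpositive clean RT; adjust intercept/slope")
    nonword_rt = {}
    for nw in nonwords["nonword"]:
        d, _ = nearest_word_distance(gt, nw, lexicon, weights_by_length)
        if d == 0:
            raise ValueError(f"nonword {nw!r} has zero distance to a lexicon word")
        nonword_rt[nw] = rt_params.scale / (rt_params.alpha * d + rt_params.beta)
    rows = []
    for subj in range(n_subjects):
        for w, rt in word_rt.items():
            noise = rt_params.noise_sd * rng.standard_normal() if rt_params.noise_sd else 0.0
            rows.append((f"s{subj:02d}", w, 1, max(rt + noise, rt_params.min_rt), 1))
        for nw, rt in nonword_rt.items():
            noise = rt_params.noise_sd * rng.standard_normal() if rt_params.noise_sd else 0.0
            rows.append((f"s{subj:02d}", nw, 0, max(rt + noise, rt_params.min_rt), 1))
    return pd.DataFrame(rows, columns=LEXICAL_COLUMNS)


# ---------------------------------------------------------------------------
# voxel patterns + embeddings


def simulate_voxel_patterns(condition_means: np.ndarray, n_runs: int,
                            noise_sd: float, seed: int,
                            condition_labels: Sequence[str] | None = None):
    """Multi-run voxel patterns: pattern[run, cond, voxel] = mean + noise."""
    from lettercode.rsa import PatternArray

    means = np.asarray(condition_means, dtype=float)
    if means.ndim != 2:
        raise ValueError("condition_means must be conditions x voxels")
    if n_runs < 2:
        raise ValueError("need n_runs >= 2 (cross-validated distances need >= 2 runs)")
    rng = np.random.default_rng(seed)
    data = means[None, :, :] + noise_sd * rng.standard_normal((n_runs, *means.shape))
    if condition_labels is None:
        condition_labels = [f"cond_{i}" for i in range(means.shape[0])]
    return PatternArray(data=data, condition_labels=list(condition_labels),
                        run_labels=[f"run_{r}" for r in range(n_runs)])


def make_embeddings(words: Sequence[str], n_dims: int, n_clusters: int, seed: int,
                    noise_sd: float = 0.1) -> pd.DataFrame:
    """Cluster-structured word embeddings (rows = words).

    Cluster centres are orthonormal, so with zero noise the cosine
    dissimilarity is 0 within a cluster and 1 across clusters; noise
    interpolates between these extremes.
    """
    words = list(words)
    if n_dims < 2:
        raise ValueError("n_dims must be >= 2")
    if n_clusters > len(words):
        raise ValueError("more clusters than words")
    if n_clusters > n_dims:
        raise ValueError("orthonormal centres need n_clusters <= n_dims")
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n_dims, n_clusters)))
    centres = q.T  # n_clusters x n_dims, orthonormal rows
    assignment = np.arange(len(words)) % n_clusters
    vecs = centres[assignment] + noise_sd * rng.standard_normal((len(words), n_dims))
    return pd.DataFrame(vecs, index=words)
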
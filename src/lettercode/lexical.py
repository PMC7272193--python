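"""Lexical-decision modelling.

Lexical decision (speeded word/nonword classification of a letter string)
is modelled as evidence accumulation against stored words: word RT falls
with log word frequency (stronger stored representation), and nonword RT
is inversely proportional to the string's distance to its *nearest* word
— a nonword similar to a word (PENICL vs PENCIL) takes longer to reject
than a dissimilar one (EPNCIL).

Three families of predictors are implemented:

- the compositional letter model's distance to the nearest word
  (``nonword_distance``), optionally with per-length summation weights
  re-fit to reciprocal RTs;
- the Orthographic Levenshtein Distance (OLD): weighted edit distance
  with insertions/deletions at cost 1 and substitutions at cost 2 (at
  that cost a substitution is never cheaper than delete+insert, giving
  the identity OLD(s,t) = |s| + |t| - 2 LCS(s,t));
- lexical factors: log word frequency, mean log bigram/letter frequency,
  and Coltheart's N (same-length neighbours differing in one position).

Models with different parameter counts are compared by subject-split
cross-validation: train on the mean RTs of a random half of subjects,
evaluate the correlation on the held-out half, repeated ``n_boot`` times;
exceedance p for a model pair is the fraction of splits in which the
observed ordering is violated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from lettercode._util import pearson
from lettercode.letters import LetterCode
from lettercode.strings import Metric, SpatialWeights, model_dissimilarity

WORD_PREDICTORS = ("log_word_freq", "n_neighbors", "mean_log_bigram_freq",
                   "mean_log_letter_freq")


def old_distance(s: str, t: str, sub_cost: float = 2.0, indel_cost: float = 1.0,
                 transpositions: bool = False) -> float:
    """Orthographic Levenshtein Distance with configurable costs.

    Dynamic-programming edit distance: insertions and deletions cost
    ``indel_cost``, substitutions ``sub_cost`` (default 2, at which the
    distance equals |s| + |t| - 2 LCS(s, t)).  ``transpositions=True``
    enables the Damerau variant where swapping two adjacent letters costs
    one indel (off by default).
    """
    if sub_cost < 0 or indel_cost < 0:
        raise ValueError("edit costs must be nonnegative")
    m, n = len(s), len(t)
    prev2 = None
    prev = np.arange(n + 1, dtype=float) * indel_cost
    for i in range(1, m + 1):
        cur = np.empty(n + 1)
        cur[0] = i * indel_cost
        for j in range(1, n + 1):
            cost = 0.0 if s[i - 1] == t[j - 1] else sub_cost
            cur[j] = min(prev[j] + indel_cost, cur[j - 1] + indel_cost, prev[j - 1] + cost)
            if (transpositions and i > 1 and j > 1
                    and s[i - 1] == t[j - 2] and s[i - 2] == t[j - 1]):
                cur[j] = min(cur[j], prev2[j - 2] + indel_cost)
        prev2, prev = prev, cur
    return float(prev[n])


def orthographic_neighbors(word: str, lexicon: Sequence[str]) -> int:
    """Coltheart's N: same-length lexicon words differing in exactly one
    position (substitution-only), the word itself excluded."""
    count = 0
    for w in lexicon:
        if w == word or len(w) != len(word):
            continue
        if sum(a != b for a, b in zip(word, w)) == 1:
            count += 1
    return count


@dataclass
class LexicalNorms:
    """Frequency norms over a lexicon: word, bigram and letter counts."""

    word_freq: dict[str, float]
    bigram_freq: dict[str, float]
    letter_freq: dict[str, float]
    lexicon: list[str]

    def __post_init__(self) -> None:
        if len(set(self.lexicon)) != len(self.lexicon):
            raise ValueError("lexicon must be unique")

    @classmethod
    def from_lexicon(cls, words: Sequence[str], frequencies: Sequence[float]) -> "LexicalNorms":
        """Derive bigram/letter norms from word frequencies by token counting."""
        word_freq = dict(zip(words, map(float, frequencies)))
        bigram: dict[str, float] = {}
        letter: dict[str, float] = {}
        for w, f in word_freq.items():
            for a, b in zip(w, w[1:]):
                bigram[a + b] = bigram.get(a + b, 0.0) + f
            for c in w:
                letter[c] = letter.get(c, 0.0) + f
        return cls(word_freq=word_freq, bigram_freq=bigram, letter_freq=letter,
                   lexicon=list(words))


def _floored_log(values: list[float], all_positive: Sequence[float],
                 base: float | None) -> float:
    """Mean log with zero/missing frequencies floored at half the minimum
    observed positive frequency."""
    positive = [v for v in all_positive if v > 0]
    floor = 0.5 * min(positive) if positive else 1.0
    logs = [np.log(max(v, floor)) for v in values]
    out = float(np.mean(logs))
    return out / np.log(base) if base else out


def lexical_features(strings: Sequence[str], norms: LexicalNorms,
                     log_base: float | None = None) -> pd.DataFrame:
    """Per-string lexical feature table.

    Columns: ``log_word_freq`` (NaN for strings not in the lexicon),
    ``mean_log_bigram_freq``, ``mean_log_letter_freq``, ``n_neighbors``.
    Single-letter strings have no bigrams: their bigram feature is NaN
    (missing), never silently zero.  Logs are natural by default.
    """
    rows = []
    for s in strings:
        if len(s) == 0:
            raise ValueError("empty string has no lexical features")
        wf = norms.word_freq.get(s)
        log_wf = np.nan
        if wf is not None and wf > 0:
            log_wf = np.log(wf) / (np.log(log_base) if log_base else 1.0)
        if len(s) >= 2:
            bg = [norms.bigram_freq.get(s[i:i + 2], 0.0) for i in range(len(s) - 1)]
            mlb = _floored_log(bg, list(norms.bigram_freq.values()), log_base)
        else:
            mlb = np.nan
        lt = [norms.letter_freq.get(c, 0.0) for c in s]
        mll = _floored_log(lt, list(norms.letter_freq.values()), log_base)
        rows.append({"string": s, "log_word_freq": log_wf,
                     "mean_log_bigram_freq": mlb, "mean_log_letter_freq": mll,
                     "n_neighbors": orthographic_neighbors(s, norms.lexicon)})
    return pd.DataFrame(rows).set_index("string")


def nonword_distance(nonword: str, lexicon: Sequence[str], code: LetterCode,
                     weights_by_length: Mapping[int, SpatialWeights],
                     metric: Metric = "euclidean") -> tuple[float, str]:
    """Letter-model distance from a string to its nearest same-length word.

    Ties broken by lexicographic word order.  The same-length restriction
    is inherent to the string model (equal-length weighted sums); OLD has
    no such restriction and serves for cross-length comparisons.
    """
    candidates = sorted(w for w in lexicon if len(w) == len(nonword))
    if not candidates:
        raise ValueError(f"no word of length {len(nonword)} in lexicon")
    if len(nonword) not in weights_by_length:
        raise ValueError(f"no summation weights for length {len(nonword)}")
    weights = weights_by_length[len(nonword)]
    best_d, best_w = np.inf, None
    for w in candidates:
        d = model_dissimilarity(code, weights, nonword, w, metric)
        if d < best_d:   # strict <: first (lexicographically smallest) wins ties
            best_d, best_w = d, w
    return float(best_d), best_w


@dataclass
class RTModelSpec:
    """A named linear RT model: predictors + target scale.

    ``target="rt"`` regresses RT on the predictors; ``"reciprocal_rt"``
    regresses 1/RT (the convention for distance-based nonword models,
    where 1/RT is proportional to dissimilarity).
    """

    predictors: tuple[str, ...]
    target: Literal["rt", "reciprocal_rt"] = "rt"
    name: str = ""

    def __post_init__(self) -> None:
        self.predictors = tuple(self.predictors)
        if len(self.predictors) < 1:
            raise ValueError("a model spec needs at least one predictor")
        if not self.name:
            self.name = "+".join(self.predictors)


@dataclass
class RTFit:
    coef: pd.Series
    intercept: float
    r: float
    target: str
    condition_number: float
    residuals: np.ndarray = field(repr=False, default=None)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return X[list(self.coef.index)].to_numpy() @ self.coef.to_numpy() + self.intercept


def fit_rt_model(features: pd.DataFrame, rts: pd.Series, spec: RTModelSpec) -> RTFit:
    """Ordinary least squares of the target on the spec's predictors.

    ``features`` is indexed by string and must contain every predictor
    column with no missing values for the fitted strings.
    """
    missing = [p for p in spec.predictors if p not in features.columns]
    if missing:
        raise ValueError(f"features table lacks predictors {missing}")
    X = features.loc[rts.index, list(spec.predictors)]
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing predictor values in {bad}; apply a feature policy first")
    y = rts.to_numpy(dtype=float)
    if spec.target == "reciprocal_rt":
        y = 1.0 / y
    A = np.column_stack([X.to_numpy(dtype=float), np.ones(len(y))])
    cond = float(np.linalg.cond(A))
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular design (condition number {cond:.3g}); predictors collinear")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    pred = A @ beta
    r = pearson(pred, y)
    return RTFit(coef=pd.Series(beta[:-1], index=list(spec.predictors)),
                 intercept=float(beta[-1]), r=0.0 if np.isnan(r) else r,
                 target=spec.target, condition_number=cond, residuals=pred - y)


def mean_rts_by_string(trials: pd.DataFrame, subjects: Sequence[str]) -> pd.Series:
    t = trials[trials["subject_id"].isin(subjects) & trials["correct"].astype(bool)]
    return t.groupby("string")["rt_s"].mean()


def crossval_compare(models: Sequence[RTModelSpec], trials: pd.DataFrame,
                     features: pd.DataFrame, n_boot: int = 1000, seed: int = 0,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-validated bootstrap model comparison on lexical-decision RTs.

    Per split: a random half of the subjects forms the training set; each
    model is fit to the per-string mean RT of the training half and its
    predictions are correlated with the per-string mean RT of the test
    half.  Returns (per-model mean +/- sd of r over splits, pairwise
    exceedance matrix p[a, b] = fraction of splits with r_a < r_b).
    """
    subjects = np.array(sorted(trials["subject_id"].unique()))
    if len(subjects) < 4:
        raise ValueError("cross-validated comparison needs >= 4 subjects")
    rng = np.random.default_rng(seed)
    names = [m.name for m in models]
    rs = np.full((n_boot, len(models)), np.nan)
    failures = np.zeros(len(models), dtype=int)
    for b in range(n_boot):
        perm = rng.permutation(subjects)
        train, test = perm[: len(subjects) // 2], perm[len(subjects) // 2:]
        y_train = mean_rts_by_string(trials, train)
        y_test = mean_rts_by_string(trials, test)
        shared = y_train.index.intersection(y_test.index).intersection(features.index)
        for mi, spec in enumerate(models):
            try:
                fit = fit_rt_model(features, y_train.loc[shared], spec)
                pred = fit.predict(features.loc[shared])
                target = y_test.loc[shared].to_numpy(dtype=float)
                if spec.target == "reciprocal_rt":
                    target = 1.0 / target
                rs[b, mi] = pearson(pred, target)
            except (ValueError, np.linalg.LinAlgError):
                failures[mi] += 1
    for mi, spec in enumerate(models):
        if failures[mi] > 0.1 * n_boot:
            raise RuntimeError(
                f"model {spec.name!r} failed to fit on {failures[mi]}/{n_boot} splits")
    summary = pd.DataFrame({
        "model": names,
        "r_mean": np.nanmean(rs, axis=0),
        "r_sd": np.nanstd(rs, axis=0),
        "n_splits": n_boot,
    }).set_index("model")
    p = np.full((len(models), len(models)), np.nan)
    for a in range(len(models)):
        for b_ in range(len(models)):
            if a != b_:
                valid = ~np.isnan(rs[:, a]) & ~np.isnan(rs[:, b_])
                # ties (identical models) count half, keeping p calibrated at 0.5
                p[a, b_] = float(np.mean(rs[valid, a] < rs[valid, b_])
                                 + 0.5 * np.mean(rs[valid, a] == rs[valid, b_]))
    return summary, pd.DataFrame(p, index=names, columns=names)


def transposition_substitution_summary(trials: pd.DataFrame, nonwords: pd.DataFrame,
                                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent RT change from source word to nonword, by manipulation category.

    For each nonword linked to its source word: 100 x (RT_nonword -
    RT_word) / RT_word, using per-string mean correct RTs.  Returns a
    per-category summary (mean, sem, n) and a pairwise rank-sum p-value
    matrix.  Categories with fewer than 2 items are excluded with a
    warning.
    """
    t = trials[trials["correct"].astype(bool)]
    mean_rt = t.groupby("string")["rt_s"].mean()
    pct: dict[str, list[float]] = {}
    for nw, src, cat in nonwords[["nonword", "source", "category"]].itertuples(index=False):
        if nw in mean_rt.index and src in mean_rt.index:
            pct.setdefault(cat, []).append(
                100.0 * (mean_rt[nw] - mean_rt[src]) / mean_rt[src])
    for cat in list(pct):
        if len(pct[cat]) < 2:
            warnings.warn(f"category {cat!r} has <2 items; excluded", stacklevel=2)
            del pct[cat]
    cats = sorted(pct)
    summary = pd.DataFrame({
        "category": cats,
        "mean_pct_change": [float(np.mean(pct[c])) for c in cats],
        "sem_pct_change": [float(np.std(pct[c], ddof=1) / np.sqrt(len(pct[c]))) for c in cats],
        "n": [len(pct[c]) for c in cats],
    }).set_index("category")
    p = pd.DataFrame(np.nan, index=cats, columns=cats)
    for a in cats:
        for b in cats:
            if a != b:
                p.loc[a, b] = float(ranksums(pct[a], pct[b]).pvalue)
    return summary, p


def exclude_low_accuracy(trials: pd.DataFrame, threshold: float = 0.2) -> tuple[pd.DataFrame, list[str]]:
    """Drop strings whose across-subject accuracy falls below ``threshold``
    (default 20%), the usual screen for uninterpretable nonwords."""
    acc = trials.groupby("string")["correct"].mean()
    bad = acc.index[acc < threshold].tolist()
    return trials[~trials["string"].isin(bad)], bad
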
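"""The compositional string model.

A neuron tuned to single letters responds to a string by a weighted sum of
its letter responses: for a bigram, r_AB = w1*r_A + w2*r_B, where w1, w2
are per-neuron spatial summation weights.  String-string dissimilarity is
computed from the per-neuron response vectors, either as the Euclidean
norm across neurons (default) or as the mean absolute per-neuron
difference.  Positional asymmetry of the weights (w1 != w2) is what makes
transposed strings like AB and BA discriminable at all.

Weight fitting minimises the squared error between observed and predicted
dissimilarities with multi-start nonlinear least squares.  Two exact
symmetries matter for interpreting fits: scaling all weights by c > 0
scales every dissimilarity by c, and flipping the sign of one neuron's
whole weight row leaves every dissimilarity unchanged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from lettercode._util import canonicalize_pairs, pearson
from lettercode.letters import LetterCode

Metric = Literal["euclidean", "mean_abs"]


@dataclass
class SpatialWeights:
    """Per-neuron, per-position summation weights (neurons x positions)."""

    w: np.ndarray
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.atleast_2d(np.asarray(self.w, dtype=float))
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite")

    @property
    def n_neurons(self) -> int:
        return self.w.shape[0]

    @property
    def string_length(self) -> int:
        return self.w.shape[1]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.w,
                     index=[f"neuron_{k}" for k in range(self.n_neurons)],
                     columns=[f"pos_{p}" for p in range(self.string_length)]).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SpatialWeights":
        return cls(w=pd.read_csv(path, index_col=0).to_numpy())


@dataclass
class ModelFit:
    r: float
    residuals: np.ndarray
    params: SpatialWeights
    loss: float
    predicted: np.ndarray

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValueError("correlation out of range")


def _letter_matrix(code: LetterCode, s: str) -> np.ndarray:
    """neurons x positions matrix of letter responses for string s."""
    cols = [code.letter_index(c) for c in s]
    return code.responses[:, cols]


def string_response(code: LetterCode, weights: SpatialWeights, s: str) -> np.ndarray:
    """Per-neuron response to a string: response[k] = sum_p w[k,p] r_k(s[p])."""
    if len(s) != weights.string_length:
        raise ValueError(
            f"string {s!r} has length {len(s)} but weights cover length {weights.string_length}")
    if weights.n_neurons != code.n_dims:
        raise ValueError("weights and code disagree on neuron count")
    return np.einsum("kp,kp->k", weights.w, _letter_matrix(code, s))


def model_dissimilarity(code: LetterCode, weights: SpatialWeights, s1: str, s2: str,
                        metric: Metric = "euclidean") -> float:
    """Dissimilarity between two equal-length strings under the letter model.

    ``euclidean``: norm of the difference of the response vectors across
    neurons.  ``mean_abs``: mean over neurons of |r_k(s1) - r_k(s2)|.
    Symmetric, zero for identical strings (and for any pair whose response
    vectors coincide, e.g. transposed strings under equal weights).
    """
    diff = string_response(code, weights, s1) - string_response(code, weights, s2)
    if metric == "euclidean":
        return float(np.linalg.norm(diff))
    if metric == "mean_abs":
        return float(np.mean(np.abs(diff)))
    raise ValueError(f"unknown metric {metric!r}")


def pair_deltas(code: LetterCode, pairs: Sequence[tuple[str, str]],
                string_length: int) -> np.ndarray:
    """Stack of per-pair letter-response differences, pairs x neurons x positions.

    delta[i, k, p] = r_k(s_i[p]) - r_k(t_i[p]) for pair i = (s_i, t_i).
    The model's per-neuron response difference is then the weighted sum
    over positions, which makes prediction a single einsum.
    """
    out = np.empty((len(pairs), code.n_dims, string_length))
    for i, (s, t) in enumerate(pairs):
        if len(s) != string_length or len(t) != string_length:
            raise ValueError(f"pair {(s, t)} not of length {string_length}")
        out[i] = _letter_matrix(code, s) - _letter_matrix(code, t)
    return out


def predict_dissimilarities(code: LetterCode, weights: SpatialWeights,
                            pairs: Sequence[tuple[str, str]],
                            metric: Metric = "euclidean",
                            deltas: np.ndarray | None = None) -> np.ndarray:
    """Vectorised model dissimilarities for many pairs."""
    if deltas is None:
        deltas = pair_deltas(code, pairs, weights.string_length)
    per_neuron = np.einsum("ikp,kp->ik", deltas, weights.w)
    if metric == "euclidean":
        return np.linalg.norm(per_neuron, axis=1)
    if metric == "mean_abs":
        return np.mean(np.abs(per_neuron), axis=1)
    raise ValueError(f"unknown metric {metric!r}")


def fit_weights(code: LetterCode, observed: pd.DataFrame, metric: Metric = "euclidean",
                n_restarts: int = 10, seed: int = 0,
                max_nfev: int | None = None) -> ModelFit:
    """Fit spatial summation weights to observed string dissimilarities.

    Least squares on the dissimilarities directly (not their reciprocal or
    log), best of ``n_restarts`` random initialisations.  Free-parameter
    count is neurons x string length (20 for bigrams with 10 neurons).

    Parameters
    ----------
    observed
        Pair table (item_a, item_b, d) over equal-length strings.

    Returns a :class:`ModelFit` with the Pearson correlation between
    predicted and observed dissimilarities, per-pair residuals
    (predicted - observed), and the fitted :class:`SpatialWeights`.
    """
    observed = canonicalize_pairs(observed)
    if not np.all(np.isfinite(observed["d"])):
        raise ValueError("observed dissimilarities contain non-finite values")
    pairs = list(zip(observed["item_a"], observed["item_b"]))
    lengths = {len(s) for p in pairs for s in p}
    if len(lengths) != 1:
        raise ValueError(f"strings of mixed lengths {sorted(lengths)}; fit one length at a time")
    length = lengths.pop()
    n_params = code.n_dims * length
    if len(pairs) < n_params:
        raise ValueError(
            f"{len(pairs)} pairs cannot identify {n_params} free parameters")
    y = observed["d"].to_numpy(dtype=float)
    deltas = pair_deltas(code, pairs, length)
    rng = np.random.default_rng(seed)

    def residual(flat_w: np.ndarray) -> np.ndarray:
        w = flat_w.reshape(code.n_dims, length)
        per_neuron = np.einsum("ikp,kp->ik", deltas, w)
        if metric == "euclidean":
            pred = np.linalg.norm(per_neuron, axis=1)
        else:
            pred = np.mean(np.abs(per_neuron), axis=1)
        return pred - y

    best = None
    for _ in range(max(1, n_restarts)):
        x0 = rng.standard_normal(n_params)
        sol = least_squares(residual, x0, method="lm" if metric == "euclidean" else "trf",
                            max_nfev=max_nfev)
        if best is None or sol.cost < best.cost:
            best = sol
    w = SpatialWeights(best.x.reshape(code.n_dims, length),
                       fit_meta={"loss": float(best.cost), "n_restarts": n_restarts,
                                 "seed": seed, "metric": metric, "n_params": n_params,
                                 "n_pairs": len(pairs)})
    pred = predict_dissimilarities(code, w, pairs, metric, deltas=deltas)
    return ModelFit(r=pearson(pred, y), residuals=pred - y, params=w,
                    loss=float(best.cost), predicted=pred)


def modulation_index(weights: SpatialWeights) -> tuple[np.ndarray, float]:
    """Positional asymmetry of bigram summation, per neuron and mean.

    MI_k = |w1 - w2| / |w1 + w2|, in [0, 1] for same-sign weights:
    0 for symmetric summation (transposition-blind), 1 for
    winner-take-all on one position.
    """
    if weights.string_length != 2:
        raise ValueError("modulation index is defined for bigram (length-2) weights")
    w1, w2 = weights.w[:, 0], weights.w[:, 1]
    denom = np.abs(w1 + w2)
    if np.any(denom == 0):
        bad = np.nonzero(denom == 0)[0].tolist()
        raise ValueError(f"w1 + w2 = 0 for neuron(s) {bad}; modulation index undefined")
    mi = np.abs(w1 - w2) / denom
    return mi, float(mi.mean())


def rank_jumbles(code: LetterCode, weights: SpatialWeights, word: str,
                 candidates: Sequence[str] | Literal["all"] = "all",
                 metric: Metric = "euclidean") -> pd.DataFrame:
    """Sort jumbled versions of a word by model distance to the word.

    Ascending distance = ascending predicted reading difficulty.  With
    ``candidates="all"``, all distinct permutations of the word's letters
    are ranked; the identity permutation ranks first with d = 0.  Ties are
    broken lexicographically for determinism.
    """
    if candidates == "all":
        cands = sorted({"".join(p) for p in itertools.permutations(word)})
    else:
        cands = list(candidates)
        for c in cands:
            if len(c) != len(word):
                raise ValueError(f"candidate {c!r} does not match word length {len(word)}")
    d = [model_dissimilarity(code, weights, word, c, metric) for c in cands]
    out = pd.DataFrame({"candidate": cands, "d": d})
    out = out.sort_values(["d", "candidate"], kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
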
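"""Part-sum model: string dissimilarity as a linear sum of letter dissimilarities.

The dissimilarity between two equal-length strings s and t is modelled as

    d(s, t) = sum_{i,j} c_ij * d_letters(s[i], t[j])  (+ intercept)

over all location pairs (i, j), where d_letters comes from single-letter
searches.  Because the model is linear in the unknown coefficients c_ij
it is estimable by ordinary least squares, unlike the nonlinear
compositional string model — and under certain conditions (single-neuron,
mean-absolute metric) the two coincide.

A reduced variant ties coefficients into classes by location separation
|i - j| (corresponding locations vs. one-apart vs. ...), shrinking the
free-parameter count of the full L^2-coefficient model to L classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from lettercode._util import dissim_to_square, pearson


@dataclass
class PartSumModel:
    """Location-pair coefficients c_(i,j) (0-indexed), plus optional intercept."""

    coeffs: dict[tuple[int, int], float]
    length: int
    intercept: float = 0.0
    reduced: bool = False
    tying: str | None = None
    n_free_params: int = 0

    def __post_init__(self) -> None:
        expected = {(i, j) for i in range(self.length) for j in range(self.length)}
        if set(self.coeffs) != expected:
            raise ValueError("coefficient map must cover all location pairs (i, j)")
        if self.n_free_params == 0:
            self.n_free_params = len(self.coeffs) + (1 if self.intercept else 0)

    def coef_vector(self) -> np.ndarray:
        return np.array([self.coeffs[(i, j)]
                         for i in range(self.length) for j in range(self.length)])

    def predict(self, design: np.ndarray) -> np.ndarray:
        return design @ self.coef_vector() + self.intercept

    def to_csv(self, path) -> None:
        rows = [{"i": i, "j": j, "coeff": c} for (i, j), c in sorted(self.coeffs.items())]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class PartSumFit:
    model: PartSumModel
    r: float
    residuals: np.ndarray = field(repr=False, default=None)
    rss: float = 0.0


def build_design(letter_D: pd.DataFrame,
                 string_pairs: Sequence[tuple[str, str]]) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Design matrix for the part-sum regression.

    Row per string pair, column per location pair (i, j); entry =
    d_letters(s[i], t[j]) with d(x, x) = 0.  Returns the matrix and the
    column labels.  Raises if a required letter pair is missing.
    """
    sq = letter_D if (letter_D.shape[0] == letter_D.shape[1]
                      and (letter_D.columns == letter_D.index).all()) else dissim_to_square(letter_D)
    lengths = {len(x) for p in string_pairs for x in p}
    if len(lengths) != 1:
        raise ValueError(f"mixed string lengths {sorted(lengths)}")
    L = lengths.pop()
    cols = [(i, j) for i in range(L) for j in range(L)]
    X = np.zeros((len(string_pairs), len(cols)))
    letters = set(sq.index)
    for row, (s, t) in enumerate(string_pairs):
        for k, (i, j) in enumerate(cols):
            a, b = s[i], t[j]
            if a == b:
                continue
            if a not in letters or b not in letters:
                raise ValueError(f"letter pair ({a!r}, {b!r}) missing from letter dissimilarities")
            X[row, k] = sq.loc[a, b]
    return X, cols


def _ols(X: np.ndarray, y: np.ndarray, intercept: bool) -> tuple[np.ndarray, float, np.ndarray]:
    A = np.column_stack([X, np.ones(len(y))]) if intercept else X
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        _, _, vt = np.linalg.svd(A)
        null = vt[rank:]
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {A.shape[1]} columns); "
            f"null-space basis:\n{np.round(null, 4)}")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    if intercept:
        return beta[:-1], float(beta[-1]), A @ beta
    return beta, 0.0, A @ beta


def fit_part_sum(design: np.ndarray, observed_d: np.ndarray,
                 length: int | None = None, intercept: bool = True,
                 ) -> PartSumFit:
    """Ordinary least squares fit of the part-sum coefficients.

    If there are fewer string pairs than coefficients, automatically falls
    back to the separation-tied reduced model with a warning.
    """
    y = np.asarray(observed_d, dtype=float)
    X = np.asarray(design, dtype=float)
    if length is None:
        length = int(round(np.sqrt(X.shape[1])))
    if length * length != X.shape[1]:
        raise ValueError("design columns must be a full L x L location-pair grid")
    n_cols = X.shape[1] + (1 if intercept else 0)
    if X.shape[0] < n_cols:
        warnings.warn(
            f"{X.shape[0]} pairs < {n_cols} parameters: falling back to the "
            "separation-tied reduced model", stacklevel=2)
        full = PartSumModel(coeffs={(i, j): 0.0 for i in range(length) for j in range(length)},
                            length=length, intercept=0.0)
        return reduce_model(full, design=X, observed_d=y, intercept=intercept)
    beta, b0, pred = _ols(X, y, intercept)
    coeffs = {(i, j): float(beta[i * length + j]) for i in range(length) for j in range(length)}
    model = PartSumModel(coeffs=coeffs, length=length, intercept=b0,
                         n_free_params=n_cols)
    resid = pred - y
    return PartSumFit(model=model, r=pearson(pred, y), residuals=resid,
                      rss=float(resid @ resid))


def separation_classes(length: int) -> dict[tuple[int, int], int]:
    """Default tying rule: class = |i - j| (corresponding vs. cross offsets)."""
    return {(i, j): abs(i - j) for i in range(length) for j in range(length)}


def reduce_model(model: PartSumModel, design: np.ndarray, observed_d: np.ndarray,
                 tying: Callable[[int], dict[tuple[int, int], int]] | None = None,
                 intercept: bool = True) -> PartSumFit:
    """Refit with coefficients tied into classes (default: by |i - j|).

    The tied design sums the full design's columns within each class, so
    the reduced model is nested in the full one: its in-sample fit can
    never exceed the full model's.
    """
    L = model.length
    classes = (tying or separation_classes)(L)
    if not classes or len(set(classes.values())) == 0:
        raise ValueError("tying rule yields zero classes")
    class_ids = sorted(set(classes.values()))
    cols = [(i, j) for i in range(L) for j in range(L)]
    X = np.asarray(design, dtype=float)
    Xc = np.zeros((X.shape[0], len(class_ids)))
    for k, (i, j) in enumerate(cols):
        Xc[:, class_ids.index(classes[(i, j)])] += X[:, k]
    y = np.asarray(observed_d, dtype=float)
    beta, b0, pred = _ols(Xc, y, intercept)
    coeffs = {(i, j): float(beta[class_ids.index(classes[(i, j)])]) for (i, j) in cols}
    reduced = PartSumModel(coeffs=coeffs, length=L, intercept=b0, reduced=True,
                           tying="separation" if tying is None else getattr(tying, "__name__", "custom"),
                           n_free_params=len(class_ids) + (1 if intercept else 0))
    resid = pred - y
    return PartSumFit(model=reduced, r=pearson(pred, y), residuals=resid,
                      rss=float(resid @ resid))
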
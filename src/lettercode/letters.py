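"""Letter space: classical MDS embedding of single-letter dissimilarities.

Each embedding dimension is read as one artificial neuron whose response to
a letter is the letter's coordinate along that dimension.  Pairwise
Euclidean distances between letters in the embedding approximate the input
perceptual dissimilarities (1/RT from oddball search).

The embedding is the classical (Torgerson) solution — double-centre the
squared-distance matrix and eigendecompose — which is deterministic and
exact when the input distances are Euclidean.  An optional metric-stress
(SMACOF) refinement initialised from the classical solution is available
for non-Euclidean inputs.

Note the coordinate axes are defined only up to rotation/reflection: any
orthogonal rotation of the code yields an equivalent set of neural
responses with identical pairwise distances.  Downstream comparisons are
therefore always made on distances, never raw coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from lettercode._util import dissim_to_square, pearson


@dataclass
class LetterCode:
    """Responses of artificial letter-tuned neurons.

    ``responses`` is neurons x letters: row k is neuron k's tuning curve
    over ``letters``.
    """

    letters: tuple[str, ...]
    responses: np.ndarray
    eigenvalues: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.letters = tuple(self.letters)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2 or self.responses.shape[1] != len(self.letters):
            raise ValueError("responses must be neurons x letters")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("letter responses must be finite")
        self._index = {c: i for i, c in enumerate(self.letters)}

    @property
    def n_dims(self) -> int:
        return self.responses.shape[0]

    def letter_index(self, c: str) -> int:
        try:
            return self._index[c]
        except KeyError:
            raise KeyError(f"letter {c!r} not in code alphabet {''.join(self.letters)}") from None

    def coords(self) -> np.ndarray:
        """Letters x dims coordinate matrix (transpose of responses)."""
        return self.responses.T

    def distances(self) -> pd.DataFrame:
        """Pairwise Euclidean distances between letters, square symmetric."""
        d = squareform(pdist(self.coords()))
        return pd.DataFrame(d, index=list(self.letters), columns=list(self.letters))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.responses, columns=list(self.letters),
                     index=[f"neuron_{k}" for k in range(self.n_dims)]).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LetterCode":
        df = pd.read_csv(path, index_col=0)
        return cls(letters=tuple(df.columns), responses=df.to_numpy())


def _classical_mds(sq: np.ndarray, n_dims: int) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson scaling: coordinates (letters x n_dims) and all eigenvalues."""
    n = sq.shape[0]
    d2 = sq ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam = np.clip(evals[:n_dims], 0.0, None)
    coords = evecs[:, :n_dims] * np.sqrt(lam)
    # deterministic sign: largest-|coordinate| entry of each axis positive
    for k in range(n_dims):
        col = coords[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords, evals


def embed_mds(D: pd.DataFrame, n_dims: int = 10, refine: bool = False,
              refine_max_iter: int = 300, seed: int = 0) -> LetterCode:
    """Embed single-item dissimilarities into ``n_dims`` dimensions.

    Parameters
    ----------
    D
        Pair table (item_a, item_b, d) or square symmetric DataFrame,
        complete over all letter pairs.
    n_dims
        Number of embedding dimensions = number of artificial neurons.
        Default 10, the working choice for letter data where ~10
        dimensions account for about 95% of the distance variance.
    refine
        If True, polish the classical solution by metric-stress
        minimisation (SMACOF) initialised from it.

    Returns a :class:`LetterCode` whose ``responses[k]`` is neuron k's
    letter tuning.  Deterministic: the classical solution is closed-form
    and the refinement starts from it (no random restarts).
    """
    sqdf = D if D.shape[0] == D.shape[1] and (D.columns == D.index).all() else dissim_to_square(D)
    letters = [str(c) for c in sqdf.columns]
    n = len(letters)
    if n_dims > n - 1:
        raise ValueError(f"n_dims={n_dims} too large for {n} letters (max {n - 1})")
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    sq = sqdf.to_numpy(dtype=float)
    coords, evals = _classical_mds(sq, n_dims)
    diagnostics = {
        "negative_eigenvalue_mass": float(-evals[evals < 0].sum()),
        "total_eigenvalue_mass": float(evals[evals > 0].sum()),
        "refined": bool(refine),
    }
    if refine:
        from sklearn.manifold import smacof

        coords, stress = smacof(sq, n_components=n_dims, init=coords, n_init=1,
                                metric=True, max_iter=refine_max_iter,
                                random_state=seed, normalized_stress=False)
        diagnostics["stress"] = float(stress)
    return LetterCode(letters=tuple(letters), responses=coords.T,
                      eigenvalues=evals, diagnostics=diagnostics)


def variance_explained_curve(D: pd.DataFrame, max_dims: int | None = None) -> pd.DataFrame:
    """Fit quality as a function of embedding dimensionality.

    For each number of dimensions k = 1..max_dims, embeds and reports

    - ``r``: Pearson correlation between the embedded pairwise distances
      and the input dissimilarities (the distance-level fit);
    - ``cum_eigenvalue_share``: cumulative share of positive eigenvalue
      mass (the variance-level account).

    Both are reported because "variance explained" is ambiguous between
    the two conventions; they agree qualitatively but not numerically.
    """
    sqdf = D if D.shape[0] == D.shape[1] and (D.columns == D.index).all() else dissim_to_square(D)
    n = sqdf.shape[0]
    if max_dims is None:
        max_dims = n - 1
    if max_dims > n - 1:
        raise ValueError(f"max_dims={max_dims} too large for {n} letters")
    sq = sqdf.to_numpy(dtype=float)
    observed = squareform(sq, checks=False)
    coords, evals = _classical_mds(sq, max_dims)
    pos = np.clip(evals, 0.0, None)
    total = pos.sum()
    rows = []
    for k in range(1, max_dims + 1):
        emb = pdist(coords[:, :k])
        rows.append({
            "dims": k,
            "r": pearson(emb, observed),
            "cum_eigenvalue_share": float(pos[:k].sum() / total) if total > 0 else np.nan,
        })
    return pd.DataFrame(rows)


class NeuronTuning(NamedTuple):
    responses: pd.Series
    preferred: str      # argmax letter
    anti_preferred: str  # argmin letter


def neuron_tuning(code: LetterCode, neuron: int) -> NeuronTuning:
    """Tuning curve of one neuron: letter -> response, with extrema."""
    if not 0 <= neuron < code.n_dims:
        raise IndexError(f"neuron index {neuron} out of range [0, {code.n_dims})")
    row = pd.Series(code.responses[neuron], index=list(code.letters), name=f"neuron_{neuron}")
    return NeuronTuning(responses=row, preferred=str(row.idxmax()),
                        anti_preferred=str(row.idxmin()))
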
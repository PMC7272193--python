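"""Representational-similarity statistics.

Neural pattern dissimilarities are computed with the cross-validated
Mahalanobis (crossnobis) distance: for each leave-one-run-out fold the
pattern difference in the held-out run is projected onto the pattern
difference averaged over the remaining runs, and folds are averaged.
Because the two factors carry independent noise the estimator is
*unbiased*: its expectation is zero when two conditions have identical
means, and estimates can legitimately be negative — unlike the plain
Mahalanobis or Euclidean distance, which are inflated by noise.

Semantic dissimilarity between words is the cosine distance (1 - cosine
similarity) between their embedding vectors.  RSA compares dissimilarity
structures by Pearson correlation over shared pairs, with bootstrap
resampling of pairs for error bars, and partial correlation to factor a
third space out of a pairwise comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from lettercode._util import align_pair_tables, all_pairs, canonicalize_pairs, dissim_table, pearson
from lettercode.preprocess import _mad_keep_mask


@dataclass
class PatternArray:
    """Multi-run response patterns: data[run, condition, voxel]."""

    data: np.ndarray
    condition_labels: list[str]
    run_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be runs x conditions x voxels")
        if self.data.shape[0] < 2:
            raise ValueError("need >= 2 runs for cross-validated distances")
        if self.data.shape[1] != len(self.condition_labels):
            raise ValueError("condition_labels length mismatch")
        if self.data.shape[0] != len(self.run_labels):
            raise ValueError("run_labels length mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("patterns contain non-finite values")


def crossnobis(patterns: PatternArray, whitening: np.ndarray | None = None) -> pd.DataFrame:
    """Leave-one-run-out cross-validated (squared) Mahalanobis distances.

    For each condition pair (a, b) and fold m:

        d_m = (x_a,m - x_b,m)^T W (mean_{r != m}(x_a,r - x_b,r))

    averaged over folds.  ``whitening`` is the inverse noise covariance W
    (identity by default, giving the cross-validated squared Euclidean
    distance).  With zero noise the result is exactly the squared
    W-norm of the mean-pattern difference; under the null of identical
    means its expectation is zero.
    """
    X = patterns.data
    n_runs, n_cond, n_vox = X.shape
    if whitening is None:
        W = np.eye(n_vox)
    else:
        W = np.asarray(whitening, dtype=float)
        if W.shape != (n_vox, n_vox):
            raise ValueError("whitening matrix must be voxels x voxels")
        evals = np.linalg.eigvalsh((W + W.T) / 2)
        if evals.min() <= 0:
            rank = int((evals > 1e-12 * evals.max()).sum())
            raise np.linalg.LinAlgError(
                f"whitening matrix not positive definite (rank {rank}/{n_vox})")
    total = np.zeros((n_cond, n_cond))
    run_sum = X.sum(axis=0)
    for m in range(n_runs):
        held = X[m]                                    # conditions x voxels
        rest = (run_sum - held) / (n_runs - 1)
        diff_h = held[:, None, :] - held[None, :, :]    # a x b x voxels
        diff_r = rest[:, None, :] - rest[None, :, :]
        total += np.einsum("abv,vw,abw->ab", diff_h, W, diff_r)
    d = total / n_runs
    d = (d + d.T) / 2
    labels = patterns.condition_labels
    pairs = all_pairs(labels)
    idx = {c: i for i, c in enumerate(labels)}
    vals = [d[idx[a], idx[b]] for a, b in pairs]
    return dissim_table(pairs, np.array(vals))


def aggregate_subjects(per_subject: Sequence[pd.DataFrame], outlier_k: float = 3.0) -> pd.DataFrame:
    """Median dissimilarity across subjects, per pair, after per-pair
    MAD-based outlier removal across subjects."""
    keyed = []
    for t in per_subject:
        keyed.append(canonicalize_pairs(t).set_index(["item_a", "item_b"])["d"])
    pair_index = keyed[0].index
    for k in keyed[1:]:
        if not pair_index.equals(k.index) and set(pair_index) != set(k.index):
            missing = set(pair_index) ^ set(k.index)
            raise ValueError(f"pair sets differ across subjects; mismatched pairs: "
                             f"{sorted(missing)[:10]}")
    mat = pd.concat(keyed, axis=1).to_numpy()   # pairs x subjects
    out = np.empty(mat.shape[0])
    for i in range(mat.shape[0]):
        vals = mat[i]
        keep = _mad_keep_mask(vals, outlier_k)
        out[i] = np.median(vals[keep])
    return dissim_table(list(pair_index), out)


def semantic_dissimilarity(embeddings: pd.DataFrame, w1: str, w2: str) -> float:
    """Cosine distance 1 - cos(v1, v2) between two word vectors, in [0, 2]."""
    for w in (w1, w2):
        if w not in embeddings.index:
            raise KeyError(f"word {w!r} not in embedding table")
    v1 = embeddings.loc[w1].to_numpy(dtype=float)
    v2 = embeddings.loc[w2].to_numpy(dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero embedding vector has no cosine dissimilarity")
    return float(1.0 - v1 @ v2 / (n1 * n2))


def semantic_dissimilarity_table(embeddings: pd.DataFrame,
                                 words: Sequence[str] | None = None) -> pd.DataFrame:
    """All pairwise cosine dissimilarities over ``words`` (default: all rows)."""
    words = list(words) if words is not None else list(embeddings.index)
    pairs = all_pairs(words)
    vals = [semantic_dissimilarity(embeddings, a, b) for a, b in pairs]
    return dissim_table(pairs, np.array(vals))


def rsa_correlation(neural: pd.DataFrame, model: pd.DataFrame,
                    n_boot: int = 1000, seed: int = 0) -> tuple[float, float, float]:
    """Correlation between two dissimilarity structures with bootstrap error.

    Pearson r over the shared pairs; sd from resampling pairs with
    replacement ``n_boot`` times; one-sided p = fraction of bootstrap
    samples with r <= 0 (testing the directional claim r > 0).
    """
    x, y = align_pair_tables(neural, model)
    if len(x) < 3:
        raise ValueError(f"need >= 3 shared pairs, got {len(x)}")
    r = pearson(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(len(x), size=len(x))
        boots[b] = pearson(x[idx], y[idx])
    boots = boots[~np.isnan(boots)]
    return r, float(np.std(boots)), float(np.mean(boots <= 0))


def partial_correlation(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Partial Pearson correlation of x and y given z.

    (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); degenerate when
    z is perfectly correlated with x or y.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if not (len(x) == len(y) == len(z)):
        raise ValueError("vectors must have equal lengths")
    if len(x) < 4:
        raise ValueError("need >= 4 observations")
    r_xy, r_xz, r_yz = pearson(x, y), pearson(x, z), pearson(y, z)
    if abs(r_xz) >= 1 - 1e-12 or abs(r_yz) >= 1 - 1e-12:
        raise ValueError("degenerate conditioning: |r| = 1 between a variable and z")
    return float((r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2)))
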
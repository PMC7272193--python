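"""Shared helpers: canonical pair keys and dissimilarity-table plumbing.

A "dissimilarity table" throughout the package is a pandas DataFrame with
columns ``item_a``, ``item_b``, ``d`` (and optionally ``n_trials``), one row
per *unordered* pair, with ``item_a < item_b`` lexicographically.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PAIR_COLS = ["item_a", "item_b"]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order an unordered pair deterministically (lexicographic)."""
    return (a, b) if a <= b else (b, a)


def canonicalize_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with item_a/item_b swapped into canonical order."""
    out = df.copy()
    swap = out["item_a"] > out["item_b"]
    out.loc[swap, ["item_a", "item_b"]] = out.loc[swap, ["item_b", "item_a"]].to_numpy()
    return out

def all_pairs(items: Sequence[str]) -> list[tuple[str, str]]:
    """All C(n,2) unordered pairs of distinct items, canonical order."""
    items = list(items)
    return [
        canonical_pair(items[i], items[j])
        for i in range(len(items))
        for j in range(i + 1, len(items))
    ]


def dissim_table(pairs: Iterable[tuple[str, str]], d: np.ndarray,
                 n_trials: np.ndarray | None = None) -> pd.DataFrame:
    pairs = [canonical_pair(a, b) for a, b in pairs]
    out = pd.DataFrame(pairs, columns=PAIR_COLS)
    out["d"] = np.asarray(d, dtype=float)
    if n_trials is not None:
        out["n_trials"] = np.asarray(n_trials)
    return out


def dissim_to_square(df: pd.DataFrame, items: Sequence[str] | None = None) -> pd.DataFrame:
    """Pivot a pair table into a symmetric square matrix (zero diagonal).

    Raises ValueError listing missing pairs if the table is incomplete over
    the item set.
    """
    df = canonicalize_pairs(df)
    if items is None:
        items = sorted(set(df["item_a"]) | set(df["item_b"]))
    items = list(items)
    idx = {it: i for i, it in enumerate(items)}
    n = len(items)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 0.0)
    for a, b, d in df[["item_a", "item_b", "d"]].itertuples(index=False):
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = d
    missing = [
        (items[i], items[j])
        for i in range(n)
        for j in range(i + 1, n)
        if np.isnan(mat[i, j])
    ]
    if missing:
        raise ValueError(f"dissimilarity table incomplete; missing pairs: {missing[:20]}"
                         + ("..." if len(missing) > 20 else ""))
    return pd.DataFrame(mat, index=items, columns=items)


def align_pair_tables(*tables: pd.DataFrame) -> list[np.ndarray]:
    """Align several pair tables on their shared pairs; return d vectors.

    Raises ValueError if the shared pair set is empty.
    """
    keyed = []
    for t in tables:
        t = canonicalize_pairs(t)
        keyed.append(t.set_index(PAIR_COLS)["d"])
    shared = keyed[0].index
    for k in keyed[1:]:
        shared = shared.intersection(k.index)
    if len(shared) == 0:
        raise ValueError("pair tables share no pairs")
    return [k.loc[shared].to_numpy(dtype=float) for k in keyed]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def check_seed(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
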
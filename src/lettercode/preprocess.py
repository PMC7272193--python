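"""From raw reaction times to pairwise dissimilarities.

Oddball-search RT for a stimulus pair indexes perceptual similarity
(harder search = more similar); its reciprocal 1/RT behaves like a
distance (it tracks the rate of evidence accumulation and combines
linearly across factors), so the pipeline's dissimilarity for a pair is
the reciprocal of the mean correct RT pooled over subjects, trials and
target assignments.

Outliers are removed per group (per search pair, or per string for
lexical trials) by the scaled-MAD rule: drop trials more than k scaled
median-absolute-deviations from the group median, with the 1.4826
normal-consistency constant (the MATLAB ``isoutlier`` default).  Split-half
reliability across subjects gives the noise ceiling any model can reach,
corrected to full-data reliability by the Spearman-Brown formula
r_data = 2 r_sh / (r_sh + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from lettercode._util import canonicalize_pairs, dissim_table, pearson

MAD_SCALE = 1.4826  # normal-consistency constant, matches MATLAB isoutlier


@dataclass
class ConsistencyStats:
    """Split-half reliability of a dissimilarity (or RT) dataset."""

    r_sh: float          # mean split-half Pearson r over random splits
    r_sh_sd: float       # sd over splits
    r_data: float        # Spearman-Brown corrected full-data reliability
    n_splits: int
    r_odd_even: float    # the deterministic odd/even-subject split


def _mad_keep_mask(x: np.ndarray, k: float) -> np.ndarray:
    """True for values within k scaled-MADs of the median.

    A single value is always kept (MAD undefined).  If MAD is zero
    (majority of values identical), anything off the median is removed —
    the behaviour of the standard median rule.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= 1 or not np.isfinite(k):
        return np.ones(x.size, dtype=bool)
    med = np.median(x)
    mad = MAD_SCALE * np.median(np.abs(x - med))
    return np.abs(x - med) <= k * mad


def _group_key(trials: pd.DataFrame) -> list[str]:
    if {"item_a", "item_b"}.issubset(trials.columns):
        return ["item_a", "item_b"]
    if "string" in trials.columns:
        return ["string"]
    raise ValueError("trial table must have item_a/item_b (search) or string (lexical) columns")


def filter_outliers(trials: pd.DataFrame, k: float = 3.0,
                    iterate: bool = False) -> tuple[pd.DataFrame, dict]:
    """Remove RT outliers per search pair (or per string), scaled-MAD rule.

    Incorrect trials are dropped first — only correct responses enter any
    analysis.  Returns the filtered table and a report with the removed
    outlier fraction (among correct trials).

    The default is a single pass (the convention of the standard
    median-rule routines).  A single pass is not idempotent in general —
    removing points shrinks the group MAD, which can expose further
    points; ``iterate=True`` repeats the pass until a fixed point, which
    is idempotent by construction.
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    cols = _group_key(trials)
    t = trials
    if "correct" in t.columns:
        t = t[t["correct"].astype(bool)]
    if cols == ["item_a", "item_b"]:
        t = canonicalize_pairs(t)
    n_total = len(t)

    def one_pass(frame: pd.DataFrame) -> pd.DataFrame:
        keep = np.ones(len(frame), dtype=bool)
        rts = frame["rt_s"].to_numpy(dtype=float)
        for _, idx in frame.groupby(cols, sort=False).indices.items():
            keep[idx] = _mad_keep_mask(rts[idx], k)
        return frame.iloc[np.nonzero(keep)[0]]

    out = one_pass(t)
    passes = 1
    while iterate:
        nxt = one_pass(out)
        if len(nxt) == len(out):
            break
        out, passes = nxt, passes + 1
    out = out.reset_index(drop=True)
    report = {
        "n_correct": int(n_total),
        "n_removed": int(n_total - len(out)),
        "removed_fraction": float((n_total - len(out)) / n_total) if n_total else 0.0,
        "k": k,
        "passes": passes,
    }
    return out, report


def dissimilarity_from_trials(trials: pd.DataFrame,
                              statistic: Literal["reciprocal_of_mean",
                                                 "mean_of_reciprocals"] = "reciprocal_of_mean",
                              ) -> pd.DataFrame:
    """Pair dissimilarity d = 1 / mean(RT), pooling subjects, trials and
    target assignments.

    ``mean_of_reciprocals`` is exposed for sensitivity analysis; the
    default follows the convention of averaging search times first and
    then taking the reciprocal.
    """
    t = canonicalize_pairs(trials)
    if "correct" in t.columns:
        t = t[t["correct"].astype(bool)]
    if len(t) == 0:
        raise ValueError("no correct trials")
    g = t.groupby(["item_a", "item_b"], sort=True)["rt_s"]
    if statistic == "reciprocal_of_mean":
        d = 1.0 / g.mean()
    elif statistic == "mean_of_reciprocals":
        d = (1.0 / t["rt_s"]).groupby([t["item_a"], t["item_b"]]).mean()
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    n = g.size()
    return dissim_table(list(d.index), d.to_numpy(), n.to_numpy())


def _half_statistic(t: pd.DataFrame, subjects: np.ndarray,
                    statistic: str) -> pd.Series:
    half = t[t["subject_id"].isin(subjects)]
    g = half.groupby(["item_a", "item_b"], sort=True)["rt_s"]
    if statistic == "mean_rt":
        return g.mean()
    if statistic == "mean_reciprocal_rt":
        return (1.0 / half["rt_s"]).groupby([half["item_a"], half["item_b"]]).mean()
    raise ValueError(f"unknown statistic {statistic!r}")


def split_half_consistency(trials: pd.DataFrame, n_splits: int = 100, seed: int = 0,
                           statistic: Literal["mean_rt", "mean_reciprocal_rt"] = "mean_rt",
                           method: Literal["pearson", "spearman"] = "pearson",
                           ) -> ConsistencyStats:
    """Split-half correlation of per-pair statistics across subject halves.

    Subjects are randomly partitioned into two halves ``n_splits`` times;
    the per-pair statistic (mean RT by default) is correlated between
    halves.  The deterministic odd/even split (by sorted subject order) is
    reported separately.  r_data applies the Spearman-Brown correction to
    the mean split-half r.
    """
    t = canonicalize_pairs(trials)
    if "correct" in t.columns:
        t = t[t["correct"].astype(bool)]
    subjects = np.array(sorted(t["subject_id"].unique()))
    if len(subjects) < 2:
        raise ValueError("split-half consistency needs at least 2 subjects")
    rng = np.random.default_rng(seed)

    def corr(a: pd.Series, b: pd.Series) -> float:
        joined = pd.concat([a, b], axis=1, join="inner").to_numpy()
        if method == "spearman":
            from scipy.stats import spearmanr
            return float(spearmanr(joined[:, 0], joined[:, 1]).statistic)
        return pearson(joined[:, 0], joined[:, 1])

    rs = []
    for _ in range(n_splits):
        perm = rng.permutation(subjects)
        h1, h2 = perm[: len(subjects) // 2], perm[len(subjects) // 2:]
        rs.append(corr(_half_statistic(t, h1, statistic), _half_statistic(t, h2, statistic)))
    odd, even = subjects[::2], subjects[1::2]
    r_odd_even = corr(_half_statistic(t, odd, statistic), _half_statistic(t, even, statistic))
    r_sh = float(np.mean(rs))
    return ConsistencyStats(r_sh=r_sh, r_sh_sd=float(np.std(rs)),
                            r_data=spearman_brown(r_sh), n_splits=n_splits,
                            r_odd_even=r_odd_even)


def spearman_brown(r_sh: float) -> float:
    """Full-data reliability from a split-half correlation: 2r/(1+r)."""
    if r_sh <= -1:
        raise ValueError("Spearman-Brown correction undefined at r_sh <= -1")
    return 2.0 * r_sh / (r_sh + 1.0)
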
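"""Group-level location statistics and tidy contrast tables.

Peak-source coordinates (one xyz triple per subject, finger and condition,
in an MNI-like frame) are summarized as group means with SEM, compared by
the Euclidean distance between group means, and tested with a nonparametric
permutation test: per subject, the two labels (fingers, or conditions) are
swapped with probability 1/2, the between-mean distance recomputed, and the
p-value taken as (b + 1)/(m + 1) where b counts null distances >= observed
(the add-one rule avoids p = 0 at finite m).

ANOVA-style analyses of CKC strength are out of scope here; the module only
emits tidy long-format tables for external statistics tooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class PermutationResult:
    observed_distance: float
    null_samples: int
    p_value: float
    seed: int | None

    def __post_init__(self):
        if not 0 < self.p_value <= 1:
            raise StatsError("p-value must lie in (0, 1]")


def mean_coordinates(coords: pd.DataFrame,
                     by=("finger", "condition")) -> pd.DataFrame:
    """Group mean and SEM of peak coordinates per cell.

    ``coords`` is long-format with columns subject, finger, condition,
    x, y, z.  Every requested cell needs at least two subjects.
    """
    required = {"subject", "x", "y", "z"} | set(by)
    missing = required - set(coords.columns)
    if missing:
        raise StatsError(f"missing columns: {sorted(missing)}")
    rows = []
    for key, g in coords.groupby(list(by), sort=True):
        if len(g) < 2:
            raise StatsError(f"cell {key} has fewer than 2 subjects")
        rec = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        rec["n"] = len(g)
        for ax in ("x", "y", "z"):
            rec[f"{ax}_mean"] = g[ax].mean()
            rec[f"{ax}_sem"] = g[ax].std(ddof=1) / np.sqrt(len(g))
        rows.append(rec)
    return pd.DataFrame(rows)


def pairwise_distance(mean_a, mean_b) -> float:
    """Euclidean distance (mm) between two group-mean points."""
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if a.shape != (3,) or b.shape != (3,):
        raise StatsError("means must be 3-vectors")
    return float(np.linalg.norm(a - b))


def permutation_distance_test(coords_a: np.ndarray, coords_b: np.ndarray,
                              n_perm: int = 100_000, seed: int | None = None,
                              exact: bool = False,
                              pooled: bool = False) -> PermutationResult:
    """Permutation test of the distance between two sets of paired coordinates.

    ``coords_a``/``coords_b`` are (n_subjects, 3), paired by row.  The
    observed statistic is the Euclidean distance between the two group
    means.  The default null swaps, per subject, the a/b labels with
    probability 1/2 (respecting the repeated-measures pairing); ``exact``
    enumerates all 2^n swap patterns instead of sampling; ``pooled``
    relabels all 2n points without respecting pairing (available for
    comparison, not the default).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise StatsError("coordinate sets must be matching (n, 3) arrays "
                         "paired by subject")
    n = a.shape[0]
    if n < 1 or n_perm < 1:
        raise StatsError("need at least one subject and one permutation")
    d = a - b
    observed = float(np.linalg.norm(d.mean(axis=0)))
    rng = np.random.default_rng(seed)
    if pooled:
        pool = np.concatenate([a, b], axis=0)
        null = np.empty(n_perm)
        for m in range(n_perm):
            idx = rng.permutation(2 * n)
            null[m] = np.linalg.norm(pool[idx[:n]].mean(axis=0)
                                     - pool[idx[n:]].mean(axis=0))
        m_total = n_perm
    else:
        if exact:
            if n > 20:
                raise StatsError("exact enumeration limited to n <= 20")
            patterns = np.array(
                [[1 if (p >> i) & 1 else -1 for i in range(n)]
                 for p in range(2 ** n)], dtype=float)
            m_total = patterns.shape[0]
        else:
            patterns = rng.choice([-1.0, 1.0], size=(n_perm, n))
            m_total = n_perm
        # mean_a - mean_b under a per-subject swap s_i is (1/n) sum s_i d_i
        null = np.linalg.norm(patterns @ d, axis=1) / n
    b_count = int(np.sum(null >= observed))
    p = (b_count + 1) / (m_total + 1)
    return PermutationResult(observed_distance=observed, null_samples=m_total,
                             p_value=p, seed=seed)


def mean_pairwise_subject_distance(coords_a, coords_b) -> float:
    """Mean of per-subject Euclidean distances (alternative statistic)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise StatsError("coordinate sets must be paired")
    return float(np.mean(np.linalg.norm(a - b, axis=1)))


def condition_contrast_table(results: pd.DataFrame,
                             value_col: str = "ckc") -> pd.DataFrame:
    """Tidy long table (subject, finger, condition, level, ckc) for rANOVA tools.

    Duplicate cells are an error; missing cells of the implied full design
    are appended with NaN and ``missing=True`` rather than silently dropped.
    """
    keys = ["subject", "finger", "condition", "level"]
    for col in keys + [value_col]:
        if col not in results.columns:
            raise StatsError(f"missing column: {col}")
    dup = results.duplicated(subset=keys)
    if dup.any():
        raise StatsError(f"duplicate cells: "
                         f"{results.loc[dup, keys].to_dict('records')}")
    out = results[keys + [value_col]].copy()
    out["missing"] = False
    full = pd.MultiIndex.from_product(
        [sorted(out[k].unique()) for k in keys], names=keys)
    have = pd.MultiIndex.from_frame(out[keys])
    absent = full.difference(have)
    if len(absent):
        pad = pd.DataFrame(list(absent), columns=keys)
        pad[value_col] = np.nan
        pad["missing"] = True
        out = pd.concat([out, pad], ignore_index=True)
    return out.sort_values(keys, kind="mergesort").reset_index(drop=True)
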
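"""Quantifier inter-correlations and category separation by Hellinger distance.

The Hellinger distance between two empirical distributions is estimated on a
shared histogram grid spanning the pooled min–max range per dimension:
``HD = sqrt(1 - sum_i sqrt(p_i * q_i))``. It is 0 for identical samples and 1
for samples with disjoint support, which the shared grid preserves exactly.
Defaults: 64 bins in 1-D, 32 per axis in 2-D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "CategorySeparation",
    "pairwise_correlations",
    "hellinger_distance",
    "category_separation_table",
    "DEFAULT_SUBSPACES",
]

# the ten comparison subspaces: three from the new proportions, five legacy
# 2-D spaces, and the two 1-D scores
DEFAULT_SUBSPACES: tuple[tuple[str, ...], ...] = (
    ("p_pheo", "p_eu"),
    ("p_non", "p_pheo"),
    ("p_non", "p_eu"),
    ("mean_h", "mean_s"),
    ("lum_l", "colour_c"),
    ("a_star", "b_star"),
    ("l_star", "a_star"),
    ("l_star", "b_star"),
    ("pie",),
    ("t_index",),
)


@dataclass
class CorrelationMatrix:
    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


@dataclass(frozen=True)
class CategorySeparation:
    subspace: tuple[str, ...]
    pair: tuple[str, str]
    hd: float
    bins: tuple[int, ...]
    best: bool = False


def pairwise_correlations(table: pd.DataFrame, variables=None) -> CorrelationMatrix:
    """Pearson r and two-sided p for every quantifier pair.

    Missing values are dropped pairwise; a constant variable yields NaN with
    a warning. p-values use the t distribution with n - 2 df.
    """
    if variables is None:
        variables = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    variables = tuple(variables)
    k = len(variables)
    if len(table.dropna(subset=list(variables), how="all")) < 3:
        raise ValueError("need at least 3 rows for correlation analysis")
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        n[i, i] = table[variables[i]].notna().sum()
        for j in range(i + 1, k):
            sub = table[[variables[i], variables[j]]].dropna()
            x, y = sub.iloc[:, 0].to_numpy(float), sub.iloc[:, 1].to_numpy(float)
            n[i, j] = n[j, i] = len(sub)
            if len(sub) < 3 or np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(
                    f"correlation undefined for ({variables[i]}, {variables[j]})"
                )
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = list(variables)
    return CorrelationMatrix(
        variables=variables,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )


def hellinger_distance(
    a, b, bins: int | tuple[int, ...] | None = None, range_=None
) -> float:
    """Histogram Hellinger distance between two point samples (1-D or 2-D).

    Both samples are binned on one shared grid spanning the pooled min–max
    per dimension (or an explicit ``range_``), normalised to probabilities
    p, q, and ``HD = sqrt(1 - sum sqrt(p*q))`` is returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ValueError("samples must have the same dimensionality")
    d = a.shape[1]
    if d not in (1, 2):
        raise ValueError("only 1-D and 2-D subspaces are supported")
    if bins is None:
        bins = 64 if d == 1 else 32
    if np.isscalar(bins):
        bins = (int(bins),) * d
    if range_ is None:
        pooled = np.vstack([a, b])
        range_ = [(pooled[:, i].min(), pooled[:, i].max()) for i in range(d)]
        range_ = [(lo, hi if hi > lo else lo + 1.0) for lo, hi in range_]
    pa, edges = np.histogramdd(a, bins=bins, range=range_)
    pb, _ = np.histogramdd(b, bins=bins, range=range_)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    bc = np.sum(np.sqrt(pa * pb))
    return float(np.sqrt(max(0.0, 1.0 - bc)))


def category_separation_table(
    table: pd.DataFrame,
    subspaces=DEFAULT_SUBSPACES,
    category_col: str = "category",
    min_n: int = 30,
) -> list[CategorySeparation]:
    """Hellinger distance for every subspace and category pair.

    Categories with fewer than ``min_n`` rows are skipped with a warning.
    The best-separating subspace per category pair is flagged.
    """
    cats = [c for c in table[category_col].dropna().unique()]
    if len(cats) < 2:
        raise ValueError("need at least two categories")
    counts = table[category_col].value_counts()
    usable = sorted(c for c in cats if counts[c] >= min_n)
    for c in cats:
        if c not in usable:
            warnings.warn(f"category {c!r} has {counts[c]} rows (< {min_n}); skipped")
    results: list[CategorySeparation] = []
    for i, ca in enumerate(usable):
        for cb in usable[i + 1:]:
            pair_results = []
            for subspace in subspaces:
                cols = list(subspace)
                sub_a = table.loc[table[category_col] == ca, cols].dropna().to_numpy(float)
                sub_b = table.loc[table[category_col] == cb, cols].dropna().to_numpy(float)
                bins = (64,) if len(cols) == 1 else (32, 32)
                hd = hellinger_distance(sub_a, sub_b, bins=bins)
                pair_results.append(
                    CategorySeparation(tuple(subspace), (ca, cb), hd, bins)
                )
            best_idx = int(np.argmax([r.hd for r in pair_results]))
            pair_results[best_idx] = CategorySeparation(
                pair_results[best_idx].subspace,
                pair_results[best_idx].pair,
                pair_results[best_idx].hd,
                pair_results[best_idx].bins,
                best=True,
            )
            results.extend(pair_results)
    return results


def separation_report(results: list[CategorySeparation]) -> pd.DataFrame:
    """Tidy DataFrame view of a category-separation analysis."""
    return pd.DataFrame(
        {
            "subspace": ["x".join(r.subspace) for r in results],
            "category_a": [r.pair[0] for r in results],
            "category_b": [r.pair[1] for r in results],
            "hellinger": [r.hd for r in results],
            "best_for_pair": [r.best for r in results],
        }
    )
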
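"""Dual-perspective yield-stability indices: superiority measure and ecovalence.

Given an entity x environment mean matrix X (entities are genotypes under the
genotype perspective, management combinations under the management
perspective), two complementary indices are computed per entity i over n
environments:

* superiority measure  P_i = sum_j (X_ij - M_j)^2 / (2n), where M_j is the best
  (maximum) observation in environment j.  P_i mixes mean performance and
  stability: low P_i = consistently close to the environment winner.

* ecovalence  W_i = sum_j (X_ij - Xbar_i - Xbar_j + Xbar)^2, the entity's share
  of the genotype x environment interaction sum of squares (double-centred
  residuals).  W_i is blind to mean level: low W_i = dynamically stable.

Lower is more stable for both.  Rankings across traits are compared with
Spearman correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .trial_io import TwoWayMatrix, env_means

__all__ = [
    "RankCorrMatrix",
    "superiority",
    "ecovalence",
    "stability_table",
    "rank_correlation_matrix",
    "spearman_exact",
]


def superiority(m: TwoWayMatrix | pd.DataFrame) -> pd.Series:
    """Superiority measure P_i per entity (row); squared trait units.

    An entity that attains the column maximum in every environment scores 0;
    adding a common constant to the whole matrix leaves P unchanged.
    """
    values = m.values if isinstance(m, TwoWayMatrix) else m
    if values.isna().any().any():
        raise ValueError("superiority requires a complete matrix")
    X = values.to_numpy(dtype=float)
    n = X.shape[1]
    if n < 1:
        raise ValueError("need at least one environment")
    M = X.max(axis=0)
    P = ((X - M) ** 2).sum(axis=1) / (2.0 * n)
    return pd.Series(P, index=values.index, name="P")


def ecovalence(m: TwoWayMatrix | pd.DataFrame) -> pd.Series:
    """Ecovalence W_i per entity; squared trait units.

    Sum over entities equals the interaction sum of squares of the two-way
    table.  Invariant to adding row- or column-constant vectors.
    """
    values = m.values if isinstance(m, TwoWayMatrix) else m
    if values.isna().any().any():
        raise ValueError("ecovalence requires a complete matrix")
    X = values.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("ecovalence needs >= 2 entities and >= 2 environments")
    resid = X - X.mean(axis=1, keepdims=True) - X.mean(axis=0, keepdims=True) + X.mean()
    W = (resid ** 2).sum(axis=1)
    return pd.Series(W, index=values.index, name="W")


def stability_table(table: pd.DataFrame, traits: list[str],
                    perspective: str = "genotype",
                    years=None) -> pd.DataFrame:
    """Both stability indices, means and ranks for each trait and entity.

    Works on block-averaged entity x environment means; ranks use average ties,
    rank 1 = most stable (lowest index).
    """
    frames = []
    for trait in traits:
        m = env_means(table, trait, perspective=perspective, years=years)
        P = superiority(m)
        W = ecovalence(m)
        mean = m.values.mean(axis=1)
        frames.append(pd.DataFrame({
            "entity": m.values.index,
            "trait": trait,
            "perspective": perspective,
            "P": P.values,
            "W": W.values,
            "mean": mean.values,
            "n_environments": m.n_environments,
            "rank_P": stats.rankdata(P.values, method="average"),
            "rank_W": stats.rankdata(W.values, method="average"),
        }))
    return pd.concat(frames, ignore_index=True)


def spearman_exact(x, y) -> tuple[float, float]:
    """Spearman rho with an exact permutation p-value (two-sided).

    Enumerates all n! pairings; intended for the small entity counts of a
    stability study (n <= 8).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > 8:
        raise ValueError("exact permutation p only supported for n <= 8")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    return rho, count / total


@dataclass
class RankCorrMatrix:
    """Trait x trait Spearman correlations of a stability index across entities."""

    rho: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # boolean mask at alpha
    alpha: float
    index: str  # which stability index was correlated: "P" or "W"


def rank_correlation_matrix(results: pd.DataFrame, index: str = "P",
                            alpha: float = 0.05,
                            method: str = "t") -> RankCorrMatrix:
    """Spearman correlation matrix of one stability index across traits.

    ``results`` is a stability_table output covering several traits with the
    same entities.  ``method`` selects the p-value: "t" for the t-distribution
    approximation, "exact" for full permutation enumeration (n <= 8).
    """
    if index not in ("P", "W"):
        raise ValueError("index must be 'P' or 'W'")
    wide = results.pivot(index="entity", columns="trait", values=index)
    if wide.isna().any().any():
        raise ValueError("entities differ across traits")
    if wide.shape[0] < 3:
        raise ValueError("need >= 3 entities for a rank correlation")
    traits = list(wide.columns)
    k = len(traits)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            x, y = wide.iloc[:, a].values, wide.iloc[:, b].values
            if method == "exact":
                r, p = spearman_exact(x, y)
            else:
                r, p = stats.spearmanr(x, y)
            rho[a, b] = rho[b, a] = r
            pval[a, b] = pval[b, a] = p
    rho_df = pd.DataFrame(rho, index=traits, columns=traits)
    p_df = pd.DataFrame(pval, index=traits, columns=traits)
    sig = (p_df < alpha) & ~np.eye(k, dtype=bool)
    return RankCorrMatrix(rho=rho_df, p=p_df, significant=sig, alpha=alpha, index=index)
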
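"""Phenotypic-space analysis: scaled PCA and per-group slope screening.

Entity x trait summary matrices (genotype or management means over the
post-anthesis physiology and yield-component traits) are projected into a
low-dimensional phenotypic space by PCA on standardised traits (centered,
unit SD — equivalent to an eigen-decomposition of the trait correlation
matrix).  Scores carry Cartesian quadrant labels (I = +,+ counterclockwise)
so genotype and management projections can be read off consistently.

slope_screen fits per-group ordinary least squares (e.g. straw WSC
concentration at maturity against green canopy duration, one group per
genotype x year over management means) and flags groups whose slope differs
from zero at alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "PhenoSpace",
    "DEFAULT_PHENOSPACE_TRAITS",
    "pca_scaled",
    "project",
    "slope_screen",
]

#: Default post-anthesis physiology + yield-component trait set.
DEFAULT_PHENOSPACE_TRAITS = (
    "GCD", "SPAD_61", "TT_71_77", "GN", "tiller_61", "TGW", "WSC_conc_87_straw",
)


@dataclass
class PhenoSpace:
    """Fitted scaled-PCA space: loadings, scores, variance fractions, scaler."""

    loadings: pd.DataFrame        # trait x PC
    scores: pd.DataFrame          # entity x PC
    variance_fraction: pd.Series  # per PC, sums to 1
    means: pd.Series              # per-trait centering
    sds: pd.Series                # per-trait scaling

    @property
    def traits(self) -> list[str]:
        return list(self.loadings.index)


def _quadrant(pc1: float, pc2: float) -> str:
    if pc1 >= 0 and pc2 >= 0:
        return "I"
    if pc1 < 0 and pc2 >= 0:
        return "II"
    if pc1 < 0 and pc2 < 0:
        return "III"
    return "IV"


def pca_scaled(matrix: pd.DataFrame) -> PhenoSpace:
    """PCA with scaling on an entity x trait mean matrix.

    Each trait is centered and scaled to unit SD (ddof=1) before the
    decomposition, so components reflect the correlation structure.  The sign
    of each loading vector is fixed by making its largest-magnitude element
    positive — eigenvector signs are otherwise arbitrary and would make
    outputs platform-dependent.
    """
    if matrix.isna().any().any():
        raise ValueError("phenospace matrix has missing values")
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 traits")
    sds = matrix.std(axis=0, ddof=1)
    dead = sds[sds == 0]
    if len(dead):
        raise ValueError(f"zero-variance trait(s): {list(dead.index)}")
    means = matrix.mean(axis=0)
    Z = (matrix - means) / sds

    n_comp = min(matrix.shape[0] - 1, matrix.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(Z.to_numpy())
    load = pca.components_.T  # trait x PC

    # deterministic sign convention
    for j in range(load.shape[1]):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] *= -1
            scores[:, j] *= -1

    pcs = [f"PC{i + 1}" for i in range(n_comp)]
    var = pca.explained_variance_ratio_
    return PhenoSpace(
        loadings=pd.DataFrame(load, index=matrix.columns, columns=pcs),
        scores=pd.DataFrame(scores, index=matrix.index, columns=pcs),
        variance_fraction=pd.Series(var, index=pcs),
        means=means,
        sds=sds,
    )


def project(space: PhenoSpace, rows: pd.DataFrame) -> pd.DataFrame:
    """Project new entity x trait rows into a fitted phenotypic space.

    Rows are standardised with the stored means/SDs and multiplied onto the
    loadings; the output carries a Cartesian quadrant label from the signs of
    PC1/PC2.
    """
    if set(rows.columns) != set(space.traits):
        raise ValueError(
            f"trait mismatch: expected {space.traits}, got {list(rows.columns)}"
        )
    Z = (rows[space.traits] - space.means) / space.sds
    scores = Z.to_numpy() @ space.loadings.to_numpy()
    out = pd.DataFrame(scores, index=rows.index, columns=space.loadings.columns)
    out["quadrant"] = [
        _quadrant(r[0], r[1] if scores.shape[1] > 1 else 0.0) for r in scores
    ]
    return out


def slope_screen(table: pd.DataFrame, x_trait: str, y_trait: str,
                 group_by: list[str], alpha: float = 0.05,
                 mean_over: list[str] | None = None) -> pd.DataFrame:
    """Per-group OLS of y_trait on x_trait with a two-sided slope test.

    ``mean_over`` optionally averages replicates (e.g. blocks) first so each
    point is a management mean; groups with fewer than 3 points or degenerate
    x variance are skipped with a warning.  ``significant`` is True iff the
    slope's p-value is below alpha.
    """
    sub = table[table["trait"].isin([x_trait, y_trait])]
    keys = [c for c in ("year", "block", "nitrogen_level", "application_time",
                        "sowing_date", "genotype") if c in table.columns]
    wide = sub.pivot_table(index=keys, columns="trait", values="value",
                           aggfunc="mean").reset_index()
    if x_trait not in wide.columns or y_trait not in wide.columns:
        raise ValueError(f"traits {x_trait!r}/{y_trait!r} not found")
    if mean_over:
        point_keys = [k for k in keys if k not in mean_over]
        wide = wide.groupby(point_keys, observed=True)[[x_trait, y_trait]].mean().reset_index()

    rows = []
    for key, g in wide.groupby(group_by, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        g = g.dropna(subset=[x_trait, y_trait])
        if len(g) < 3:
            warnings.warn(f"group {key}: fewer than 3 points, skipped", stacklevel=2)
            continue
        x, y = g[x_trait].to_numpy(), g[y_trait].to_numpy()
        if np.ptp(x) == 0 or np.var(x) == 0:
            warnings.warn(f"group {key}: degenerate x variance, skipped", stacklevel=2)
            continue
        fit = stats.linregress(x, y)
        rows.append(dict(zip(group_by, key)) | {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.rvalue ** 2,
            "p_value": fit.pvalue,
            "n": len(g),
            "significant": bool(fit.pvalue < alpha),
        })
    return pd.DataFrame(rows)
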
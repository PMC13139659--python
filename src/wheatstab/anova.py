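"""Split--split--split-plot ANOVA with expected-mean-square F tests.

The field layout randomizes nitrogen level on main plots within blocks,
application time on split plots, sowing date on split--split plots, and
genotype on split--split--split plots.  Blocks are random; all treatment
factors are fixed.  Each treatment stratum carries its own error term, so F
ratios must be formed per the expected mean squares: a fixed effect is tested
against the pooled block-interaction terms of its own stratum, and the
deepest stratum pools with the within-cell residual.

Sums of squares use the classical balanced-factorial identity: for a term S
(a subset of factors), SS_S is the inclusion--exclusion alternating sum of
"uncorrected" marginal sums of squares U(T) = sum over T-cells of
(cell total)^2 / cell size, over all subsets T of S.  On balanced data this
reproduces the orthogonal decomposition exactly and is order-independent.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trial_io import DesignSpec, validate_design

__all__ = [
    "AnovaResult",
    "UnbalancedError",
    "ems_denominators",
    "fit_split3",
    "letters",
]

BLOCK = "block"
#: Treatment factors in stratum order (main plot -> deepest split).
STRATUM_ORDER = ("nitrogen_level", "application_time", "sowing_date", "genotype")


class UnbalancedError(ValueError):
    """The table is not balanced; run trial_io.validate_design for the census."""


def _term_name(term: tuple[str, ...]) -> str:
    return ":".join(term)


def ems_denominators(strata: tuple[str, ...] = STRATUM_ORDER) -> dict[str, str]:
    """Map every fixed-effect source to its error stratum.

    For a fixed term whose deepest factor sits in stratum d, the denominator
    pools block x (that factor) x (any subset of shallower treatment factors);
    the deepest stratum additionally pools the within-cell residual and is
    labelled "residual".  The mapping is a function: one denominator per
    source.
    """
    if not strata:
        raise ValueError("need at least one treatment stratum")
    mapping: dict[str, str] = {}
    last = strata[-1]
    for r in range(1, len(strata) + 1):
        for term in itertools.combinations(strata, r):
            deepest = max(term, key=strata.index)
            if deepest == last:
                mapping[_term_name(term)] = "residual"
            else:
                mapping[_term_name(term)] = f"error({deepest})"
    return mapping


def _stratum_members(strata: tuple[str, ...]) -> dict[str, list[tuple[str, ...]]]:
    """Random (block-interaction) terms pooled into each error stratum."""
    pools: dict[str, list[tuple[str, ...]]] = {}
    last = strata[-1]
    for d, factor in enumerate(strata):
        label = "residual" if factor == last else f"error({factor})"
        shallower = strata[:d]
        members = []
        for r in range(len(shallower) + 1):
            for extra in itertools.combinations(shallower, r):
                term = tuple(sorted((BLOCK, factor, *extra),
                                    key=(BLOCK, *strata).index))
                members.append(term)
        pools[label] = members
    return pools


def _balanced_ss(y: np.ndarray, codes: dict[str, np.ndarray],
                 levels: dict[str, int]) -> tuple[dict[tuple[str, ...], float], float, float]:
    """Orthogonal SS for every factorial term of a balanced layout.

    Returns (SS per term, correction term, total SS about the mean).
    """
    n = y.size
    factors = list(codes)
    ct = y.sum() ** 2 / n
    U: dict[tuple[str, ...], float] = {(): ct}
    for r in range(1, len(factors) + 1):
        for sub in itertools.combinations(factors, r):
            idx = np.zeros(n, dtype=np.int64)
            size = 1
            for f in sub:
                idx = idx * levels[f] + codes[f]
                size *= levels[f]
            totals = np.bincount(idx, weights=y, minlength=size)
            counts = np.bincount(idx, minlength=size)
            if counts.min() == 0 or counts.max() != counts.min():
                raise UnbalancedError(
                    f"unequal cell counts for term {sub}; validate_design first"
                )
            U[sub] = float((totals ** 2 / counts[0]).sum())
    ss: dict[tuple[str, ...], float] = {}
    for sub in U:
        if not sub:
            continue
        total = 0.0
        for r in range(len(sub) + 1):
            for t in itertools.combinations(sub, r):
                total += (-1) ** (len(sub) - len(t)) * U[t]
        ss[sub] = total
    ss_total = float((y ** 2).sum() - ct)
    return ss, ct, ss_total


@dataclass
class AnovaResult:
    """ANOVA table plus the error-stratum bookkeeping needed for letters()."""

    table: pd.DataFrame          # source, df, SS, MS, F, p, denominator
    strata: dict[str, tuple[float, float]]  # label -> (SS, df)
    cell_means_n: dict[str, int] = field(default_factory=dict)  # factor -> obs per level mean
    data: pd.DataFrame | None = None

    def stratum_ms(self, label: str) -> tuple[float, float]:
        ss, df = self.strata[label]
        if df <= 0:
            raise ValueError(f"error stratum {label!r} has no degrees of freedom")
        return ss / df, df


def fit_split3(table: pd.DataFrame, trait: str, year: int | None = None,
               strata: tuple[str, ...] = STRATUM_ORDER) -> AnovaResult:
    """Fit the per-year split--split--split-plot ANOVA for one trait.

    Balanced data only; the sequential decomposition is orthogonal, F ratios
    follow the expected-mean-square mapping of :func:`ems_denominators`, and
    p-values come from the F distribution.
    """
    sub = table[table["trait"] == trait].copy()
    if year is not None:
        sub = sub[sub["year"] == year]
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}"
                         + (f" in {year}" if year else ""))
    if year is None and sub["year"].nunique() > 1:
        raise ValueError("fit_split3 is a per-year model; pass year=...")

    factors = (BLOCK, *strata)
    codes: dict[str, np.ndarray] = {}
    levels: dict[str, int] = {}
    for f in factors:
        cats, codes_f = np.unique(sub[f].to_numpy(), return_inverse=True)
        codes[f] = codes_f
        levels[f] = len(cats)
        if len(cats) < 2:
            raise ValueError(f"factor {f!r} has a single level")
    y = sub["value"].to_numpy(dtype=float)

    try:
        ss, _, ss_total = _balanced_ss(y, codes, levels)
    except UnbalancedError:
        raise UnbalancedError(
            f"trait {trait!r} is unbalanced; run trial_io.validate_design"
        )

    df_term = {t: int(np.prod([levels[f] - 1 for f in t])) for t in ss}
    n_cells = int(np.prod(list(levels.values())))
    ss_resid_within = ss_total - sum(ss.values())
    df_resid_within = y.size - n_cells

    # pool random block-interaction terms into their error strata
    pools = _stratum_members(strata)
    strata_ssdf: dict[str, tuple[float, float]] = {}
    for label, members in pools.items():
        s = sum(ss[m] for m in members)
        d = sum(df_term[m] for m in members)
        if label == "residual":
            s += max(ss_resid_within, 0.0)
            d += df_resid_within
        strata_ssdf[label] = (s, d)

    denom_map = ems_denominators(strata)
    rows = []
    # block row (random; no F by convention)
    rows.append({"source": BLOCK, "df": df_term[(BLOCK,)], "SS": ss[(BLOCK,)],
                 "MS": ss[(BLOCK,)] / df_term[(BLOCK,)], "F": np.nan,
                 "p": np.nan, "denominator": ""})
    for r in range(1, len(strata) + 1):
        for term in itertools.combinations(strata, r):
            name = _term_name(term)
            t = tuple(term)
            ss_t, df_t = ss[t], df_term[t]
            denom = denom_map[name]
            ms_d, df_d = strata_ssdf[denom][0] / strata_ssdf[denom][1], strata_ssdf[denom][1]
            ms_t = ss_t / df_t
            F = ms_t / ms_d if ms_d > 0 else np.inf
            p = float(stats.f.sf(F, df_t, df_d))
            rows.append({"source": name, "df": df_t, "SS": ss_t, "MS": ms_t,
                         "F": F, "p": p, "denominator": denom})
    for label, (s, d) in strata_ssdf.items():
        rows.append({"source": label, "df": d, "SS": s,
                     "MS": s / d if d else np.nan, "F": np.nan, "p": np.nan,
                     "denominator": ""})
    out = pd.DataFrame(rows)

    # observations averaged into each level mean of a main effect
    cell_means_n = {f: y.size // levels[f] for f in strata}
    return AnovaResult(table=out, strata=strata_ssdf,
                       cell_means_n=cell_means_n, data=sub)


def _insert_absorb(levels: list, sig_pairs: set[frozenset]) -> dict:
    """Compact letter display by the insert-and-absorb algorithm.

    Two levels share a letter iff their pair is NOT significantly different.
    """
    groups: list[set] = [set(levels)]
    for pair in sig_pairs:
        a, b = tuple(pair)
        new_groups = []
        for g in groups:
            if a in g and b in g:
                new_groups.append(g - {a})
                new_groups.append(g - {b})
            else:
                new_groups.append(g)
        # absorb subsets
        groups = []
        for g in sorted(new_groups, key=len, reverse=True):
            if not any(g < h or g == h for h in groups):
                groups.append(g)
    # stable letter order: by best (first) level appearance
    order = {lv: i for i, lv in enumerate(levels)}
    groups.sort(key=lambda g: min(order[lv] for lv in g))
    display = {lv: "" for lv in levels}
    for letter, g in zip(string.ascii_lowercase, groups):
        for lv in g:
            display[lv] += letter
    return {lv: "".join(sorted(s)) for lv, s in display.items()}


def letters(result: AnovaResult, factor: str, alpha: float = 0.05,
            adjust: str = "none") -> pd.DataFrame:
    """Compact letter display for a main effect's level means.

    Pairwise t comparisons use the factor's EMS denominator mean square and
    degrees of freedom (unadjusted LSD by default; ``adjust="bonferroni"``
    scales alpha by the number of pairs).  Levels sharing a letter are not
    significantly different at alpha.
    """
    if result.data is None:
        raise ValueError("AnovaResult carries no data")
    row = result.table[result.table["source"] == factor]
    if row.empty:
        raise ValueError(f"factor {factor!r} not in the ANOVA table")
    denom = row["denominator"].iloc[0]
    ms_err, df_err = result.stratum_ms(denom)

    means = result.data.groupby(factor, observed=True)["value"].mean()
    means = means.sort_values(ascending=False)
    n_per = result.cell_means_n[factor]
    se_diff = np.sqrt(2.0 * ms_err / n_per)

    pairs = list(itertools.combinations(means.index, 2))
    alpha_eff = alpha / len(pairs) if adjust == "bonferroni" else alpha
    sig = set()
    pvals = {}
    for a, b in pairs:
        t = abs(means[a] - means[b]) / se_diff
        p = 2.0 * float(stats.t.sf(t, df_err))
        pvals[frozenset((a, b))] = p
        if p < alpha_eff:
            sig.add(frozenset((a, b)))
    display = _insert_absorb(list(means.index), sig)
    return pd.DataFrame({
        "level": means.index,
        "mean": means.values,
        "letters": [display[lv] for lv in means.index],
    })
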
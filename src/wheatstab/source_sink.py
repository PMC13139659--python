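"""Source-sink partitioning of spike content at maturity.

Spike content at maturity (BBCH87) is supplied by three sources: the
pre-anthesis reserve already in the spike at flowering (BBCH61), net
remobilization from the straw between anthesis and maturity, and post-anthesis
assimilation.  The same arithmetic applies to dry matter, nitrogen and
water-soluble carbohydrates:

    pool_87_spike = pool_61_spike + remobilized_straw + post_anthesis

Remobilization is the straw's net loss, clipped at zero when the straw gains
mass after anthesis (the straw can act as a sink); post-anthesis assimilation
is then the balancing residual and may be negative under measurement noise,
in which case it is flagged rather than clipped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PoolQuartet",
    "PartitionResult",
    "remobilized",
    "partition_spike",
    "partition_table",
    "contribution_summary",
]


@dataclass(frozen=True)
class PoolQuartet:
    """One substance (DM, N or WSC) measured in spike and straw at BBCH61/87."""

    pool_61_spike: float
    pool_61_straw: float
    pool_87_spike: float
    pool_87_straw: float

    def __post_init__(self) -> None:
        for name in ("pool_61_spike", "pool_61_straw", "pool_87_spike", "pool_87_straw"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")


@dataclass(frozen=True)
class PartitionResult:
    """Decomposition of the spike pool at maturity into its three sources.

    Fractions are relative to ``pool_87_spike`` and are NaN when that pool is
    zero.  ``negative_post_flag`` marks plots where the post-anthesis residual
    came out negative (possible under measurement noise).
    """

    pre_anthesis_spike: float
    remobilized_straw: float
    post_anthesis: float
    pool_87_spike: float
    frac_pre: float
    frac_remobilized: float
    frac_post: float
    negative_post_flag: bool


def remobilized(pool_61_straw: float, pool_87_straw: float) -> float:
    """Net straw remobilization, clipped at zero when the straw gains mass."""
    if pool_61_straw < 0 or pool_87_straw < 0:
        raise ValueError("straw pools must be non-negative")
    return max(0.0, pool_61_straw - pool_87_straw)


def partition_spike(q: PoolQuartet) -> PartitionResult:
    """Partition the spike-at-maturity pool; the identity holds exactly.

    post_anthesis is computed as the residual pool_87_spike - pool_61_spike -
    remobilized, so pre + remobilized + post reproduces pool_87_spike to the
    last bit.
    """
    remob = remobilized(q.pool_61_straw, q.pool_87_straw)
    post = q.pool_87_spike - q.pool_61_spike - remob
    if q.pool_87_spike > 0:
        fp = q.pool_61_spike / q.pool_87_spike
        fr = remob / q.pool_87_spike
        fa = post / q.pool_87_spike
    else:
        fp = fr = fa = float("nan")
    return PartitionResult(
        pre_anthesis_spike=q.pool_61_spike,
        remobilized_straw=remob,
        post_anthesis=post,
        pool_87_spike=q.pool_87_spike,
        frac_pre=fp,
        frac_remobilized=fr,
        frac_post=fa,
        negative_post_flag=post < 0,
    )


# trait naming convention used in trial tables: <substance>_<stage>_<part>
_POOL_TRAITS = {
    "pool_61_spike": "{s}_61_spike",
    "pool_61_straw": "{s}_61_straw",
    "pool_87_spike": "{s}_87_spike",
    "pool_87_straw": "{s}_87_straw",
}


def partition_table(table: pd.DataFrame, substance: str = "DM",
                    key_cols: tuple = ("year", "block", "nitrogen_level",
                                       "application_time", "sowing_date",
                                       "genotype")) -> pd.DataFrame:
    """Partition every plot of a tidy trial table for one substance.

    Expects traits named ``<substance>_<61|87>_<spike|straw>``.  Returns one
    row per plot with the three components, fractions and the negative-post
    flag, keyed by the plot columns.
    """
    want = {k: t.format(s=substance) for k, t in _POOL_TRAITS.items()}
    sub = table[table["trait"].isin(want.values())]
    if sub.empty:
        raise ValueError(f"no pool traits found for substance {substance!r}")
    wide = sub.pivot_table(index=list(key_cols), columns="trait",
                           values="value", aggfunc="first")
    missing = [t for t in want.values() if t not in wide.columns]
    if missing:
        raise ValueError(f"missing pool trait(s): {missing}")
    rows = []
    for key, row in wide.iterrows():
        q = PoolQuartet(
            pool_61_spike=row[want["pool_61_spike"]],
            pool_61_straw=row[want["pool_61_straw"]],
            pool_87_spike=row[want["pool_87_spike"]],
            pool_87_straw=row[want["pool_87_straw"]],
        )
        res = partition_spike(q)
        rows.append(dict(zip(key_cols, key)) | {
            "pre_anthesis_spike": res.pre_anthesis_spike,
            "remobilized_straw": res.remobilized_straw,
            "post_anthesis": res.post_anthesis,
            "pool_87_spike": res.pool_87_spike,
            "frac_pre": res.frac_pre,
            "frac_remobilized": res.frac_remobilized,
            "frac_post": res.frac_post,
            "negative_post_flag": res.negative_post_flag,
        })
    return pd.DataFrame(rows)


def contribution_summary(parts: pd.DataFrame, grouping: list | None = None) -> pd.DataFrame:
    """Mean contribution fractions per group.

    Averages the per-observation fractions (not the ratio of pool means)
    within each group; with ``grouping=None`` a single overall row is
    returned.  Groups whose fractions are all missing yield NaN with a
    warning.
    """
    if parts.empty:
        raise ValueError("no partition results to summarise")
    cols = ["frac_pre", "frac_remobilized", "frac_post"]

    def agg(g: pd.DataFrame) -> pd.Series:
        out = g[cols].mean()
        if out.isna().all():
            warnings.warn("group has all-missing fractions", stacklevel=2)
        out["n"] = len(g)
        return out

    if grouping:
        res = parts.groupby(grouping, observed=True)[cols].apply(
            lambda g: agg(parts.loc[g.index])
        )
        if isinstance(res, pd.Series):  # single group edge case
            res = res.to_frame().T
        return res.reset_index()
    return agg(parts).to_frame().T
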
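"""Trial data model, CSV I/O, design validation, and two-way aggregation.

A trial table is a tidy, long-format plot-level record of a multi-environment
winter wheat experiment laid out as a split--split--split-plot design:
nitrogen level on the main plot, nitrogen application time on the split plot,
sowing date on the split--split plot, and genotype on the split--split--split
plot, replicated in blocks.  Every downstream stage (stability indices, ANOVA,
partitioning, phenotypic space) consumes either this table or the entity x
environment mean matrices derived from it here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KEY_COLUMNS",
    "DesignSpec",
    "TwoWayMatrix",
    "BalanceReport",
    "SchemaError",
    "IntegrityError",
    "MissingCellError",
    "read_trial_table",
    "write_trial_table",
    "validate_trial_table",
    "validate_design",
    "env_means",
]

#: Columns that uniquely key one plot-level observation of one trait.
KEY_COLUMNS = (
    "year",
    "block",
    "nitrogen_level",
    "application_time",
    "sowing_date",
    "genotype",
    "trait",
)

#: Management factors, in stratum order (main plot -> split -> split-split).
MANAGEMENT_FACTORS = ("nitrogen_level", "application_time", "sowing_date")


class SchemaError(ValueError):
    """A trial CSV does not match the expected column schema or factor levels."""


class IntegrityError(ValueError):
    """A trial table violates a structural invariant (duplicate keys, NaN keys)."""


class MissingCellError(ValueError):
    """A genotype x environment cell required for aggregation has no data."""


@dataclass(frozen=True)
class DesignSpec:
    """Factor levels of the four-stratum split-plot design.

    The stratum order is fixed by the field layout: nitrogen level is the main
    plot factor, application time the split, sowing date the split-split, and
    genotype the split-split-split factor.  ``n_blocks`` blocks replicate the
    whole arrangement.
    """

    genotypes: tuple[str, ...] = (
        "Akteur", "Alves", "Capone", "Esket",
        "Patras", "Pionier", "Potenzial", "Tobak",
    )
    years: tuple[int, ...] = (2020, 2021)
    nitrogen_levels: tuple[str, ...] = ("optimal", "suboptimal")
    application_times: tuple[str, ...] = ("split", "combined")
    sowing_dates: tuple[str, ...] = ("early", "late")
    n_blocks: int = 3
    expected_replicates: int = 1

    #: kg N / ha totals behind the categorical nitrogen levels.
    nitrogen_rates: Mapping[str, int] = field(
        default_factory=lambda: {"optimal": 220, "suboptimal": 176}
    )

    @property
    def blocks(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_blocks + 1))

    @property
    def managements(self) -> list[tuple[str, str, str]]:
        """All nitrogen x application-time x sowing-date combinations."""
        return [
            (n, a, s)
            for n in self.nitrogen_levels
            for a in self.application_times
            for s in self.sowing_dates
        ]

    def factor_levels(self) -> dict[str, tuple]:
        return {
            "year": self.years,
            "block": self.blocks,
            "nitrogen_level": self.nitrogen_levels,
            "application_time": self.application_times,
            "sowing_date": self.sowing_dates,
            "genotype": self.genotypes,
        }


@dataclass
class TwoWayMatrix:
    """Entity x environment mean-value matrix feeding the stability indices.

    ``perspective`` records which role the rows play: under the genotype
    perspective rows are genotypes and columns are year x management
    combinations; under the management perspective rows are management
    combinations and columns are year x genotype combinations.
    """

    values: pd.DataFrame
    perspective: str
    trait: str

    def __post_init__(self) -> None:
        if self.perspective not in ("genotype", "management"):
            raise ValueError(f"unknown perspective {self.perspective!r}")
        if self.values.isna().any().any():
            bad = [
                (r, c)
                for r in self.values.index
                for c in self.values.columns
                if pd.isna(self.values.loc[r, c])
            ]
            raise MissingCellError(f"missing cells in two-way matrix: {bad[:5]}")

    @property
    def entities(self) -> list:
        return list(self.values.index)

    @property
    def environments(self) -> list:
        return list(self.values.columns)

    @property
    def n_environments(self) -> int:
        return self.values.shape[1]


@dataclass
class BalanceReport:
    """Replicate census of every design cell."""

    balanced: bool
    expected: int
    deficient_cells: pd.DataFrame  # columns: key factors + observed count

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.balanced:
            return f"balanced design ({self.expected} replicate(s) per cell)"
        return (
            f"unbalanced design: {len(self.deficient_cells)} cell(s) deviate "
            f"from {self.expected} replicate(s)"
        )


def _check_columns(df: pd.DataFrame) -> None:
    missing = [c for c in (*KEY_COLUMNS, "value") if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table is missing column(s): {missing}")


def validate_trial_table(df: pd.DataFrame, spec: DesignSpec | None = None) -> pd.DataFrame:
    """Validate a tidy trial table; returns the typed table.

    Checks the column schema, key uniqueness, absence of NaN in key columns,
    and (when ``spec`` is given) that all factor levels are known.
    """
    _check_columns(df)
    df = df.copy()
    for col in KEY_COLUMNS:
        if df[col].isna().any():
            raise IntegrityError(f"NaN in key column {col!r}")
    df["year"] = df["year"].astype(int)
    df["block"] = df["block"].astype(int)
    df["value"] = df["value"].astype(float)

    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        first = df.loc[dup, list(KEY_COLUMNS)].iloc[0].to_dict()
        raise IntegrityError(f"duplicate observation key, e.g. {first}")

    if spec is not None:
        for col, levels in spec.factor_levels().items():
            if col == "year":
                continue  # year subsetting handled by callers
            unknown = set(df[col].unique()) - set(levels)
            if unknown:
                raise SchemaError(f"unknown level(s) {sorted(unknown)} in {col!r}")
    return df


def read_trial_table(path, spec: DesignSpec | None = None) -> pd.DataFrame:
    """Read and validate a trial table CSV (comma, UTF-8, '.' decimal, header)."""
    df = pd.read_csv(path)
    return validate_trial_table(df, spec)


def write_trial_table(df: pd.DataFrame, path) -> None:
    """Write a trial table CSV with 10 significant digits on the value column."""
    out = df.copy()
    out["value"] = out["value"].map(lambda v: f"{v:.10g}")
    out.to_csv(path, index=False)


def validate_design(table: pd.DataFrame, spec: DesignSpec,
                    trait: str | None = None) -> BalanceReport:
    """Census every design cell and report replicate deficits.

    Report-only: an unbalanced table is a finding, not an exception.  A cell is
    one (year, block, management, genotype, trait) combination; balanced means
    every cell holds exactly ``spec.expected_replicates`` observations.
    """
    _check_columns(table)
    if trait is not None:
        table = table[table["trait"] == trait]
    traits = sorted(table["trait"].unique()) if len(table) else ([trait] if trait else [])

    index = pd.MultiIndex.from_product(
        [spec.years, spec.blocks, spec.nitrogen_levels, spec.application_times,
         spec.sowing_dates, spec.genotypes, traits or [None]],
        names=list(KEY_COLUMNS),
    )
    if len(table):
        counts = table.groupby(list(KEY_COLUMNS), observed=True).size()
        counts = counts.reindex(index, fill_value=0)
    else:
        counts = pd.Series(0, index=index)
    bad = counts[counts != spec.expected_replicates]
    deficient = bad.rename("observed").reset_index()
    return BalanceReport(
        balanced=len(deficient) == 0,
        expected=spec.expected_replicates,
        deficient_cells=deficient,
    )


def _management_label(row) -> str:
    return f"{row['nitrogen_level']}/{row['application_time']}/{row['sowing_date']}"


def env_means(table: pd.DataFrame, trait: str, perspective: str = "genotype",
              years: Sequence[int] | None = None) -> TwoWayMatrix:
    """Aggregate plot observations into an entity x environment mean matrix.

    Block replicates are averaged first; the stability indices are defined on a
    single mean value per entity-environment cell.  Under the genotype
    perspective the environments are year x management combinations; under the
    management perspective they are year x genotype combinations, mirroring the
    symmetric dual treatment of the two stability viewpoints.
    """
    if perspective not in ("genotype", "management"):
        raise ValueError(f"unknown perspective {perspective!r}")
    _check_columns(table)
    sub = table[table["trait"] == trait].copy()
    if years is not None:
        sub = sub[sub["year"].isin(list(years))]
    if sub.empty:
        raise MissingCellError(f"no observations for trait {trait!r}")

    sub["management"] = sub.apply(_management_label, axis=1)
    cell = (
        sub.groupby(["year", "management", "genotype"], observed=True)["value"]
        .mean()
        .reset_index()
    )
    if perspective == "genotype":
        cell["environment"] = cell["year"].astype(str) + ":" + cell["management"]
        wide = cell.pivot(index="genotype", columns="environment", values="value")
    else:
        cell["environment"] = cell["year"].astype(str) + ":" + cell["genotype"]
        wide = cell.pivot(index="management", columns="environment", values="value")
    wide = wide.sort_index(axis=0).sort_index(axis=1)
    if wide.isna().any().any():
        missing = [
            (r, c) for r in wide.index for c in wide.columns
            if pd.isna(wide.loc[r, c])
        ]
        raise MissingCellError(
            f"trait {trait!r}: empty entity x environment cell(s), e.g. {missing[:3]}"
        )
    return TwoWayMatrix(values=wide, perspective=perspective, trait=trait)
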
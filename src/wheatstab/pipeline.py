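"""End-to-end orchestration: simulate/read -> validate -> derive -> analyse.

One RunConfig drives the whole analysis: trial data either comes from CSV
files or from the synthetic generator; stages run in dependency order
(validate -> phenology, partition -> stability, anova, phenospace); a stage
failure stops its dependents but independent stages still complete.  Every
written file is recorded in the run report with a content hash, so two runs
with the same seed can be compared manifest-to-manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import anova, phenology, phenospace, source_sink, stability, synthetic, trial_io

__all__ = ["RunConfig", "RunReport", "run", "load_config"]

log = logging.getLogger("wheatstab")

DEFAULT_STABILITY_TRAITS = ["GY", "GN", "TGW", "SN", "GpS", "GL", "GW"]
ALL_STAGES = ("simulate", "read", "validate", "phenology", "partition",
              "stability", "anova", "phenospace")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one data source)."""

    output_dir: str = "wheatstab_out"
    seed: int = 0
    trial_csv: str | None = None          # data source A: files
    simulate: bool = False                # data source B: generator
    years: list[int] | None = None
    stability_traits: list[str] = field(default_factory=lambda: list(DEFAULT_STABILITY_TRAITS))
    perspectives: list[str] = field(default_factory=lambda: ["genotype", "management"])
    anova_trait: str = "GY"
    phenospace_traits: list[str] = field(
        default_factory=lambda: list(phenospace.DEFAULT_PHENOSPACE_TRAITS))
    alpha: float = 0.05
    stages: list[str] = field(default_factory=lambda: [s for s in ALL_STAGES])

    def __post_init__(self) -> None:
        if self.simulate == (self.trial_csv is not None):
            raise ValueError("exactly one of trial_csv / simulate must be set")


@dataclass
class RunReport:
    """Stage statuses, row counts, balance summary and output manifest."""

    statuses: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)
    balanced: bool | None = None
    manifest: dict[str, str] = field(default_factory=dict)  # path -> sha256
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        """True when no stage errored and none was skipped for a failed dependency."""
        return not self.errors and not any(
            s.startswith("skipped (") for s in self.statuses.values()
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


def _write(df: pd.DataFrame, path: Path, report: RunReport) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    report.manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> RunReport:
    """Execute the requested stages in dependency order."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    spec = trial_io.DesignSpec()
    failed: set[str] = set()

    def stage(name: str, deps: tuple[str, ...] = ()):
        def wrap(fn):
            if name not in config.stages and name not in ("read", "simulate"):
                report.statuses[name] = "skipped"
                return None
            if any(d in failed for d in deps):
                report.statuses[name] = "skipped (dependency failed)"
                failed.add(name)
                return None
            try:
                result = fn()
                report.statuses[name] = "ok"
                log.info("[%s] ok", name)
                return result
            except Exception as exc:  # noqa: BLE001 - report, don't crash
                report.statuses[name] = "error"
                report.errors[name] = f"{type(exc).__name__}: {exc}"
                log.error("[%s] %s", name, exc)
                log.debug("%s", traceback.format_exc())
                failed.add(name)
                return None
        return wrap

    table = None
    truth = None
    sim_cfg = None
    if config.simulate:
        def _sim():
            nonlocal truth, sim_cfg
            sim_cfg = dataclasses.replace(synthetic.SimConfig(), seed=config.seed)
            t, truth = synthetic.simulate_trial(sim_cfg)
            _write(t, out / "trial_table.csv", report)
            return t
        table = stage("simulate")(_sim)
        report.statuses.setdefault("read", "skipped")
    else:
        def _read():
            return trial_io.read_trial_table(config.trial_csv, spec)
        table = stage("read")(_read)
        report.statuses.setdefault("simulate", "skipped")
    if table is None:
        failed.update({"simulate", "read"})
    else:
        report.row_counts["trial_table"] = len(table)
    src = "simulate" if config.simulate else "read"

    def _validate():
        traits = DEFAULT_STABILITY_TRAITS[:1]
        rep = trial_io.validate_design(table, spec, trait=traits[0])
        report.balanced = rep.balanced
        _write(rep.deficient_cells, out / "balance_deficits.csv", report)
        return rep
    stage("validate", (src,))(_validate)

    def _phenology():
        rows = []
        for yi, year in enumerate(spec.years):
            profile = dataclasses.replace(
                synthetic.WeatherProfile(), start=f"{year - 1}-10-15")
            weather = synthetic.simulate_weather(profile, seed=config.seed + yi)
            for geno, cp in synthetic.SimConfig().canopy_params().items():
                series = synthetic.simulate_canopy(
                    cp, weather, seed=config.seed + yi, noise_sd=0.02)
                fit = phenology.fit_senescence(series["tt"], series["gca"])
                gcd = phenology.green_canopy_duration(fit, cp.tt_anthesis)
                rows.append({"year": year, "genotype": geno,
                             "gca_max": fit.gca_max, "tt50": fit.tt50,
                             "k": fit.k, "sse": fit.sse,
                             "tt_anthesis": cp.tt_anthesis, "gcd": gcd})
        df = pd.DataFrame(rows)
        _write(df, out / "senescence_fits.csv", report)
        return df
    stage("phenology", (src,))(_phenology)

    def _partition():
        parts = source_sink.partition_table(table, substance="DM")
        summary = source_sink.contribution_summary(parts, grouping=["year"])
        overall = source_sink.contribution_summary(parts)
        _write(parts, out / "partition_DM.csv", report)
        _write(summary, out / "partition_DM_by_year.csv", report)
        _write(overall, out / "partition_DM_overall.csv", report)
        report.row_counts["partition_DM"] = len(parts)
        return parts
    stage("partition", (src,))(_partition)

    def _stability():
        frames = []
        for persp in config.perspectives:
            res = stability.stability_table(
                table, config.stability_traits, perspective=persp,
                years=config.years)
            frames.append(res)
            rc = stability.rank_correlation_matrix(res, index="P",
                                                   alpha=config.alpha)
            _write(rc.rho.reset_index(), out / f"rank_corr_P_{persp}.csv", report)
        res_all = pd.concat(frames, ignore_index=True)
        _write(res_all, out / "stability.csv", report)
        return res_all
    stage("stability", (src, "validate"))(_stability)

    def _anova():
        frames = []
        for year in sorted(table["year"].unique()):
            res = anova.fit_split3(table, config.anova_trait, year=int(year))
            tab = res.table.assign(year=year)
            frames.append(tab)
            lets = anova.letters(res, "genotype", alpha=config.alpha)
            _write(lets, out / f"letters_{config.anova_trait}_{year}.csv", report)
        df = pd.concat(frames, ignore_index=True)
        _write(df, out / f"anova_{config.anova_trait}.csv", report)
        return df
    stage("anova", (src, "validate"))(_anova)

    def _phenospace():
        sub = table[table["trait"].isin(config.phenospace_traits)]
        mat = sub.pivot_table(index="genotype", columns="trait",
                              values="value", aggfunc="mean")
        space = phenospace.pca_scaled(mat)
        scores = phenospace.project(space, mat)
        _write(space.loadings.reset_index(names="trait"),
               out / "phenospace_loadings.csv", report)
        _write(scores.reset_index(names="genotype"),
               out / "phenospace_scores.csv", report)
        _write(space.variance_fraction.rename("fraction").rename_axis("PC").reset_index(),
               out / "phenospace_variance.csv", report)
        return space
    stage("phenospace", (src,))(_phenospace)

    with open(out / "run_report.yml", "w") as fh:
        yaml.safe_dump(report.to_dict(), fh, sort_keys=True)
    return report
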
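"""Synthetic multi-environment winter wheat trial generator with known truth.

The generator emulates the study design every downstream stage expects:
8 genotypes x 2 years x 8 managements (2 nitrogen levels x 2 application
times x 2 sowing dates) x 3 blocks, with plot values built from a
Finlay--Wilkinson-style structure

    y = mu + g_i + b_i * e_j + eta_ij + block + eps,

where g_i are genotype main effects, e_j environment (year x management)
indices, b_i genotype sensitivity slopes (mean 1), eta_ij genotype-specific
interaction noise with SD sigma_GE[i], and block/eps nuisance terms.  G x E
is thus slope heterogeneity plus per-genotype interaction variance — the
simplest structure whose ground truth maps onto both the superiority and the
ecovalence index.

Secondary traits (yield components, stay-green and reserve traits) are linear
responses to the same latent with trait-specific baselines, loadings and
correlated residual noise.  Canopy senescence follows the logistic in thermal
time; source--sink pools are drawn so the partition identity holds by
construction, with PS1 (stay-green, straw accumulates WSC after anthesis) and
PS2 (early remobilization, straw WSC falls) genotype archetypes.

All randomness flows from one root seed through named child streams
(weather, yield, canopy, source_sink — spawned in that fixed order), so a
fixed (config, seed) pair reproduces every output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trial_io import DesignSpec

__all__ = [
    "WeatherProfile",
    "TraitSpec",
    "SimConfig",
    "SimTruth",
    "simulate_weather",
    "simulate_yield_components",
    "simulate_canopy",
    "simulate_source_sink",
    "simulate_trial",
]

YIELD_COMPONENT_TRAITS = ("GY", "GN", "TGW", "SN", "GpS", "GL", "GW")

#: Reference GY plot noise (t/ha); SimConfig.residual_sd rescales all trait
#: noise relative to this value.
_REF_RESIDUAL_SD = 0.25


@dataclass(frozen=True)
class WeatherProfile:
    """Statistical daily weather: seasonal sinusoid plus Gaussian noise."""

    start: str = "2019-10-15"        # sowing
    n_days: int = 340                # sowing -> maturity; season TT ~2800 degC d
    tmin_mean: float = 4.0           # degC
    tmax_mean: float = 12.0          # degC
    amplitude: float = 9.0           # seasonal half-range, degC
    peak_doy: int = 200              # day index of warmest day (mid-summer)
    noise_sd: float = 1.5            # degC, day-to-day
    precip_rate: float = 1.6         # mm/day mean of exponential draws


@dataclass(frozen=True)
class TraitSpec:
    """Linear response of one trait to the shared plot latent."""

    baseline: float   # trait units
    loading: float    # trait units per t/ha of latent
    noise_sd: float   # trait units


def _default_traits() -> dict[str, TraitSpec]:
    # baselines/loadings chosen once to sit in agronomically plausible ranges
    return {
        "GY": TraitSpec(0.0, 1.0, 0.25),            # t/ha (baseline folded into mu)
        "GN": TraitSpec(18.0, 1.5, 0.8),            # 1e6 grains/ha
        "TGW": TraitSpec(45.0, 0.8, 1.5),           # g
        "SN": TraitSpec(5.5, 0.4, 0.3),             # 1e6 spikes/ha
        "GpS": TraitSpec(30.0, 1.2, 1.5),           # grains per spike
        "GL": TraitSpec(6.5, 0.05, 0.08),           # mm
        "GW": TraitSpec(3.3, 0.03, 0.05),           # mm
        # stay-green / reserve traits used by the phenotypic space
        "GCD": TraitSpec(700.0, 22.0, 25.0),        # degC d
        "SPAD_61": TraitSpec(50.0, 1.2, 1.5),       # SPAD units
        "TT_71_77": TraitSpec(300.0, 12.0, 15.0),   # degC d
        "tiller_61": TraitSpec(6.2, 0.35, 0.4),     # 1e6 tillers/ha
        "WSC_conc_87_straw": TraitSpec(100.0, 9.0, 12.0),  # mg/g
    }


@dataclass(frozen=True)
class CanopyParams:
    """Per-genotype logistic senescence parameters."""

    tt_anthesis: float   # degC d at BBCH61
    tt50: float          # degC d at 50% GCA (within the observed 2086-2336 window)
    k: float             # senescence rate, per degC d
    gca_max: float = 1.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("senescence rate k must be positive")
        if self.tt50 <= self.tt_anthesis:
            raise ValueError("tt50 must exceed tt_anthesis")


@dataclass(frozen=True)
class SourceSinkTargets:
    """Mean pool magnitudes for the partition generator (t/ha for DM)."""

    spike_61: float = 1.9       # pre-anthesis spike reserve
    remobilized: float = 1.8    # straw -> spike net transfer
    post_anthesis: float = 5.3  # post-anthesis assimilation
    straw_61: float = 9.0
    rel_sd: float = 0.12        # lognormal-ish spread on each component
    p_wsc_gain_ps1: float = 0.85  # P(straw WSC rises after anthesis | PS1)
    p_wsc_gain_ps2: float = 0.15  # same for PS2
    wsc_61_straw: float = 110.0   # kg/ha scale pools for WSC
    n_61_straw: float = 60.0      # kg/ha scale pools for N


@dataclass(frozen=True)
class SimConfig:
    """Full generator configuration; defaults copy the study conditions."""

    design: DesignSpec = field(default_factory=DesignSpec)
    mu: float = 6.95                               # grand-mean grain yield, t/ha
    genotype_effects: tuple[float, ...] = (
        -0.45, -0.25, 0.55, -0.55, 0.30, 0.40, -0.20, 0.20)
    year_effects: dict[int, float] = field(
        default_factory=lambda: {2020: 0.73, 2021: -0.73})
    management_effects: tuple[float, ...] = (
        0.35, 0.20, 0.10, -0.05, 0.05, -0.10, -0.20, -0.35)
    sensitivity_slopes: tuple[float, ...] = (
        1.10, 0.95, 0.90, 1.20, 0.95, 0.90, 1.05, 0.95)
    sigma_ge: tuple[float, ...] = (
        0.10, 0.14, 0.08, 0.50, 0.12, 0.09, 0.35, 0.20)
    block_sd: float = 0.12
    residual_sd: float = 0.25
    trait_specs: dict[str, TraitSpec] = field(default_factory=_default_traits)
    trait_corr_rho: float = 0.2                    # exchangeable residual corr
    canopy: dict[str, CanopyParams] | None = None  # per genotype; default built
    canopy_noise_sd: float = 0.02                  # GCA fraction
    archetypes: tuple[str, ...] = (
        "PS1", "PS2", "PS1", "PS2", "PS2", "PS1", "PS2", "PS1")
    source_sink: SourceSinkTargets = field(default_factory=SourceSinkTargets)
    weather: WeatherProfile = field(default_factory=WeatherProfile)
    seed: int = 0

    def __post_init__(self) -> None:
        g = len(self.design.genotypes)
        for name in ("genotype_effects", "sensitivity_slopes", "sigma_ge",
                     "archetypes"):
            if len(getattr(self, name)) != g:
                raise ValueError(f"{name} must have {g} entries")
        if len(self.management_effects) != len(self.design.managements):
            raise ValueError("management_effects must match the management grid")
        if any(s < 0 for s in self.sigma_ge):
            raise ValueError("sigma_ge entries must be >= 0")
        if self.block_sd < 0 or self.residual_sd < 0:
            raise ValueError("SDs must be >= 0")
        if any(a not in ("PS1", "PS2") for a in self.archetypes):
            raise ValueError("archetypes must be PS1 or PS2")

    def canopy_params(self) -> dict[str, CanopyParams]:
        if self.canopy is not None:
            return self.canopy
        # TT50 spread across the observed senescence window
        tt50s = np.linspace(2100.0, 2330.0, len(self.design.genotypes))
        return {
            g: CanopyParams(tt_anthesis=1500.0 + 12.0 * i, tt50=float(t),
                            k=0.012, gca_max=1.0)
            for i, (g, t) in enumerate(zip(self.design.genotypes, tt50s))
        }


@dataclass
class SimTruth:
    """Realised generator latents retained for recovery tests."""

    genotype_effects: pd.Series
    environment_index: pd.Series          # per year:management label
    sensitivity_slopes: pd.Series
    sigma_ge: pd.Series
    interaction: pd.DataFrame             # genotype x environment eta draws
    block_effects: pd.DataFrame           # (year, block) effects
    gcd_true: pd.Series                   # per genotype, tt50 - tt_anthesis
    partition_truth: pd.DataFrame | None = None


def _streams(seed: int, n: int = 4) -> list[np.random.Generator]:
    """Child generators in fixed order: weather, yield, canopy, source_sink."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_weather(profile: WeatherProfile, seed: int | None = None,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Daily weather from sowing to maturity; tmax >= tmin on every row."""
    if rng is None:
        rng = _streams(seed if seed is not None else 0)[0]
    dates = pd.date_range(profile.start, periods=profile.n_days, freq="D")
    doy = dates.dayofyear.to_numpy()
    season = profile.amplitude * np.cos(2 * np.pi * (doy - profile.peak_doy) / 365.25)
    noise = rng.normal(0.0, profile.noise_sd, size=(2, profile.n_days))
    tmin = profile.tmin_mean + season + noise[0]
    tmax = profile.tmax_mean + season + noise[1]
    tmax = np.maximum(tmax, tmin)  # enforce physical ordering
    precip = rng.exponential(profile.precip_rate, size=profile.n_days) \
        if profile.precip_rate > 0 else np.zeros(profile.n_days)
    return pd.DataFrame({
        "date": dates.strftime("%Y-%m-%d"),
        "tmin_C": tmin,
        "tmax_C": tmax,
        "precip_mm": precip,
    })


def _trait_corr(names: list[str], rho: float) -> np.ndarray:
    k = len(names)
    R = np.full((k, k), rho)
    np.fill_diagonal(R, 1.0)
    # exchangeable matrices are PD iff rho > -1/(k-1)
    if np.linalg.eigvalsh(R).min() <= 0:
        raise ValueError("trait correlation matrix is not positive definite")
    return R


def simulate_yield_components(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Plot-level trial table for all traits, plus the realised ground truth."""
    rng = _streams(config.seed)[1]
    d = config.design
    genos = list(d.genotypes)
    env_labels = [f"{y}:{n}/{a}/{s}" for y in d.years for (n, a, s) in d.managements]
    e = np.array([
        config.year_effects[y] + m
        for y in d.years for m in config.management_effects
    ])
    g = np.asarray(config.genotype_effects)
    b = np.asarray(config.sensitivity_slopes)
    sig = np.asarray(config.sigma_ge)

    eta = rng.normal(0.0, 1.0, size=(len(genos), len(env_labels))) * sig[:, None]
    block_eff = rng.normal(0.0, config.block_sd,
                           size=(len(d.years), d.n_blocks))

    names = list(config.trait_specs)
    R = _trait_corr(names, config.trait_corr_rho)
    L = np.linalg.cholesky(R)
    specs = [config.trait_specs[t] for t in names]
    base = np.array([s.baseline for s in specs])
    lam = np.array([s.loading for s in specs])
    nsd = np.array([s.noise_sd for s in specs])
    # residual_sd rescales all trait noise relative to the reference GY noise,
    # so residual_sd = 0 silences every trait and GY's SD equals residual_sd
    noise_scale = config.residual_sd / _REF_RESIDUAL_SD

    rows = []
    for yi, year in enumerate(d.years):
        for mi, (nl, at, sd_) in enumerate(d.managements):
            j = yi * len(d.managements) + mi
            for gi, geno in enumerate(genos):
                latent_cell = g[gi] + b[gi] * e[j] + eta[gi, j]
                for bi in range(d.n_blocks):
                    latent = latent_cell + block_eff[yi, bi]
                    z = L @ rng.normal(size=len(names))
                    eps = noise_scale * nsd * z
                    vals = base + lam * latent + eps
                    # GY carries the grand mean itself
                    vals[names.index("GY")] += config.mu
                    for t, v in zip(names, vals):
                        rows.append((year, bi + 1, nl, at, sd_, geno, t, v))
    table = pd.DataFrame(rows, columns=[
        "year", "block", "nitrogen_level", "application_time", "sowing_date",
        "genotype", "trait", "value",
    ])
    cp = config.canopy_params()
    truth = SimTruth(
        genotype_effects=pd.Series(g, index=genos),
        environment_index=pd.Series(e, index=env_labels),
        sensitivity_slopes=pd.Series(b, index=genos),
        sigma_ge=pd.Series(sig, index=genos),
        interaction=pd.DataFrame(eta, index=genos, columns=env_labels),
        block_effects=pd.DataFrame(block_eff, index=list(d.years),
                                   columns=list(d.blocks)),
        gcd_true=pd.Series({gn: cp[gn].tt50 - cp[gn].tt_anthesis for gn in genos}),
    )
    return table, truth


def simulate_canopy(params: CanopyParams, weather: pd.DataFrame,
                    seed: int | None = None, noise_sd: float = 0.0,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Weekly (TT, GCA) observations of post-anthesis senescence.

    Thermal time is accumulated over the weather series (base 0 degC, daily
    clipping); GCA follows the declining logistic with optional Gaussian
    observation noise, floored at 0.
    """
    if rng is None:
        rng = _streams(seed if seed is not None else 0)[2]
    daily = np.clip((weather["tmin_C"].to_numpy()
                     + weather["tmax_C"].to_numpy()) / 2.0, 0.0, None)
    cum_tt = np.cumsum(daily)
    weekly_idx = np.arange(0, len(cum_tt), 7)
    tt = cum_tt[weekly_idx]
    tt = tt[tt > params.tt_anthesis]
    if len(tt) == 0:
        raise ValueError("weather series too short: no post-anthesis weeks")
    gca = params.gca_max / (1.0 + np.exp(params.k * (tt - params.tt50)))
    if noise_sd > 0:
        gca = np.clip(gca + rng.normal(0.0, noise_sd, size=len(gca)), 0.0, None)
    return pd.DataFrame({"tt": tt, "gca": gca})


def simulate_source_sink(archetype: str, targets: SourceSinkTargets,
                         n: int = 1, seed: int | None = None,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw DM/N/WSC pool quartets honouring the partition identity.

    DM components (pre-anthesis spike, remobilized, post-anthesis) are drawn
    around the configured targets and summed into the spike-at-maturity pool,
    so the identity is exact by construction.  The straw WSC trajectory
    follows the archetype: PS1 gains straw WSC after anthesis with probability
    ``p_wsc_gain_ps1``; PS2 with ``p_wsc_gain_ps2``.
    """
    if archetype not in ("PS1", "PS2"):
        raise ValueError("archetype must be PS1 or PS2")
    if rng is None:
        rng = _streams(seed if seed is not None else 0)[3]
    t = targets

    def draw(mean: float) -> np.ndarray:
        return np.clip(rng.normal(mean, t.rel_sd * mean, size=n), 0.0, None)

    rows: dict[str, np.ndarray] = {}
    # dry matter, t/ha
    pre = draw(t.spike_61)
    remob = draw(t.remobilized)
    post = draw(t.post_anthesis)
    straw61 = np.maximum(draw(t.straw_61), remob)  # cannot remobilize more than exists
    rows["DM_61_spike"] = pre
    rows["DM_61_straw"] = straw61
    rows["DM_87_spike"] = pre + remob + post
    rows["DM_87_straw"] = straw61 - remob

    # nitrogen, kg/ha: mostly remobilized from straw
    n_pre = draw(t.n_61_straw * 0.3)
    n_remob = draw(t.n_61_straw * 0.5)
    n_post = draw(t.n_61_straw * 0.4)
    n_straw61 = np.maximum(draw(t.n_61_straw), n_remob)
    rows["N_61_spike"] = n_pre
    rows["N_61_straw"] = n_straw61
    rows["N_87_spike"] = n_pre + n_remob + n_post
    rows["N_87_straw"] = n_straw61 - n_remob

    # WSC, kg/ha: direction of the straw pool set by the archetype
    p_gain = t.p_wsc_gain_ps1 if archetype == "PS1" else t.p_wsc_gain_ps2
    gain = rng.random(n) < p_gain
    w_straw61 = draw(t.wsc_61_straw)
    delta = draw(t.wsc_61_straw * 0.25)
    w_straw87 = np.where(gain, w_straw61 + delta, np.maximum(w_straw61 - delta, 0.0))
    w_remob = np.maximum(w_straw61 - w_straw87, 0.0)
    w_pre = draw(t.wsc_61_straw * 0.15)
    w_post = draw(t.wsc_61_straw * 0.35)
    rows["WSC_61_spike"] = w_pre
    rows["WSC_61_straw"] = w_straw61
    rows["WSC_87_spike"] = w_pre + w_remob + w_post
    rows["WSC_87_straw"] = w_straw87

    out = pd.DataFrame(rows)
    out.insert(0, "archetype", archetype)
    return out


def simulate_trial(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Full study simulation: yield components plus source--sink pool traits.

    Appends tidy rows for the twelve DM/N/WSC pool traits (one quartet per
    plot) to the yield-component table so partitioning, stability, ANOVA and
    phenospace all run from one table.
    """
    table, truth = simulate_yield_components(config)
    d = config.design
    rng = _streams(config.seed)[3]

    rows = []
    parts = []
    for year in d.years:
        for (nl, at, sd_) in d.managements:
            for gi, geno in enumerate(d.genotypes):
                pools = simulate_source_sink(
                    config.archetypes[gi], config.source_sink,
                    n=d.n_blocks, rng=rng,
                )
                for bi in range(d.n_blocks):
                    for col in pools.columns:
                        if col == "archetype":
                            continue
                        rows.append((year, bi + 1, nl, at, sd_, geno, col,
                                     float(pools[col].iloc[bi])))
                rec = pools.assign(year=year, nitrogen_level=nl,
                                   application_time=at, sowing_date=sd_,
                                   genotype=geno,
                                   block=np.arange(1, d.n_blocks + 1))
                parts.append(rec)
    pool_rows = pd.DataFrame(rows, columns=list(table.columns))
    truth.partition_truth = pd.concat(parts, ignore_index=True)
    return pd.concat([table, pool_rows], ignore_index=True), truth
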
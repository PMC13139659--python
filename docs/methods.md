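# Methods

## Study design and data model

The package targets a split–split–split-plot multi-environment trial:
nitrogen level (optimal 220 / sub-optimal 176 kg N ha⁻¹) on main plots
within blocks, nitrogen application time (split / combined) on split plots,
sowing date (early / late) on split–split plots, and genotype (8 winter
wheat cultivars) on split–split–split plots, with 3 blocks and 2 balanced
years. Observations live in a tidy long table keyed by
(year, block, nitrogen level, application time, sowing date, genotype,
trait); the key must be unique, key columns NaN-free, and factor levels
known. CSV I/O is comma-separated UTF-8 with '.' decimals and a mandatory
header; values are written with 10 significant digits, which round-trips
float64 to ~1e-10 relative.

**Environment definition.** For genotype-perspective stability an
"environment" is one year × management combination (16 with two years); for
management-perspective stability it is one year × genotype combination.
This symmetric treatment lets the same index code serve both viewpoints.

**Block means, not plot values.** Stability indices are computed on
block-averaged entity × environment means: the index definitions address a
single value per entity–environment cell. Missing cells are an error, never
imputed — the double-centering behind ecovalence requires a complete table.

## Stability indices

Superiority `P_i = Σ_j (X_ij − M_j)² / (2n)` (n = number of environments of
the matrix, 16 in the default configuration) and ecovalence
`W_i = Σ_j (X_ij − X̄_i − X̄_j + X̄)²`. Both are in squared trait units;
lower is more stable. `Σ_i W_i` equals the interaction sum of squares of the
two-way table, which the tests verify against a brute-force double loop.
Ranks use average ties. Spearman correlations between per-trait index
vectors use the t-approximation p-value by default; with ≤ 8 entities an
exact full-enumeration permutation p (all n! pairings) is available, since
the t approximation is rough at n = 8.

## Thermal time and canopy senescence

Daily thermal contribution is `max(0, (Tmin+Tmax)/2 − Tbase)` with
Tbase = 0 °C. Clipping at zero follows the standard growing-degree-day
convention; with a 0 °C base, winter days would otherwise subtract
development. BBCH stage dates observed on weekly visits are interpolated
linearly on the BBCH-versus-date line and rounded to whole days.

Post-anthesis green canopy area is fitted with
`GCA(TT) = GCA_max / (1 + exp(k(TT − TT50)))` by bounded least squares
(`scipy.optimize.curve_fit`): initial GCA_max = max observed, initial TT50 =
TT of the point nearest half-max, initial k = 4/TT-range, with k bounded to
(0, 1] per °Cd and GCA_max to (0, 1.2]. At least 4 points spanning the
decline are required; a rising series is rejected. Green canopy duration is
`GCD = TT50 − TT_anthesis`, with the 50% point taken relative to the fitted
asymptote rather than the first observation — this makes GCD invariant to
vertical scaling of the series and robust to a late first measurement.

## Source–sink partition

For each substance (DM t ha⁻¹; N, WSC kg ha⁻¹) the spike pool at maturity
decomposes into pre-anthesis spike reserve, net straw remobilization
`max(0, pool_61_straw − pool_87_straw)` (clipped at zero when the straw
gains mass — straw can act as a sink), and post-anthesis assimilation as the
exact residual. The residual may be negative under measurement noise; it is
flagged, not clipped, because only the straw term has a physical
non-negativity argument. Reconstruction drift is bounded by a few ulps of
the largest pool. Contribution summaries average *per-observation fractions*
(not ratios of means): "average across years, cultivars and managements"
is read as averaging observations.

## Split–split–split-plot ANOVA

Per-year model with blocks random and all treatment factors fixed. Sums of
squares come from the balanced-factorial inclusion–exclusion identity on
marginal totals (orthogonal, order-independent; verified against a type-I
OLS decomposition to 1e-9 relative). Error strata pool the block-interaction
terms of each treatment level: block×N (2 df) tests nitrogen; block×AT +
block×N×AT (4 df) tests application time and N×AT; the four block×SD terms
(8 df) test the sowing-date level; all eight block×genotype terms plus any
within-cell residual (112 df with one plot per cell) form the residual
stratum testing genotype and its interactions. Under the null with iid
normal errors every stratum's F test is exact, which the 2000-replicate
calibration confirms empirically (rejection rates within [0.040, 0.060] at
α = 0.05).

Compact letter displays use pairwise t comparisons with the factor's
stratum mean square and df, unadjusted LSD at α = 0.05 by default
(Bonferroni available); letters are assigned by insert-and-absorb, so two
levels share a letter iff their pairwise p ≥ α.

## Phenotypic space

PCA is computed on traits centered and scaled to unit SD (ddof = 1), i.e. on
the correlation structure. Default trait set: GCD, SPAD_61, TT_71_77, GN,
tiller_61, TGW, WSC concentration in straw at maturity; leaf-area-index and
light-interception traits are excluded by default as they add little
explained variance. Eigenvector signs are fixed by making each loading
vector's largest-magnitude element positive, so outputs are deterministic
across runs and platforms. Scores carry Cartesian quadrant labels
(I = +,+, counterclockwise). Per-group slope screening is ordinary least
squares on group-level means (managements weighted equally), two-sided
slope test, groups with < 3 points or zero x-variance skipped with a
warning.

## Synthetic trial generator

Plot values follow `y = μ + g_i + b_i·e_j + η_ij + block + ε` with genotype
main effects g_i, environment indices e_j = year effect + management
effect, sensitivity slopes b_i (mean 1), and genotype-specific interaction
noise η_ij ~ N(0, σ²_GE,i). G×E is therefore slope heterogeneity plus
per-genotype interaction variance — the simplest structure whose ground
truth maps onto both stability indices (σ²_GE drives ecovalence; g_i and
b_i drive superiority). Secondary traits are linear responses to the same
latent with trait-specific baselines, loadings, and residual noise drawn
from an exchangeable correlation matrix (ρ = 0.2 by default; positive
definiteness checked). `residual_sd` rescales all trait noise relative to
the reference grain-yield SD of 0.25 t ha⁻¹, so zeroing it makes the model
exactly additive.

Defaults copy the study conditions: 8 genotypes × 2 years × 8 managements ×
3 blocks; year effects ±0.73 t ha⁻¹ around μ = 6.95 t ha⁻¹ place the
simulated annual means near 7.68 (wet 2020) and 6.22 (dry 2021) t ha⁻¹;
source–sink pool targets (1.9 / 1.8 / 5.3 t ha⁻¹ for pre / remobilized /
post) put the overall contribution fractions near 21 / 20 / 59%; canopy
TT50 values span 2100–2330 °Cd, inside the observed 50%-senescence window,
with anthesis near 1500 °Cd. Genotype archetypes encode two physiological
strategies: PS1 (stay-green; straw WSC rises after anthesis with
probability 0.85) and PS2 (early remobilization; probability 0.15).

Weather is statistical, not meteorological: a seasonal sinusoid plus
Gaussian noise with tmax floored at tmin, exponential daily precipitation,
340 days from mid-October sowing (≈ 2800 °Cd, enough for the slowest
senescence to complete — shorter seasons truncate the logistic tail and
bias TT50 low). One root seed feeds named child streams (weather, yield,
canopy, source–sink — spawned in that order), so outputs are byte-identical
for a fixed (config, seed).

**What the generator does not emulate:** spatial field trends, weather-
driven trait responses (year effects are additive constants, not functions
of the simulated weather), measurement-protocol artefacts, and any
mechanistic crop growth. Passing tests therefore demonstrate correctness of
the *analysis arithmetic and its calibration under the stated stochastic
model*, not agreement with any particular field dataset.

## Problem sizes and numerical choices

The default simulated study (9216 trait rows) runs every stage in under a
second. The ANOVA calibration uses 2000 null replicates (standard error of
the empirical rate ≈ 0.005 at α = 0.05); the ecovalence recovery experiment
uses 5 seeds with a 10× σ_GE spread over 16 environments. The
balanced-factorial SS identity holds to ~1e-12 relative (cancellation in
the inclusion–exclusion of large uncorrected totals); tests assert 1e-9.
Logistic-fit convergence failures raise a dedicated error with the
offending series characteristics rather than returning garbage parameters.

## Known limitations

- Unbalanced METs are rejected, not modelled; there is no REML/mixed-model
  path and no missing-cell imputation.
- Only the two implemented stability indices; no Finlay–Wilkinson slope
  index, AMMI or GGE decompositions.
- Per-year ANOVA only; no across-year combined model.
- The exact-permutation Spearman p is O(n!) and restricted to n ≤ 8.
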
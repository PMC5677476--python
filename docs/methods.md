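# Methods

`plantspectrum` tests whether leaf, stem and fine-root economics traits of
woody species align along a single interspecific "fast–slow" axis, and
whether intraspecific trait responses to the environment can mask such an
axis when species are sampled across environments. This note records the
models, the numerical choices, and what the synthetic data generator does
and does not emulate.

## Traits and growth rates

Seven tissue traits are derived from raw organ measurements, one value per
individual, averaged (unweighted) to species level:

| trait | definition | units |
|---|---|---|
| LMA  | leaf dry mass / fresh one-sided area | g/m² |
| LDMC | leaf dry mass / fresh mass | fraction |
| LTD  | leaf dry mass / (area × thickness) | mg/mm³ |
| WD   | wood dry mass / fresh cylinder volume | mg/mm³ |
| WDMC | wood dry mass / fresh mass | fraction |
| RTD  | root dry mass / fresh volume | mg/mm³ |
| RDMC | root dry mass / fresh mass | fraction |

Wood fresh volume uses an elliptical cylinder from the two orthogonal
caliper diameters, V = π(a/2)(b/2)L; with equal diameters this is the
ordinary circular cylinder. Dry mass greater than fresh mass is rejected;
equality (dry-matter content exactly 1) is allowed with a warning.

Above-ground relative growth rate from two stem measurements is

    RGR = (ln(d₂²h₂) − ln(d₁²h₁)) / (t₂ − t₁)   [per year]

because d²h is a linear proxy for stem mass. RGR is antisymmetric under
swapping the time points and invariant to the unit of the diameters (they
cancel in the log ratio). Negative-growth records are filtered explicitly:
juvenile records are dropped when the d²h index shrinks, mature-tree
records when the diameter shrinks (heights of mature trees are typically
allometry-estimated, so the diameter is the reliable signal). Zero growth
is kept under both rules. A generic pluggable power law
`height = a·d^b·elevation_adj` stands in for published species-specific
diameter–height allometries; coefficients must be supplied by the caller
and there is deliberately no default table.

Per species we report mean RGR and RGR95, the 95th percentile across
individuals (linear interpolation between order statistics — the common
default in scientific software; no percentile method is canonical here).
RGR95 estimates the maximum realized growth rate and discounts individuals
suppressed by neighborhood competition; with one-sided suppression it sits
well above the mean (roughly double under the generator defaults below).

Interspecific vs intraspecific variance fractions come from a one-way
random-effects ANOVA with the unbalanced-design coefficient
n₀ = (N − Σnᵢ²/N)/(k − 1); the between-species variance is truncated at
zero so the reported fraction lies in [0, 1].

## Phylogenetic comparative machinery

Species are non-independent samples; all cross-species analyses are
tree-corrected assuming Brownian motion, under which trait values are
multivariate normal with covariance proportional to C, where
C[i,j] is the root-to-MRCA path length shared by tips i and j.

*Independent contrasts* follow the pruning algorithm: at each internal
node the contrast (x₁−x₂)/√(b₁+b₂) is standardized by its expected
variance; the node receives the precision-weighted average value and its
parent branch is extended by b₁b₂/(b₁+b₂). Polytomies are resolved to
zero-length bifurcations at parse time (the zero-length contrasts this
creates are well-defined as long as the sister branches do not both vanish;
two zero-length sister branches raise an error rather than being patched
with an epsilon, since no convention for that case is established).

*Phylogenetic PCA* estimates the GLS root state a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X and
the evolutionary covariance R = (X−1a)ᵀC⁻¹(X−1a)/(n−1), standardizes R to
a correlation matrix (the default; covariance mode is available), and
eigendecomposes it. Scores are the GLS-centered, SD-standardized data
projected on the eigenvectors, so they have exactly zero GLS mean.
Eigenvector signs are fixed so the largest-magnitude loading is positive,
which makes reports platform-deterministic. Eigenvalues in [−1e-10, 0) are
clipped to zero; anything more negative is an error. Two identities anchor
the implementation and are enforced in tests: on a star tree with equal
depths the procedure reduces exactly to ordinary correlation PCA, and the
through-origin correlation of contrasts equals the GLS evolutionary
correlation to machine precision.

The *phenotypic integration index* is the variance of the
correlation-matrix eigenvalues, Var(λ) = Σ(λᵢ−1)²/N: 0 when traits are
mutually uncorrelated, N−1 when one axis absorbs everything. For an
equicorrelation matrix the closed form is (N−1)ρ². *Dimensionality* is
Kaiser's rule, the number of eigenvalues strictly greater than 1 (1 is the
mean eigenvalue of a correlation matrix; an eigenvalue of exactly 1 does
not count).

## Bivariate statistics

Trait allometry uses standardized major axis (SMA) regression, which
treats x and y symmetrically: slope = sign(r)·s_y/s_x. Because the SMA
slope magnitude does not shrink toward zero for uncorrelated data, the
significance of a relationship is the two-tailed test of r = 0
(t = r√((n−2)/(1−r²))). Contrast regressions are forced through the origin
with positivized x-contrasts (the standard convention; |r| and |slope| are
invariant to the sign flips), with n−1 degrees of freedom since no
intercept is estimated. A relationship is reported as robust only when
both the raw and the contrast regressions are significant at α = 0.05.

Paired greenhouse-vs-field trait changes use the Wilcoxon signed-rank
test. Zero differences are dropped (the classic treatment; alternatives
exist and this choice is therefore documented), tied absolute differences
get average ranks. For n ≤ 25 the two-tailed p-value is exact: the null
distribution of the rank sum over all 2ⁿ sign patterns is built by dynamic
programming over doubled (hence integer) ranks, which is algebraically
identical to full enumeration. Above 25 a normal approximation with
continuity and tie corrections is used; the two agree to better than 0.01
at the boundary.

## Meta-analysis of site-level correlations

Wild growth rates are measured across sites differing in climate and
composition. Per site (≥ 4 species, otherwise excluded with a logged
reason) a Pearson correlation between a trait and RGR or RGR95 is Fisher
z-transformed (variance 1/(n−3)) and pooled across sites with site as a
random effect via the DerSimonian–Laird estimator:
Q = Σwᵢ(zᵢ−z̄)², τ² = max(0, (Q−(k−1))/(Σw−Σw²/Σw)), random weights
1/(vᵢ+τ²). DL is the conventional default of correlation meta-analysis
tools; with τ² = 0 it reduces exactly to the fixed-effect inverse-variance
pool. A within-site |r| numerically equal to 1 is nudged to ±0.9999 with a
warning rather than dropped.

## Environment-mixing resampling null

For a trait pair, B datasets (default 10,000) are simulated in which each
species contributes its pair of values from either the greenhouse or the
field table with probability ½ — one coin per species per replicate
governing both traits, because a species' phenotype comes from one
environment. The observed R² in the standardized (greenhouse) environment
is located in the simulated R² distribution with the ≤ tie rule, so an
observed value above every replicate has position 1.0. A position ≥ 0.95
("exceeds the 95th quantile") indicates that mixed-environment sampling
weakens the pair's correlation. When the two tables are identical the
distribution is degenerate and the flag is forced off. An
independent-coin-per-trait mode exists for sensitivity analysis only.

The criterion is calibrated: when the two environments are exchangeable
(both equal to the same species means plus independent equal-variance
noise), the all-greenhouse dataset is just one more corner of the mixture
space, so the exceed probability is ~5% by construction — the acceptance
checks verify ≈5% empirically.

## Synthetic data generator

The generator emulates the structure of a two-environment trait/growth
study of ~56 woody species so that every stage runs with no external data.
Defaults (chosen once):

- **Tree**: pure-birth (Yule), strictly bifurcating, ultrametric, rescaled
  to unit depth. 56 species.
- **Traits**: correlated Brownian motion; tip values are matrix-normal
  with row covariance C and column covariance DRD (vec-covariance
  kron(DRD, C)). Default cross-trait correlation: equicorrelation 0.7, a
  strong but imperfect single axis. Root states and tip SDs (LMA 180 ± 30
  g/m², LTD 0.35 ± 0.07, LDMC 0.35 ± 0.06, WD 0.55 ± 0.10, WDMC 0.45 ±
  0.08, RTD 0.25 ± 0.05, RDMC 0.25 ± 0.05) keep simulated ranges inside
  published global trait ranges (e.g. WD ≈ 0.25–0.85 mg/mm³) and keep all
  species means positive by construction (root ≥ 5 SD).
- **Environment shifts**: per-species greenhouse→field displacement
  Normal(mean, sd) per trait. Defaults emulate the shade response:
  LMA −30 g/m² (≈ −1 interspecific SD), WD +0.10 and RTD +0.05 (≈ +1 SD),
  between-species shift SD 0.25 SD — divergent for (LMA, WD) and
  (LMA, RTD), convergent for (WD, RTD).
- **Individuals**: 8 greenhouse and 3 field replicates per species
  (within typical study ranges), multiplicative lognormal measurement
  noise with CV 0.15 (no published error magnitudes exist; this is a free
  choice). Raw organ measurements are back-constructed from noisy trait
  targets (fixed leaf area 25 cm², wood segment 20 × 4 mm, root volume
  100 mm³) so that the derivation code recovers the targets exactly —
  trait derivation is exercised end-to-end, and cv = 0 round-trips to
  machine precision.
- **Growth**: true RGR = 1.0 − 0.3 × (standardized composite of LMA, WD,
  RTD z-scores), i.e. resource-conservative species grow slower. Final
  stem dimensions are solved from the RGR equation (d₂ = d₁e^{rΔt/3},
  h₂ = h₁e^{rΔt/3}), so recomputing RGR returns the injected value
  exactly. Greenhouse: Δt = 0.31 yr, no suppression. Field: 3 sites,
  species occupancy 0.6, 8 individuals per species-site, Δt ~ U(1, 3) yr,
  and a one-sided half-normal suppression (SD 0.6 on the log-growth scale)
  that can only lower growth — which is what justifies RGR95 as a
  maximum-realized-growth filter and yields RGR95/mean ≈ 1.9 in the field.

Every generator is bit-reproducible for a fixed seed; a study bundle
written to disk (Newick with 17-significant-digit branch lengths, CSVs
parsed with round-trip float precision) reproduces the in-memory pipeline
results exactly.

**What the generator does not emulate**: climate/soil covariates,
ontogenetic drift within individuals, site-structured trait variation
(traits shift by environment, not by site), deciduousness classes, and
non-Brownian evolution (no Ornstein–Uhlenbeck or λ transforms). Passing
tests therefore show that the statistical machinery recovers the
structures this model can generate, not that real communities behave this
way.

### Measurement error and the GLS metric

One behaviour worth knowing: replicate measurement error is iid across
species, not tree-structured, so phylogenetic correction amplifies it —
contrasts across short sister branches divide a noise-dominated difference
by a small expected variance. With the default CV of 0.15 the evolutionary
correlation of a strongly integrated trait set is noticeably attenuated
and the apparent Kaiser dimensionality can rise above 1 even when the
generating process is one-dimensional. The end-to-end demonstration of the
single-axis pattern therefore uses a low-noise scenario (CV 0.02,
evolutionary correlation 0.9), mirroring the role of precise standardized
measurement protocols; the dimensionality-recovery checks operate on the
species means directly. This attenuation is a property of comparative
methods generally, not an artifact of this implementation.

## Problem sizes

Monte-Carlo checks use 100 seeded replicates per claim; the resampling
null uses B = 1,000 inside rate estimates and B = 10,000 in single runs,
matching the method's published replicate count. The full default pipeline
(56 species, 3 field sites, B = 10,000 × 3 trait pairs) runs in a few
seconds.

## Known limitations

- No confidence intervals on SMA slopes (not needed by any consumer here).
- REML as an alternative to DerSimonian–Laird is exposed only as a future
  hook; DL is the sole estimator implemented.
- Whether traits should be log-transformed before analysis is left to the
  caller (`log_traits`); the default is untransformed.
- The mature-tree environment is supported in the measurement and
  filtering layers but the synthetic generator produces only cultivated
  and wild-juvenile data.
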
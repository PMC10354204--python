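# Methods

This note documents the models implemented in `predscale`, the defaults and
why they were chosen, the numerical details, and what the synthetic-data
generators do and do not emulate.

## Phylogenetic generalized least squares (`phylocomp`)

### Model

For `n` species on a rooted, time-calibrated phylogeny, the regression of
log₁₀ maximum prey mass `y` on log₁₀ predator mass `x` is

    y = b0 + b1 x + e,     e ~ MVN(0, sigma2 * V(theta)),

where `V` is built from the shared-time matrix `C`
(`C[i,j]` = time from the root to the most recent common ancestor of tips
`i` and `j`; `C[i,i]` = depth of tip `i`):

| structure | V | parameter, domain |
|---|---|---|
| BM | `V = C` | — |
| Pagel's λ | off-diagonals `λ·C[i,j]`, diagonal unchanged | `λ ∈ [0, 1]` |
| OU | `V[i,j] = exp(−α·d[i,j])`, `d` patristic distance, unit diagonal | `α > 0` |
| ACDC | `V[i,j] = (exp(g·C[i,j]) − 1)/g`, rescaled so max diag = tree depth | `g` fixed, default 0.5 |

The OU form is the `corMartins`-style correlation convention (exponential
decay on tip-to-tip distance with unit diagonal), not the stationary-OU
integral; this matches the R comparative-methods toolchain the field uses
for these fits. The ACDC form is the accumulated variance of a process
whose rate changes as `e^(g·t)`; it is continuously extended to `C` as
`g → 0`, and the rescaling keeps its overall scale comparable to BM so
that `sigma2` means the same thing across structures. `g` is not profiled:
with both `g` and `sigma2` free the likelihood is very weakly identified
at these sample sizes, so `g` is a fixed model choice, like the exponent
choice in any named transformation.

### Estimation

All fits are maximum likelihood (not REML). ML makes AIC comparable across
covariance structures with identical fixed effects; REML likelihoods are
only comparable at fixed fixed-effects design. For fixed `theta`, `b` and
`sigma2` have closed forms via a Cholesky whitening of `V`; `λ` or `α` is
then profiled by bounded Brent search (`λ ∈ [1e−6, 1]`,
`α ∈ [1e−6, 50/depth]`, relative tolerance 1e−8). AIC counts
`k = 3` (intercept, slope, `sigma2`) for BM and fixed-`g` ACDC and `k = 4`
for OU and λ. Ties in the AIC ranking keep input order.

The implementation is cross-checked in the test suite against (a) a dense
multivariate-normal log-density oracle on random instances (agreement to
1e−8) and (b) frozen coefficients/log-likelihood from an independent
R `nlme::gls` + `ape::corPagel` fit on a fixed 5-taxon fixture (agreement
to 1e−8).

Known property: ML estimates of the structure parameter are finite-sample
biased even when the likelihood is exact — at `n = 200` the mean of
`λ̂` sits about 0.02 below a true λ of 0.7, and `α̂` runs roughly 15% high.
Slope and intercept are unbiased to Monte-Carlo precision. The recovery
tests therefore hold slope/intercept to two Monte-Carlo standard errors
but the structure parameter to an absolute band (±0.15 for λ), which is
the resolution at which these parameters are scientifically interpreted.

### Outlier screening

Rosner's generalized extreme studentized deviate test, applied per stratum
to the response (log₁₀ maximum prey mass) before fitting, with defaults
`k_max = 3`, `α = 0.05`, and a floor of `n ≥ 10`. The per-step critical
values use the t-distribution approximation; the implementation reproduces
the published n = 54, k = 10 reference example exactly, and its empirical
null rejection rate at n = 50 is ≈ 6%, the documented mild liberality of
the approximation at moderate n. Screening the response (rather than raw
masses or residuals) is a package choice: the screen must not depend on
the model being selected afterwards.

### Intervals

At a new predictor value `x0`, with `v0 = (1, x0)` and
`A = (XᵀV⁻¹X)⁻¹`:

    CI half-width = t_{n−2} · sqrt(sigma2 · v0ᵀ A v0)
    PI half-width = t_{n−2} · sqrt(sigma2 · (1 + v0ᵀ A v0))

The new point is treated as phylogenetically independent of the tree
(variance `sigma2`, no covariance with fitted tips). That is the right
treatment for a fossil taxon far outside the sampled clade; for a point
inside the clade it understates the covariance and widens the PI slightly.
Empirical new-observation coverage at nominal 95% is ≈ 93% at `n = 64`
(the profiled structure parameter's estimation error is not propagated,
and ML `sigma2` is slightly small); the tests assert the [92%, 98%] band.

## Mass and age (`massage`)

Scaling equations live in `data/equations.json` (slope, intercept, input
measurement, output unit, percent prediction error), never in code, so the
registry can be extended without touching logic. Shipped equations: the
bipedal femoral-circumference relation
(log₁₀ mass[g] = 2.749·log₁₀ C[mm] − 0.683, PPE 25.6%) and the quadrupedal
combined stylopodial relation
(log₁₀ mass[g] = 2.754·log₁₀(C_h+C_f)[mm] − 1.097, PPE 25.6%). Outputs are
converted to kg at the registry boundary. Error bands are symmetric
(mass × PPE) and propagate multiplicatively through DME — the ± band is a
relative error, so it scales with the point estimate.

Developmental mass extrapolation multiplies a somatically mature
reference mass by `k³` for a linear ratio `k`, assuming isometry. The age
line (years = 0.0615·femur[mm] − 1.9214) is valid only above its zero-age
root at 31.24 mm; calls below it are a domain error rather than a negative
age.

## Community reconstruction (`community`)

Counts retro-calculated from published percentages use largest-remainder
rounding so they sum to the published tally exactly. The taphonomic
correction multiplies each species' count by
`N/S = 10^(1.96 − 0.45·log₁₀ W)` and renormalises; it is scale-free in the
counts, and species of equal mass keep their raw shares.

Rarefaction uses the exact hypergeometric expectation with log-gamma
combinatorics (overflow-free at any census size). The variance is
*unconditional* — it treats the census itself as a sample from a richer
assemblage rather than as the complete universe. With detection
probability `p_i = 1 − C(N−N_i, n)/C(N, n)` and an estimated assemblage
richness `S~` (bias-corrected Chao1 from the counts),

    var(S_n) = Σ p_i² − (Σ p_i)² / S~ ,

which is nonnegative (Cauchy–Schwarz with `S~ ≥ S_obs`) and remains
positive at `n = N` whenever Chao1 exceeds observed richness, so the 95%
band does not pinch to zero at the full census — the defining behaviour of
an unconditional estimator. The expectation is verified against both a
20,000-draw resampling oracle and frozen values from R `vegan::rarefy`.

Biomass shares multiply corrected abundance by per-capita mass and
renormalise; the pyramid reports per-species, per-trophic-level, and
within-level percentages, each summing to 100 within 1e−9. Trophic levels
are input data, never inferred. Taxa known only from teeth are included by
default (large-bodied animals dominate standing biomass even at tiny
counts) and can be excluded with a flag for sensitivity runs.

## Clast morphometrics (`clasts`)

The three printed formulas only: Wadell roundness (mean corner-radius to
inscribed-radius ratio), Krumbein–Sloss sphericity (`D_min/D_max`), mean
cross-sectional size. Inputs are measured radii and dimensions in CSV;
corner detection/digitisation is out of scope. Both shape indices are
dimensionless and scale-invariant, which the tests assert to 1e−12.
Colour and composition labels group case-insensitively. The
matrix:framework ratio comes from user-supplied mapped areas, normalised
to sum to 100.

## Synthetic data (`synthdata`)

Every generator is a pure function of its arguments and seed (NumPy
`default_rng`); identical configs give byte-identical files.

- **Trees**: pure-birth (Yule) with Exp(k) waiting times, rescaled to unit
  depth, tips labelled in preorder. Real carnivoran trees are neither Yule
  nor error-free, but only the shared-time geometry matters to PGLS, and a
  Yule tree exercises the same range of nested covariances.
- **Traits**: defaults are the study conditions — 64 solitary + 12 pack
  species, masses log-uniform over 0.1–500 kg, slope 1.0, intercept 0.3,
  residuals MVN under Pagel's λ = 0.7 with scale 0.5 log₁₀ units (R² ≈ 0.8
  over that mass range, typical of carnivoran max-prey regressions). The
  λ = 0.7 default makes the AIC self-consistency experiment meaningful:
  strictly nested alternatives (BM at λ=1, independence at λ=0) are both
  wrong.
- **Census**: the packaged fixed table has 1522 individuals, a dominant
  small ornithischian at 90.0% raw abundance, masses 0.01–1000 kg, one
  teeth-only large-bodied taxon, and both consumer levels; all species and
  numbers are synthetic. The stochastic generator inverts the taphonomic
  correction (skeleton share ∝ true share / (N/S)) and draws multinomially,
  so correction recovers the true shares on large censuses — the
  round-trip the tests assert.
- **Clasts**: class-specific lognormal sizes matching the thin-section
  characterization (lithic mean 0.46 mm, mineral 0.11 mm, lithic fraction
  165/373), Beta(5,2) sphericity, Beta(2,3) roundness (an angular,
  poorly rounded assemblage), 3–8 corners with radii jittered around the
  target roundness so their mean reproduces it exactly.

What passing tests on synthetic data do **not** show: that any particular
empirical dataset satisfies the model assumptions (Yule-like tree shape,
homoscedastic log-scale residuals, the Amboseli N/S calibration's
transferability to an obrution deposit, lognormal clast sizes). They show
the estimators recover known truth when the assumptions hold, and that the
deterministic arithmetic matches independent oracles.

## Problem sizes and numerical choices

Simulation-based tests use: 100 random instances (n ≤ 12) for the
likelihood oracle; 200 replicates at n = 200 for parameter recovery;
1,000 replicates at n = 64 for PI coverage; 50 replicates at n = 150 for
AIC self-consistency; 500 null replicates at n = 50 for the outlier
screen; 20,000 resamples for the rarefaction oracle — sizes at which
Monte-Carlo error is well below the tolerances being asserted. Cholesky
factorisations add a 1e−12 diagonal jitter only where simulation requires
a factor of a possibly semidefinite matrix; model fitting itself treats a
failed factorisation as an infinite-negative-likelihood point during
profiling and a hard error at the optimum. CSV round-trips write floats
via `repr` and read with round-trip precision, so record equality is
exact.

## Known limitations

- Single predictor only; no multi-predictor PGLS, no measurement-error
  models, no phylogenetic signal tests.
- The OU structure assumes an ultrametric-like correlation decay; on very
  non-ultrametric trees the unit-diagonal convention and the
  integral-form OU diverge.
- The unconditional rarefaction variance depends on Chao1, which is itself
  noisy on small censuses; the band is approximate (normal quantiles).
- DME assumes strict isometry; real ontogenies deviate.
- The equation registry ships only the two circumference allometries used
  by the headline estimates; tooth-area and other mammal equations can be
  added as JSON without code changes.
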
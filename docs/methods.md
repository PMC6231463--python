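# Methods

This note documents the statistical models, the synthetic-data
generator, and the numerical and design choices behind `landgen`.

## Genetic summaries

Genotypes are diploid microsatellite calls; a locus call is either both
alleles present or fully missing (half-missing calls are coerced to
missing on input, the conservative reading for noninvasive data).
Individual identification collapses repeat samples whose genotypes agree
on all co-typed loci up to a mismatch budget; a missing locus is never a
mismatch, grouping is the transitive closure of pairwise matches, and
each group keeps its most completely typed sample (ties: input order).

- Observed heterozygosity H_O is the fraction of typed individuals
  heterozygous at the locus; expected heterozygosity uses Nei's
  small-sample correction H_E = (2n/(2n−1))(1 − Σp²) (the uncorrected
  form is a flag). Means over loci are unweighted.
- P(ID) per locus is Σp⁴ + Σ_{i<j}(2pᵢpⱼ)², and for full sibs
  0.25 + 0.5Σp² + 0.5(Σp²)² − 0.25Σp⁴; multilocus values multiply across
  loci (linkage equilibrium assumed). Both match exhaustive
  genotype-pair enumeration to 1e−12 (tested).
- D_ps = 1 − PSA, where PSA averages, over co-typed loci, the number of
  shared alleles counted with multiplicity divided by 2. Averaging is
  per-locus (not pooled counts), following the convention of the
  software that popularized the distance.

## Resistance surfaces

Each landscape variable maps to resistance ≥ 1 through a registered
transform: circular-deviation power for aspect, Gaussian suitability for
elevation (optimum, SD in metres), min–max-rescaled power for continuous
variables (TC, slope), and class lookup for categorical layers. All
transforms satisfy R(optimum) = 1 and R ≤ R_max, and are monotone in
their deviation variable (property-tested). Multivariate surfaces are
cell-wise sums floored at 1; the alternative literal reading — summing
pairwise resistance *matrices* instead of surfaces — is available via
`combine="matrix"` in the causal engine, since either reading is
defensible; the surface sum is the default because it also yields the
combined map needed for current-density work.

Topographic complexity (TC) is the standard deviation of elevation in a
square window (default 3×3), computed over the available in-grid cells
(population SD). Slope and aspect use Horn's third-order finite
differences on the 3×3 neighbourhood; aspect is the compass bearing of
the steepest-ascent direction and is nodata on flat cells. In aspect
resistance, flat/nodata cells take the surface's median resistance (a
level cell carries no directional information).

## Circuit theory

A resistance surface becomes an undirected resistor network: valid cells
are nodes; 4- or 8-neighbour adjacency; edge resistance is the mean of
the two cell resistances, scaled by √2 for diagonal neighbours (the
average-resistance convention of the standard connectivity software).
Effective resistance comes from LU-factorized solves of the reduced
Laplacian (one ground node); for k focal points all pairwise resistances
use one factorization and k−1 solves through the Green's-function
identity R_ab = G_aa + G_bb − G_ab − G_ba. Focal points snap to cell
centres; points in one cell collapse to one node (distance 0 among
them). Solutions match the Moore–Penrose pseudo-inverse oracle to 1e−8
on random grids and obey Kirchhoff conservation and Rayleigh
monotonicity (tested). Current maps report, per cell, half the sum of
absolute currents on incident edges at unit injection, with terminal
cells reporting the injected current, summed over focal pairs.

## Mantel machinery

Mantel r is the Pearson correlation over the n(n−1)/2 unordered pairs;
the permutation null relabels individuals (simultaneous row/column
permutation), and p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1), one-tailed
positive by default to match the directional resistance hypotheses
(two-tailed by flag). The partial Mantel statistic is the partial
correlation of the condensed matrices, computed as the correlation of
OLS residuals on the conditioning matrix; permutation follows the
residuals-of-A scheme (permute the residual matrix of A|C, recompute).
An exactly constant conditioner degenerates gracefully to the simple
test; a conditioner collinear with B raises. Rejection under the null is
calibrated at the nominal 5% over 500 replicates and p-values are
uniform by KS (tested).

The spatial autocorrelogram is the multivariate (all-loci) form:
Gower-center the element-wise squared genetic distance matrix to get a
pair covariance matrix C, then for distance class h

  r_h = mean of C_ij over pairs in h / mean of C_ii over individuals in those pairs.

This count-normalized ratio lies in [−1, 1] with null expectation
−1/(n−1). The null envelope permutes individual locations; the CI
bootstraps pairs within class. The default class width of 1900 m is the
radius of a typical giant-panda home range — the scale at which local
genetic structure is expected. Sex-stratified runs use shared settings;
a sex absent from the data maps to `None`, fewer than 3 individuals is
an error.

## Causal modelling

A landscape model LR beats the uniform-surface IBD null when
(a) GD~LR|IBD is significant and (b) GD~IBD|LR is not, at α = 0.05
throughout (the framework reports raw p-values; no multiplicity
correction is applied, which is a known caveat of the approach).
Relative support RS_1|2 = r(GD~LR₁|LR₂) − r(GD~LR₂|LR₁) compares
competing models; the per-variable champion is the candidate that wins
the RS round robin among that variable's Mantel-significant
parameterizations (restricted to criteria-passing candidates when any
exist).

The multivariate search is coordinate-wise ascent on r(GD~combined|IBD)
over the per-variable grids, first-in-grid winning ties, each variable
initialized at its univariate optimum (a grid-corner start can converge
to poor local optima). Variables are admitted one at a time, in scan
rank order, and an admission must (i) pass the reduced-model criteria —
(c) GD~full|reduced significant, (d) GD~reduced|full not — against its
*nested* reduction (shared variables held at the full model's
parameters, so the test isolates the newcomer's contribution), and
(ii) raise the objective over the current model (the search is an
ascent; a re-converged enlarged model at a worse optimum must not have
its lack-of-fit credited to the new variable). The final model must
itself pass (a)/(b) against IBD; failing that the engine falls back to
the best criteria-passing univariate model.

Candidates enter the search ordered with univariately supported
variables first, but unsupported variables are not barred: under a
multi-factor truth, each univariate test's criterion (b) is contaminated
by the *other* factors' residual signal, so exactly when power is high
no single variable passes (a)+(b) — the reduced-model criteria and the
final support check then carry the selection. This behaviour of the
framework (univariate support is hardest to attain for the true
variables at large sample sizes) emerged consistently in the recovery
benchmark and is worth knowing when interpreting univariate tables.

## MLPE models

For pairwise response y_ij = x_ij'β + u_i + u_j + e_ij with
u ~ N(0, σ_u²) per individual and independent residuals, the covariance
is V = σ_u² ZZ' + σ_e² I with Z the pair–individual incidence. β and
σ_e² are profiled out; the single ratio γ = σ_u²/σ_e² is optimized by
bounded scalar search on log γ, with all products through the Woodbury
identity (only n×n factorizations; fits are invariant to pair order,
tested). REML estimates are reported; ML log-likelihoods feed AICc
(REML likelihoods are not comparable across fixed-effect structures).
Convergence is audited by the profiled gradient unless the optimum is at
the variance boundary. The REML/ML values match a direct dense
multivariate-normal oracle to 1e−4 (tested).

Predictors are standardized per column; VIF_k = 1/(1−R²_k) from
regressing predictor k on the rest, with iterative removal above 5.
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k = fixed effects + 2 variance
components and n defaulting to the number of pairs (number of
individuals available by argument — the effective sample size of
pairwise data is genuinely ambiguous). R²_β uses the Wald F of the
non-intercept coefficients with containment denominator degrees of
freedom df₂ = m − n − p + 1; this is a deliberate approximation in place
of Kenward–Roger, adequate for ranking effect sizes but not for exact
small-sample inference.

## Corridors

A cell is disturbed if within 1 km of farmland or 2 km of residences
(Euclidean cell-centre distances via distance transforms). Candidate
paths between adjacent habitat components are least-cost routes on the
8-neighbour grid (edge cost = mean endpoint resistance, ×√2 diagonal)
through undisturbed cells; alternatives come from successive
penalization (×10 on used cells, default 5 candidates). Selection is
lexicographic: among candidates crossing the separating major road,
highest mean current density, then lower mean resistance, then shorter
path; if none crosses a road the best-current candidate is returned with
a warning flag. Selected corridors are audited against the buffers
(hard post-condition).

## Synthetic data

The generator's defaults define the study conditions: a 48×48 grid of
1 km cells, 120 individuals (a desk-scale stand-in for the 178 of the
motivating study), 12 loci with 5 alleles each, sex ratio 0.63 female,
2% missing calls, and a true model of easterly aspect (90°, x=10,
R_max=500) plus topographic complexity (x=10, R_max=500).

**Landscape.** Elevation is a randomly oriented washboard of parallel
ridges (axis within ~36° of north–south, so flanks have east/west
exposure; a north/south-facing washboard would carry no aspect contrast
against an easterly optimum) blended with a smooth random field over a
1000 m relief, plus a cell-scale checkerboard corrugation (±200 m)
modulated by a smooth saturating envelope. The checkerboard is the key
construction: Horn's 3×3 gradient cancels it exactly, so topographic
complexity becomes a coherent, near-binary landscape gradient while
slope and aspect remain governed by the large-scale relief — two
separable terrain signals, which a dual-variable recovery benchmark
requires. Vegetation, rivers, roads and disturbance patches come from
independent fields.

**Placement.** The benchmark places individuals uniformly, emulating
systematic survey transects; habitat-weighted placement (probability ∝
1/R) is available but concentrates samples into patches so that a single
barrier type dominates the realized genetic structure.

**Genotypes.** Per locus, one latent Gaussian field per allele (marginal
variance σ² = 4) is softmax-transformed into individual allele
probabilities; two alleles are drawn per individual. The field
correlation between individuals decreases with their resistance
distance. The default link is *linearized*: ρ(R) is chosen by
numerically inverting the Monte-Carlo E[D_ps | ρ] curve so that expected
genetic distance is an exactly linear function of R (the kernel matrix
is spectrally clipped to the PSD cone, a negligible correction at these
sizes). A classic exponential kernel ρ = exp(−R/λ) is available, but a
saturating link leaves concave lack-of-fit whose residual loads onto the
IBD matrix in partial Mantel tests — strongly enough that even the true
generating model fails the IBD-exclusion criterion in most realizations.
That sensitivity of causal modelling to link nonlinearity is a finding
in its own right: the framework assumes the genetic-distance/resistance
relationship is linear, and departures masquerade as distance effects.

**What passing does and does not show.** The generator produces
realistic marker statistics (mean alleles/locus ≈ 4.6–5, H_E ≈ 0.5–0.6,
strong per-marker discrimination) and a clean IBR world with known
truth. It does not emulate demographic history (bottlenecks, drift),
null alleles or genotyping error beyond random missingness, sex-biased
dispersal, or temporally autocorrelated sampling — so end-to-end
recovery demonstrates the inferential machinery, not robustness to
those complications.

**Problem sizes.** The recovery benchmark runs the full pipeline
(landscape → surfaces → circuit → scan → multivariate search → MLPE) on
the default 48×48 / n=120 configuration with 499 permutations per test;
one replicate takes seconds on a single core, and the test suite runs
20 recovery and 20 null replicates. Measured at these conditions:
recovery of exactly {aspect, tc} in 33/40 replicates (82.5%) across two
disjoint seed banks, and spurious support for aspect or TC in 1/20
replicates under an IBD-only truth.

## Known limitations

- Partial-Mantel causal modelling is knife-edged at high power: small
  lack-of-fit (link curvature, grid discretization) turns criterion (b)
  significant. The package mirrors the published framework rather than
  replacing it with e.g. distance-based MLPE selection alone.
- Kenward–Roger degrees of freedom are not implemented (containment
  approximation only).
- No CRS/reprojection handling; all rasters must share one grid.
- The categorical scan enumerates class-rank permutations, which grows
  factorially; it is intended for small class counts (vegetation: 3).
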
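# Methods

## Scope and data model

The package analyses plot-level grain yield from a line-breeding program
in which every yearly "set" of single-seed-descent (SSD) lines is tested
once, unreplicated, in the F5 generation and then in replicated
multi-location F6 trials in the following years.  A trial holds ~22
candidate lines plus repeated check varieties, laid out as randomized
complete blocks on an integer plot grid; the combined year–location–trial
(YLT) factor absorbs environment means.  Three tabular inputs (TSV/CSV,
`NA` for missing) describe genotypes (minor-allele counts 0/1/2),
pedigree (parents plus a recorded count of selfing cycles) and plots
(design factors, grid coordinates, yield in kg per 8.25 m² plot).
Field coordinates are 0-based integers on a per-(year, location, trial)
grid; which corner is the origin is irrelevant to the models.

## Relationship matrices

**Genomic (G).**  VanRaden's first method on post-QC, marker-mean-imputed
counts: `Z = M − 2p`, `G = ZZ′/2Σpⱼ(1−pⱼ)`.  Quality control removes
lines with more than 2% missing calls first, then recomputes allele
frequencies on the surviving lines and removes markers with minor-allele
frequency below 1% — a marker is judged on the data that actually enters
G.  Frequencies for centring and the denominator come from the same
post-QC matrix, so Z columns have exactly zero mean and `1′G1 = 0`.
The counts-coding centring `2p` is used throughout; the equivalent
−1/0/1-coding centring `2(p − ½)` differs only by a constant row/column
shift and is not offered, to keep one convention testable.

**Pedigree (A).**  The tabular recursion with explicit selfing
bookkeeping: off-diagonals `a_ij = ½(a_{i,p1(j)} + a_{i,p2(j)})` are
unchanged by selfing (expected allele content is preserved), while the
inbreeding coefficient follows `F = ½·a_{p1,p2}` at the cross and
`F′ = ½(1 + F)` per recorded selfing cycle.  Founders and unknown-parent
lines start non-inbred and default to nine cycles (fully inbred parent
lines, diagonal `1 + (1 − 2⁻⁹) = 1.998046875`); an F5 line carries four
cycles (F1→F5).  A line with one known parent is treated as a cross with
an unrelated non-inbred founder.  The recursion is validated against a
gene-dropping identity-by-descent simulation that expands every selfing
chain explicitly.

**Conditioning.**  REML needs invertible covariances, and duplicate or
near-duplicate lines make G rank-deficient; when the smallest eigenvalue
is below ε (default 1e-6) the matrix is shifted by `(ε − λ_min)I` and the
bend recorded.  PCoA double-centres the matrix and reports each axis's
share of the sum of positive eigenvalues only; negative eigenvalues
(possible for a bent or non-Euclidean similarity) are excluded from the
denominator.

## Mixed models and REML

Design matrices are cell-means incidences: the YLT factor has one column
per observed cell and exactly one 1 per row, so X has full column rank
and no reference-level constraint is needed (the restricted likelihood is
invariant to this choice; a test asserts it).  Spatial terms are nested
within (year, location, trial).  The F5 layout fits row and column
factors (n = 2) sharing one variance — the two incidences are stacked
into a single term.  The F6 layout fits a moving average: each plot loads
its own grid position and every Moore neighbour that exists in the same
trial, so interior plots sum nine positions and edge plots fewer, with no
padding or reflection.  Neighbourhood counts n = 2 and n = 9 (the plot
itself included) propagate into the heritability formula as `nₛ`.

Estimation is average-information (AI) REML on the mixed-model equations
`C = W′R⁻¹W + diag(0, G*⁻¹)`, using the identities
`P = R⁻¹ − R⁻¹WC⁻¹W′R⁻¹`, `log|V| + log|X′V⁻¹X| = log|R| + log|G*| +
log|C|` and `Z′PZ = G*⁻¹ − G*⁻¹C^{uu}G*⁻¹`, so nothing of size n×n is
formed.  Scores and the AI matrix are exact (finite-difference checked);
a dense direct evaluation of the restricted likelihood is kept as an
independent oracle and equals the factorized form to ~1e-9.

Each iteration evaluates two candidates: the AI (Newton) step, halved up
to six times until it stops decreasing the likelihood, and the EM step,
which can never decrease it.  The better of the two is taken.  This
matters near the parameter-space boundary: an overshooting AI step whose
trait covariance H is clamped back to positive-definiteness can
technically "not decrease" the likelihood while gluing the iterate to the
boundary, after which pure EM needs hundreds of iterations to crawl back;
comparing against EM every iteration removes the failure mode.
Variances are floored at 1e-8 × the phenotypic variance (non-negative
estimates, as breeding-value software conventionally reports); H is kept
positive definite by flooring its diagonal and clamping the covariance to
0.999 of its bound.  Convergence is a relative parameter change below
`tol` (default 1e-8; the pipeline uses 1e-6 where many fits are run),
with floored components judged on a 1e-6 × phenotypic-variance scale so a
boundary solution does not stall the criterion.  Initialisation splits
half of each trait's phenotypic variance equally among the random terms
touching that trait, the other half to the residual, and starts the
genetic covariance at zero.  Non-convergence within `max_iter` (200) is
flagged on the result, not raised.

The bivariate model stacks the two traits' records with block-diagonal
fixed effects, a correlated genetic term `H ⊗ G` (columns ordered
trait-major), and per-trait residual variances; the residual covariance
is structurally zero because no plot carries both traits.  Pedigree and
spatial terms, when enabled, are fitted per trait with independent
variances — the genetic covariance between generations is carried by the
genomic term.  Lines observed for one trait only contribute that trait's
records and still receive breeding values for both traits through G.

In the extended model the pedigree term A and the genomic term G compete
for the same additive variance on SSD material (A approximates the
expectation of G), so σa² and σg² are individually ill-determined; their
sum is the meaningful quantity and recovery checks assert it.

## Genetic parameters

`σp² = d(G)σg² + nₛσs²/r₁ + σe²/r₂` and `h² = d(G)σg²/σp²`.  Plot
heritability sets r₁ = r₂ = 1; line heritability uses the mean number of
plots per line computed from the plot table (an explicit override is
accepted), so a single-plot F5 test has equal plot and line heritability
and replication can only raise the line value.  `σs²` enters multiplied
by nₛ exactly as the decomposition is written — the spatial variance is
per underlying position effect, and a plot's spatial value sums nₛ of
them.  The genetic correlation is `H₁₂/√(H₁₁H₂₂)`.

## Forward cross-validation

The newest set is the validation population; its F6 records never enter
any training fit (a leakage test permutes them and asserts the training
likelihood is bit-identical).  STGP trains on the earlier sets' F6
records; MTGP adds all F5 records including the validation lines' own.
Corrected line means ȳ_c are computed from validation records alone: YLT
effects are estimated with a model treating line as a random genomic
effect (so no training phenotype influences the correction), then
`ȳ_c = mean(y − x′b̂)` per line; plain within-YLT centring is available
as an option.  Check varieties are excluded from ρ by default (they are
not selection candidates), includable by flag.  Accuracy divides ρ by the
square root of the line-mean heritability estimated on the training data.

## Synthetic data generator

The generator emulates the program structure: fully inbred founders
(homozygous at every marker, allele frequencies U(0.05, 0.5)), biparental
crosses, SSD advance to F5 by per-marker Mendelian gene dropping (four
selfing rounds, so residual heterozygosity is 2⁻⁴ of the F1 level),
~1% of genotype calls masked missing.  Yearly sets are staggered so later
sets are genuinely in the program's future.  Phenotypes follow the fitted
models' own generative form: YLT effects drawn per cell (SD 0.5 kg by
default — environments differ far more than genotypes), spatial surfaces
built in the same moving-average / row-column form the models fit, and
iid residuals.

True breeding values are model-scale: marker effects are drawn iid with
variance `σg²/2Σp(1−p)` (bivariate pairs with correlation r_g), so
`g ~ N(0, G σg²)` holds exactly for the VanRaden G of the true counts and
the configured variances are the parameters REML estimates.  Realized BV
variance across lines is then `d(G)σg²` — about 1.9 σg² for these fully
inbred simulated lines, whose G diagonal is higher than a typical real
panel's.  Defaults follow a spring-barley program (four sets of 330
lines, trials of 22 + 3 checks, three locations, 3/2 replicates over two
F6 years, σg² = 0.017 and σe² = 0.057 kg² for F6, 0.003/0.066 for F5,
r_g = 0.7, yield means 6.60/6.11 kg per plot).

What the generator does *not* emulate: linkage (markers segregate
independently, so there is no LD beyond co-ancestry), selection during
line development, genotype-by-environment variance beyond the YLT means,
non-grid field trends (the spatial truth matches the fitted form by
design, so spatial-recovery tests are well-posed — an AR(1)-style
misspecified surface is deliberately out of scope), and non-normal trait
distributions.  Passing recovery tests therefore show the estimation
machinery is correct under the stated model, not that the model is
adequate for any particular real field.

## Problem sizes and study conditions used by the test suite

Parameter recovery runs 20 replicate programs of 400 lines × 2,000
markers with two F6 replicates and no spatial term (matching the fitted
bivariate model); mean components recover within ~6% and r̂_g within
~0.02 of 0.7.  Spatial variance is recovered within ~15% from a single
~2,000-plot univariate fit.  The STGP/MTGP comparison uses 20 replicate
programs of 4 × 40 lines under the high-F5-heritability condition
(σg²_F5 = 0.029, σe²_F5 = 0.078, i.e. F5 plot h² ≈ 0.41, r_g = 0.72):
with a barely heritable F5 (h² ≈ 0.09) the multi-trait advantage is real
but far too small for a 20-replicate sign test, which mirrors how the
benefit scales with the secondary trait's information content; with
r_g = 0 the two models are equivalent and the win count stays at
coin-flip level.  The acceptance script uses 8 recovery replicates and 12
comparison replicates, all seeded from its `--seed`.

## Known limitations

Dense linear algebra throughout: the coefficient matrix holds every
fixed, genetic and spatial level, so desk-scale problems (a few thousand
plots) fit comfortably but national-evaluation sizes would need sparse
supernodal solvers.  Two traits maximum; no Bayesian alternatives; no
AR1×AR1 or spline spatial models; no standard errors on heritabilities or
genetic correlations.  The pipeline configuration is validated by a
hand-rolled key check rather than a JSON schema.  Fixed-effect estimates
in the ȳ_c correction are slightly shrunk toward the validation-set mean
structure when trials are small; the centring option bounds the effect of
that choice.
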
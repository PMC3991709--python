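# Methods

## The quantity being measured

A mapped forest plot censused twice gives, for every stem ≥ 1 cm DBH, its
species, coordinates, size, and survival status.  Tiling the plot with
square quadrats of side *s* (10–50 m), the temporal phylogenetic turnover of
a quadrat is the Rao quadratic entropy across the two censuses,

    RaoD = Σ_i Σ_j  pA_i · pB_j · d_ij ,

the expected patristic distance between one stem drawn from the quadrat at
the first census and one drawn at the second.  Conspecific pairs contribute
zero.  Relative abundance is by stem count.  ``RaoD`` is implemented as the
pure cross term — the definition above is a single double sum, and that is
what the package computes by default; a normalized variant (cross term minus
the mean within-census Rao diversity) is available behind an option for
sensitivity analysis but is never the default.

Raw RaoD confounds turnover with standing diversity, so it is standardized
against replicate data sets from a null model:

    ses.RaoD = (RaoD_obs − mean(RaoD_null)) / sd(RaoD_null) .

`sd` uses the n−1 denominator; 499 replicates by default.  Quadrats empty at
either census, and quadrats whose null distribution is degenerate
(sd = 0), are flagged and excluded from downstream regressions.

## The two null models

**NM-I (species-name shuffle).**  One uniform permutation of species
identities per replicate, applied to both censuses, so abundances,
richness, occupancy and species turnover through time are all preserved
while phylogenetic identities are scrambled.  It implicitly assumes all
species share the same dispersal ability and survival schedule.

**NM-II (demographic null).**  Simulates the interval's demography with the
observed species- and size-specific rates:

* *Mortality.*  Census-1 stems are grouped by species and DBH class
  (1-cm classes to 20 cm, then 20–25, 25–35, 35–45, 45–55, ≥ 55 cm).
  Within each (species, class) cell the observed number of deaths is
  reassigned uniformly at random among the cell's stems.  This
  ``exact_count`` mode is the default: it holds every per-cell death count
  fixed, so whole-plot species abundances at census 2 are reproduced
  exactly and all null variance comes from *where* deaths fall, not from
  demographic noise.  A ``bernoulli`` mode (independent deaths at the
  cell's observed rate) is available.
* *Recruitment.*  A stem is mature if its census-1 DBH is ≥ 15 cm (trees)
  or ≥ 5 cm (shrubs).  For each observed recruit the distance Dp to its
  nearest mature conspecific within 50 m is recorded; in a replicate, a
  parent is redrawn uniformly from all mature conspecifics plot-wide and
  the recruit is placed at a uniform random angle *on the circle* of radius
  Dp around it.  Placement on the circumference (not inside the disk)
  preserves each recruit's observed parent–offspring distance; uniform-in-
  disk is available as an option.  If the point falls outside the plot the
  angle is redrawn (up to 100 times), then the parent is redrawn once, then
  the position falls back to uniform-in-plot; every fallback is counted in
  the replicate's log.  Recruits with no mature conspecific within 50 m are
  placed uniformly in the plot.  Size classes and maturity are always taken
  from census-1 DBH; empty survival cells contribute nothing (no pooling
  across classes); recruits are never subjected to simulated mortality.

NM-II preserves plot-level species abundances, richness and temporal
species turnover exactly (in ``exact_count`` mode); it deliberately does
*not* preserve per-quadrat abundances — the spatial rearrangement is the
null ensemble.

## Phylogenetic similarity and signal

Per quadrat, MPD is the unweighted mean patristic distance over all pairs of
species present, and

    NRI = −(MPD_obs − mean(MPD_null)) / sd(MPD_null)

with null communities from the independent-swap randomization: sequences of
2×2 checkerboard submatrix swaps that preserve each quadrat's richness and
each species' occurrence frequency exactly.  Each null matrix uses an
independent chain of 2 × (number of presences) successful swaps started
from the observed matrix.  Positive NRI means co-occurring species are more
closely related than the null expects.  NRI is computed on the first census
by default (the phylogenetic similarity *preceding* the turnover interval);
census 2 or pooled are options.  A technical note: counting *successful*
swaps samples the chain's jump process, whose stationary weight of a matrix
is proportional to its number of swappable 2×2 units; counting *attempts*
(the lazy chain) gives the exactly uniform distribution.  The difference is
negligible for the large matrices analyzed here, but the attempt-counting
mode is exposed and is what the uniformity test checks.

Phylogenetic signal of a trait is Blomberg's K: the ratio of the observed
(MSE0/MSE) to its Brownian-motion expectation, where MSE uses the tree's
shared-path-length covariance C and the phylogenetically corrected mean.
K = 1 under Brownian motion, ≈ 0 without signal.  Significance is the
one-tailed tip-shuffle test (1000 shuffles by default) with the add-one
rule p = (1 + #{K_null ≥ K_obs}) / (1 + n_shuffles).  Species missing the
trait are pruned for that trait's test and the n used is reported.

## Spatial statistics

Quadrats are lattice cells; "1 grid-cell lag" contiguity is rook
(4-neighborhood) by default — a distance threshold of one cell width
excludes diagonals (s√2 > s) — with queen available.  Weights are
row-standardized (the convention of the spatial-regression software this
mirrors).  Moran's I uses the permutation test (999 permutations,
two-sided by rank, add-one rule).

The relationship between ses.RaoD and NRI is fitted by the simultaneous
autoregressive error model y = Xβ + u, u = λWu + ε, by maximum likelihood:
β and σ² are profiled out and the concentrated likelihood over λ — with
ln|I − λW| from the eigenvalues of W, computed once per lattice — is
maximized by bounded scalar search (tolerance 1e-8) on λ ∈ (1/ω_min, 1/ω_max).
Coefficient p-values are asymptotic z-tests with Var(β̂) = σ̂²(X'A'AX)⁻¹ at
λ̂.  Quadrats flagged upstream are dropped listwise before the weights are
built; isolated quadrats are excluded from Moran and SAR fits with a
warning.

## PCNM variation partitioning

PCNM axes come from PCoA of the truncated centroid-distance matrix:
truncation t = s√2 (diagonally adjacent centers), distances > t replaced by
the constant 4t — the established convention; a literal reading that
multiplies each above-threshold distance by four is available as a
sensitivity option.  Only positive-eigenvalue axes are kept.  ses.RaoD is
detrended with a full third-degree orthogonal polynomial in the centroid
coordinates *before* axis selection.  Forward selection adds the axis with
the largest R² increase and keeps it only if a Freedman–Lane permutation
test (permuting current-model residuals, 999 permutations) accepts it at
α = 0.05; the permutation statistic is the *best achievable* gain among the
remaining axes, so the selection step's type-I error is controlled despite
best-of-m selection (verified by simulation).  Partitioning uses adjusted
R²: with [ab] = R²a(NRI), a = R²a(both) − R²a(PCNM),
c = R²a(both) − R²a(NRI), b = [ab] − a, d = 1 − (a+b+c); fractions can be
slightly negative, an adjusted-R² property.

## Branch-length smoothing

Trees come in as Newick with tip labels equal to species codes.  Node-age
smoothing fixes dated nodes (the root must be dated) and places every
undated node by even interpolation between its nearest dated ancestor and
nearest dated descendant along the path, nearest by edge count with ties
broken by the oldest such descendant; branch lengths are rewritten as age
differences and the output is ultrametric.  Conflicting constraints (a
child at least as old as its parent) raise an error.  Trees are used as
given — polytomies are permitted and never resolved automatically.

## The synthetic-data generator

Real repeat-census data are not redistributable, so the generator creates
the full input bundle with known parameters:

* **Phylogeny and traits** — pure-birth tree rescaled to unit root depth;
  traits evolve by Brownian motion along branches (or are i.i.d. normal at
  the tips for signal-free controls).  `n_traits` independent Brownian
  traits can be generated; a trait *vector* tracks the phylogeny much more
  tightly than any single Brownian trait (convergence in all coordinates
  simultaneously is rare), which matters when filtering is supposed to act
  along phylogenetic lines.
* **Census 1** — lognormal species-abundance distribution; stem positions
  from a Thomas cluster process (cluster size ~25 stems, spread 8 m) with
  torus wrap-around; DBH = 1 cm + lognormal; growth forms assigned per
  species (70% trees).  With habitat sorting (`prefilter_phi > 0`) cluster
  centers are placed by rejection sampling with acceptance
  exp(−prefilter_phi · mismatch), so species ranges already track the
  environment at the first census.
* **Mortality** — per-stem survival probability is logistic in species
  baseline and size class, optionally reduced by habitat filtering
  (exp(−φ·(mismatch − mean mismatch)); centering makes φ steer *who* dies
  more than *how many* die) and by phylogenetic density dependence
  (exp(−δ·z) with z the standardized phylogenetically weighted neighbor
  density within 10 m).
* **Recruitment** — around surviving mature conspecifics at
  exponential-kernel distances with per-species (lognormally varying)
  dispersal scales.
* **Environment** — either monotone gradients (one plot direction per
  trait) or a patchy mosaic (sums of Gaussian bumps with a configurable
  correlation length), in both cases quantile-mapped through the trait
  distribution so every position has species whose traits match it.
* A truth record retains every realized survival probability, death,
  parent assignment and dispersal distance.

Defaults are a desk-scale plot: 40 species, 200 m × 100 m, 8,000 stems,
~15% interval mortality — big enough for 10–50 m grids, small enough that a
full two-null-model pipeline runs in minutes.

### Scenario presets

`scenario_config` packages three study conditions.  `neutral` is the
default generator.  `filtering` uses 60 species, a 500 m × 250 m plot with
50,000 stems, eight Brownian traits, a patchy environment with 20 m
correlation length, strong filtering mortality (φ = 6) on ranges already
habitat-sorted at census 1 (prefilter 3).  The patch scale matters: the SAR
error model whitens away broad gradients, so the turnover–similarity
association must live at the quadrat scale to appear in the slope; the
larger plot supplies enough 20 m quadrats for a stable fit.  `density` uses
δ = 1.5 on a 300 m × 150 m plot with 18,000 stems.  Under filtering,
quadrats of distantly related (trait-mismatched) species turn over more
than the demographic null expects — a negative ses.RaoD–NRI slope; under
density dependence, quadrats of close relatives do — a positive slope at
the finest scale.

### What the generator does not emulate

No allometric growth, no habitat-dependent recruitment (filtering acts on
mortality and, optionally, initial placement), no immigration from outside
the plot, no calibration to any real plot's rates.  Passing tests show the
estimators and null models behave correctly under these idealized
processes; they do not certify behavior under real-forest complications
(measurement error, multi-stem individuals, unrecorded treefall gaps).

## Numerical choices and degenerate inputs

* Null replicate streams: one master seed spawns an independent substream
  per replicate (`numpy.random.SeedSequence`), so results are reproducible
  and order-independent.
* Degenerate null ensembles (sd ≤ 1e-12) flag the quadrat rather than
  aborting the grid; single-species quadrats are flagged for NRI
  (richness < 2).
* Grid cells are half-open [i·s, (i+1)·s) with the plot's maximal edges
  clamped into the last cell; stems in partial edge cells (plot dimensions
  not divisible by s) are excluded and counted in the grid log.
* The SAR λ search is bounded scalar optimization to 1e-8; the eigenvalues
  of the row-standardized W are obtained from the similar symmetric matrix
  D^{-1/2}BD^{-1/2}, so they are real.
* Blomberg's K inverts C directly (dense, tens-to-hundreds of species); a
  singular C (duplicate tips at zero distance) is an error naming the
  problem.
* PCNM keeps eigenvalues above max(1e-8·λ_max, 1e-10); the cubic detrend
  standardizes coordinates and uses a QR-orthogonalized basis.

## Problem sizes used by the validation suite

The statistical tests run at sizes chosen to finish in minutes while
keeping the Monte-Carlo error well inside the asserted bands: 200 Brownian
replicates on 128-tip trees for the K calibration; 500 signal-free
data sets with 199 shuffles for the type-I rate; 1,000 random communities
for the Rao oracle; one 8,000-stem plot with 499 NM-II replicates for the
self-consistency check; 200 lattice replicates for SAR recovery; and 50
generator replicates per directional scenario with 99-replicate nulls,
where the slope sign — not its magnitude — is the assertion.

## Known limitations

* NM-II's recruitment null measures Dp to the nearest mature conspecific,
  which underestimates the true parent distance in dense clusters; the
  null therefore concentrates replicate recruits slightly more around
  adults than the generating kernel does.  This is a property of the
  method itself, visible in the self-consistency check as a ses.RaoD
  standard deviation a few percent above 1.
* The directional scenarios document a real sensitivity of the
  turnover–similarity slope to the spatial scale of the habitat structure:
  broad gradients are absorbed by the SAR error term and do not register
  in the slope.  Users analyzing real plots should read the PCNM fractions
  alongside the SAR coefficient for exactly this reason.
* Habitat-dependent mortality is deliberately absent from NM-II (it is a
  null model for detecting such effects, not a fitted model of them).
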
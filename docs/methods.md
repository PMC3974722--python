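# Methods

## Model and pipeline

`somcoex` treats each expression database independently.  A gene is a
point in ℝ^D, D the number of time samples of that database; a
self-organizing map projects these points onto a 20 × 20 hexagonal
sheet while preserving neighborhood structure, so map-unit distance is
a (coarse, bounded) proxy for expression-profile dissimilarity.  The
cross-database analysis then works entirely in map space: for each
gene pair present everywhere, the vector of per-database unit distances
is screened for quartile outliers, and thresholded for consistently
close / consistently far pairs.

The fixed preprocessing order is standardize names → filter missing →
impute → rescale.  Each step's contract is enforced (rescaling and
training refuse data with missing values; training refuses non-[0,1]
scales), so the orchestrator cannot silently reorder stages.

### Hexagonal grid

Units are labeled 1..400 row-major.  Row r (0-based) sits at
y = r·√3/2; column c at x = c + 0.5·(r mod 2).  With unit edge length 1
every interior unit has six neighbors at centroid distance exactly 1;
squared distances are computed as dx² + 0.75·Δr², which is exact in
binary floating point, so lattice-neighbor distances are exactly 1.0
rather than 1 − ε.  Any labeling in which labels 20 apart are
lattice-adjacent is geometrically equivalent; row-major with odd-row
offset is pinned by the geometry tests.

### Training

* **Initialization** — units are laid on the plane spanned by the two
  leading principal components: unit (r, c) gets
  mean + α(c)·s₁·v₁ + β(r)·s₂·v₂ with α, β spanning [−1, 1] and sₖ the
  per-component standard deviation (singular value / √(n−1)).  Scaling
  by the standard deviation rather than the raw singular value keeps
  the initial sheet inside the data cloud regardless of gene count; it
  is the convention of the classical SOM toolbox's linear
  initialization.  Rank-deficient data falls back to the available rank
  with a warning.
* **Schedule** — σ decays linearly from 3 to 1 across epochs; η(n) =
  0.5 / (1 + 100 n/T) per epoch ('inv'); T = ⌈10·K/N⌉ epochs, each a
  full pass over the genes in seeded shuffled order (a fixed order is
  available for exact cross-implementation comparison).  All units are
  updated every presentation (no radius cutoff); ties in the BMU search
  break to the lowest unit label.  Training is bit-deterministic given
  the config.
* **Defaults and units** — σ in lattice units; η dimensionless in
  (0, 1].  η₀ = 0.5 is a conventional default, not a measured value;
  the epoch multiplier (default 10) is configurable because ⌈10·K/N⌉
  is a small number of passes for a few hundred genes.

### Missing data

Genes missing more than 2 of their time points are excluded (the
bookkeeping report counts the 0/1/2/>2 bins and reconciles retained +
excluded = present).  Remaining gaps are imputed by EM under a
multivariate normal over samples, estimated per database:

* start: mean = observed column means, covariance = diagonal of
  observed column variances — so the first E-step fills each gap with
  its sample's observed mean;
* E-step: conditional expectation of the missing block given the
  gene's observed block; M-step: re-estimate mean and covariance from
  the completed matrix with a ridge of 10⁻⁶·trace/D on the diagonal;
* stop when the imputed vector changes by less than `em_tol` = 10⁻⁶
  (relative, successive fills seeded at zero so the first fill counts
  as a full-magnitude change) or after 100 iterations;
* imputations are clamped to the gene's observed range ± 3 observed
  standard deviations; observed entries are restored bit-identically.
  With fewer than 3 genes the covariance is unidentifiable and
  per-sample mean imputation is used with a warning.

### Rescaling

Each gene's profile is mapped linearly so min → 0 and max → 1
("expression fractions"); a constant profile maps to 0.5 (the midpoint
avoids biasing constant genes toward a map corner).  Min-max scaling is
invariant to positive affine transforms, so log₂- and log₁₀-ratio
versions of the same measurements yield identical fractions — this is
what makes the databases comparable.  Per-database min-max is available
as an option but is not the default, since profile *shape* is what the
map should cluster.

### Outlier rule

Quartiles use linear interpolation between order statistics (the
quantile-method choice is material at n = 5 and is pinned by tests).
Tukey fences with multiplier 1.5 are the quartile-based rule; the
multiplier is configurable.  Outliers are computed per pair across
databases — the question is "in which database does this pair
misbehave", not "which pairs are extreme within a database".  The rule
needs at least 4 databases; below that the pipeline refuses to run the
outlier stage.

## Synthetic data generator

The generator emulates synchronized cell-cycle experiments: gene g's
noiseless value at time t is A·sin(2πt/P + φ_g) on a log-ratio scale,
P = 60 min per cycle, two cycles, with per-database sampling intervals
(7, 10, 10, 5, 5 min → 18/13/13/25/25 samples via ⌊2P/i⌋ + 1), log
bases (2, 2, 2, 10, 10), Gaussian noise (σ = 0.05), optional uniform
missing values capped per gene, and optionally scrambled gene naming
(systematic/standard/alias chosen per gene per database, resolvable
through the generated catalog).  120 genes by default: four
phase-locked clusters of 25 (peak phases evenly spaced, jitter 0.05
rad) and 20 free genes, two of which form an anti-phase pair (phases π
apart).  Phase labels partition the cycle at fractions 0–0.1 (M/G1),
0.1–0.4 (G1), 0.4–0.6 (S), 0.6–0.8 (G2), 0.8–1.0 (M); t = 0 is the
synchronized release point.  Amplitude damping across cycles
(synchrony loss) is available and off by default.

A database can be perturbed — selected genes redrawn with independent
phases, or rows reshuffled — to plant a known discordant experiment.
Ground truth (phases, memberships, anti-phase pairs, pre-noise values,
values hidden behind the missing mask) is returned for tests only.

What the generator does *not* emulate: hybridization/dye noise physics,
amplitude differences between genes, non-sinusoidal wave shapes,
arrest-release transients, strain-specific biology.  Passing tests
therefore demonstrate that the pipeline recovers planted periodic
structure and planted discordance under idealized periodic signals, not
that it would resolve any particular real regulatory relationship.

The two 10-min pseudo-databases get 13 samples — fewer than the real
experiments they echo, which sampled a longer window than two 60-min
cycles; the sample-count formula is kept uniform rather than adding
per-database window overrides.

## Numerical and design choices

* BMU ties → lowest label; quantile method → linear interpolation;
  constant profile → 0.5; these degenerate-case rules are pinned by
  tests because they affect downstream counts.
* Single training phase (no rough/fine-tune split) and sequential (not
  batch) updates: the online rule is the one the weight-update formula
  defines.
* Component planes are colored on the fixed [0, 1] fraction domain, not
  per-image min/max, so a color means the same expression fraction in
  every sample's map.
* Every figure-producing function writes the plotted numbers as a
  sidecar TSV; tests assert on data, never pixels.
* Model persistence is a JSON header plus a TSV weight matrix;
  round-trips are exact (`repr` formatting of doubles).
* The false-positive rate for planted-cluster recovery is defined over
  ground-truth-negative pairs (pairs not in the same planted cluster).

## Known limitations

* Map-unit distance saturates at the grid diameter and quantizes small
  dissimilarities; it is a screening statistic, not a metric on
  expression space.
* With many more units than genes (400 vs ~120–280), the map dedicates
  a contiguous region to each tight co-expression cluster and spreads
  the cluster's members across it (roughly one unit per member).  A
  planted 25-gene cluster therefore occupies a region wider than
  lattice radius 3, and the fraction of its pairs within radius 3 in
  *all five* independently trained maps is small.  Consistently-close
  screening at small radii is correspondingly conservative for large
  clusters — pairs it returns are reliable, but it does not enumerate
  every within-cluster pair.  Smaller groups (a handful of genes)
  concentrate on a few adjacent units, matching the behavior reported
  for real co-regulated gene families.
* The EM imputer assumes profiles are draws from one multivariate
  normal per database; strongly multimodal expression (e.g. distinct
  anti-phase families) violates this, which is tolerable at ≤ 2 imputed
  points per gene but would bias heavier imputation.
* Quartile fences over five values are coarse: a single discordant
  database is detected reliably, but the low fence can also trip when
  four background distances are themselves spread out.
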
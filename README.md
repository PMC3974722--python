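# somcoex

Self-organizing-map (SOM) analysis of gene co-expression consistency
across expression time-series databases.

## The problem

Cell-cycle synchronization experiments measure the expression of
thousands of genes at a handful of time points over one or two cycles.
Several such databases exist for *Saccharomyces cerevisiae*, but they
use different strains, synchronization methods, sampling intervals and
value scales (log₂- vs log₁₀-ratios), so their expression matrices
cannot simply be merged.  `somcoex` instead compares the databases
through the *geometry* of one self-organizing map trained per database:
genes whose map units sit consistently close together in every database
are candidate co-regulation relationships; genes consistently on
opposite sides suggest negative regulation; and gene pairs whose
distance in exactly one database is a quartile outlier point at
experimental conditions that distorted those genes' behavior.

The package is aimed at computational biologists exploring candidate
gene relationships from time-series expression data, and ships a
synthetic multi-database generator so the whole pipeline runs and is
testable without any downloads.

## The method

Each gene is a vector **x** of expression fractions over the database's
time samples.  A sheet of K = 20 × 20 units on a hexagonal lattice
(adjacent centroids at distance 1) carries one weight vector **w**ⱼ per
unit, initialized on the plane of the data's two leading principal
components.  Sequential training presents each gene once per epoch:

1. *Competition*: the best matching unit (BMU) is
   i = argminⱼ ‖**x** − **w**ⱼ‖.
2. *Cooperation*: every unit j receives the Gaussian neighborhood value
   h = exp(−d²ⱼᵢ / 2σ²) over its lateral (grid) distance to the BMU.
3. *Adaptation*: **w**ⱼ ← **w**ⱼ + η·h·(**x** − **w**ⱼ).

The radius σ shrinks linearly from 3 to 1 across epochs; the learning
rate follows the inverse-time schedule η(n) = η₀ / (1 + 100 n/T) with
η₀ = 0.5; the epoch count is ⌈10·K / N⌉ for N genes.  Preprocessing
standardizes gene names through a catalog, drops genes with more than
two missing time points, imputes the rest by expectation-maximization
under a multivariate normal over samples, and rescales each profile to
[0, 1] — which makes log₂ and log₁₀ inputs exactly comparable.

For every pair of genes present in all databases, the pair's unit
distances (one per database) are screened with Tukey fences
[Q1 − 1.5·IQR, Q3 + 1.5·IQR]: a distance outside the fences flags that
pair as an outlier in that database.

## Worked example

`examples/03_cross_database_consistency.py` builds five synthetic
databases (120 genes, four phase-locked clusters, two cell cycles,
database-specific sampling grids) with the fifth database perturbed so
its profiles are independent, trains one map per database, and prints:

```
gene pairs analyzed: 7140
outlier pairs per database (db5 was perturbed):
  db1: 308
  db2: 398
  db3: 268
  db4: 571
  db5: 3077
consistently close pairs (<= 3 units everywhere): 96
consistently far pairs (>= half the map everywhere): 1501
planted anti-phase pair YSG101W/YSG102W among far pairs: True
```

7140 = C(120, 2) pairs are screened; the perturbed database collects
roughly an order of magnitude more outlier pairs than its peers, which
is exactly how a discordant experiment surfaces in this analysis.  The
close/far lists (computed over the four unperturbed databases) recover
the planted anti-phase pair among the consistently-far pairs.  The
other examples cover preprocessing bookkeeping
(`01_simulate_and_preprocess.py`) and training plus component-plane
rendering (`02_train_and_visualize.py`).

A thin CLI mirrors the stages (`somcoex simulate | preprocess | train |
map | outliers | pairs | render | run`); `somcoex run config.yaml`
executes everything from a single YAML config, e.g.:

```yaml
dataset_paths: [syn/db1.tsv, syn/db2.tsv, syn/db3.tsv, syn/db4.tsv, syn/db5.tsv]
catalog_path: syn/catalog.csv
out_dir: runout
seed: 7
```

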
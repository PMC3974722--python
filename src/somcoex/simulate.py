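"""Synthetic multi-database cell-cycle expression generator.

Emulates the structure of synchronized yeast cell-cycle time-series
experiments: several databases measure the same genes over two cell
cycles but with database-specific sampling intervals, value scales
(log2- vs log10-ratio), missing values and inconsistent gene naming.
Each gene's noiseless profile is a sinusoid over time,

    value(t) = A * sin(2*pi*t / P + phi_g) + noise,

with P the cycle period and phi_g the gene's peak phase.  Genes are
organized into phase-locked co-regulated clusters (small within-cluster
phase jitter), free "singleton" genes, and designated anti-phase pairs
(phases pi apart).  Ground truth (phases, clusters, anti-phase pairs,
pre-noise values, true values behind injected gaps) is returned for
tests and never consumed by the analysis pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import ExpressionDataset, GeneCatalog, GeneRecord

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "phase_label",
    "perturb_database",
    "n_samples_for",
]

#: cycle-fraction boundaries for the phase tags, in cycle order
DEFAULT_PHASE_BOUNDARIES = (
    ("M/G1", 0.0, 0.1),
    ("G1", 0.1, 0.4),
    ("S", 0.4, 0.6),
    ("G2", 0.6, 0.8),
    ("M", 0.8, 1.0),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic multi-database experiment.

    Defaults: 120 genes (4 co-regulated clusters of 25 plus 20 singletons,
    two of the singleton genes forming an anti-phase pair), 5 databases
    with sampling intervals of 7, 10, 10, 5 and 5 minutes over two 60-min
    cycles, Gaussian measurement noise of 0.05 on the log-ratio scale.
    """

    n_genes: int = 120
    n_databases: int = 5
    cycle_period_min: float = 60.0
    n_cycles: int = 2
    sampling_intervals_min: tuple[float, ...] = (7.0, 10.0, 10.0, 5.0, 5.0)
    n_clusters: int = 4
    cluster_size: int = 25
    phase_jitter_sd: float = 0.05  # radians within a cluster
    n_anti_phase_pairs: int = 1
    amplitude: float = 1.0
    noise_sd: float = 0.05
    missing_rate: float = 0.0
    max_missing_per_gene: int | None = 2
    log_bases: tuple[int, ...] = (2, 2, 2, 10, 10)
    alias_scramble: bool = False
    perturbed_database: int | None = None
    damping: float = 0.0  # amplitude loss per cycle (synchrony decay)
    rng_seed: int = 0
    phase_boundaries: tuple = DEFAULT_PHASE_BOUNDARIES

    def __post_init__(self) -> None:
        if len(self.sampling_intervals_min) != self.n_databases:
            raise ValueError("need one sampling interval per database")
        if len(self.log_bases) != self.n_databases:
            raise ValueError("need one log base per database")
        if self.n_clusters * self.cluster_size > self.n_genes:
            raise ValueError("clusters cannot exceed n_genes")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic run; consumed only by tests."""

    phases: dict[str, float]
    clusters: dict[str, int]  # gene -> cluster index; -1 for singletons
    anti_phase_pairs: list[tuple[str, str]]
    true_values: list[np.ndarray]  # pre-noise matrix per database
    masked_true_values: list[dict[tuple[int, int], float]]
    perturbed_database: int | None = None
    perturbed_genes: list[str] = field(default_factory=list)

    def within_cluster_pairs(self) -> set[tuple[str, str]]:
        groups: dict[int, list[str]] = {}
        for g, c in self.clusters.items():
            if c >= 0:
                groups.setdefault(c, []).append(g)
        pairs: set[tuple[str, str]] = set()
        for members in groups.values():
            members = sorted(members)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pairs.add((members[i], members[j]))
        return pairs


def n_samples_for(spec: SyntheticSpec, db_index: int) -> int:
    """floor(n_cycles * period / interval) + 1 samples for one database."""
    interval = spec.sampling_intervals_min[db_index]
    return int(math.floor(spec.n_cycles * spec.cycle_period_min / interval)) + 1


def phase_label(t: float, spec: SyntheticSpec) -> str:
    """Cell-cycle phase tag for sampling time ``t`` (minutes).

    The cycle position t mod P is mapped to M/G1, G1, S, G2 or M through
    fixed cycle-fraction boundaries; t = 0 is the synchronized release
    point, labeled M/G1.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    frac = (t % spec.cycle_period_min) / spec.cycle_period_min
    for name, lo, hi in spec.phase_boundaries:
        if lo <= frac < hi:
            return name
    return spec.phase_boundaries[-1][0]


def _gene_names(n: int) -> tuple[list[str], list[str], list[list[str]]]:
    systematic = [f"YSG{i + 1:03d}W" for i in range(n)]
    standard = [f"GEN{i + 1}" for i in range(n)]
    aliases = [[f"G{i + 1}ALT"] for i in range(n)]
    return systematic, standard, aliases


def _assign_phases(spec: SyntheticSpec, rng: np.random.Generator):
    """Plant phases: evenly spaced cluster peaks, jittered members, free singletons."""
    n_clustered = spec.n_clusters * spec.cluster_size
    cluster_peaks = [2 * math.pi * k / spec.n_clusters for k in range(spec.n_clusters)]
    phases = np.empty(spec.n_genes)
    clusters = np.full(spec.n_genes, -1, dtype=int)
    for k in range(spec.n_clusters):
        lo = k * spec.cluster_size
        idx = np.arange(lo, lo + spec.cluster_size)
        clusters[idx] = k
        phases[idx] = cluster_peaks[k] + rng.normal(0, spec.phase_jitter_sd, idx.size)
    n_single = spec.n_genes - n_clustered
    phases[n_clustered:] = rng.uniform(0, 2 * math.pi, n_single)
    anti_pairs: list[tuple[int, int]] = []
    # anti-phase pairs drawn from the singleton block when possible
    for p in range(spec.n_anti_phase_pairs):
        if n_single >= 2 * (p + 1):
            a = n_clustered + 2 * p
            b = a + 1
        else:
            a, b = 2 * p, 2 * p + 1
        phases[b] = (phases[a] + math.pi) % (2 * math.pi)
        anti_pairs.append((a, b))
    return phases, clusters, anti_pairs


def generate(
    spec: SyntheticSpec,
) -> tuple[list[ExpressionDataset], GeneCatalog, GroundTruth]:
    """Generate the synthetic databases, a gene catalog and ground truth.

    Databases carry log-ratio values (log2 or log10 per ``log_bases``)
    with missing entries injected uniformly at ``missing_rate``, capped at
    ``max_missing_per_gene`` per gene unless the cap is disabled (None).
    When ``alias_scramble`` is set, each database labels each gene by a
    name tier (systematic/standard/alias) chosen at random, emulating the
    naming inconsistency of real databases.  Fully reproducible from
    ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    systematic, standard, aliases = _gene_names(spec.n_genes)
    catalog = GeneCatalog(
        [
            GeneRecord(standard[i], systematic[i], tuple(aliases[i]))
            for i in range(spec.n_genes)
        ]
    )
    phases, clusters, anti_pairs = _assign_phases(spec, rng)

    if spec.max_missing_per_gene is not None:
        capacity = spec.n_genes * spec.max_missing_per_gene
        worst = max(
            round(spec.missing_rate * spec.n_genes * n_samples_for(spec, d))
            for d in range(spec.n_databases)
        )
        if worst > capacity:
            raise ValueError(
                f"missing_rate {spec.missing_rate} cannot respect the "
                f"{spec.max_missing_per_gene}-per-gene cap"
            )

    datasets: list[ExpressionDataset] = []
    true_values: list[np.ndarray] = []
    masked_truth: list[dict[tuple[int, int], float]] = []
    perturbed_genes: list[str] = []
    for d in range(spec.n_databases):
        n_s = n_samples_for(spec, d)
        times = np.arange(n_s) * spec.sampling_intervals_min[d]
        db_phases = phases.copy()
        if spec.perturbed_database == d:
            db_phases = rng.uniform(0, 2 * math.pi, spec.n_genes)
            perturbed_genes = list(systematic)
        clean = _profiles(db_phases, times, spec)
        if spec.log_bases[d] == 10:
            clean = clean * math.log10(2.0)  # same measurements on log10 scale
        noisy = clean + rng.normal(0, spec.noise_sd, clean.shape)
        mask = _inject_missing(spec, rng, noisy.shape)
        masked_truth.append(
            {(i, j): noisy[i, j] for i, j in zip(*np.nonzero(mask))}
        )
        gene_ids = _database_gene_ids(
            spec, rng, d, systematic, standard, aliases
        )
        datasets.append(
            ExpressionDataset(
                database_name=f"db{d + 1}",
                gene_ids=gene_ids,
                sample_times=times,
                values=noisy,
                missing_mask=mask,
                scale="log10-ratio" if spec.log_bases[d] == 10 else "log2-ratio",
                phase_labels=[phase_label(t, spec) for t in times],
            )
        )
        true_values.append(clean)

    truth = GroundTruth(
        phases={systematic[i]: float(phases[i]) for i in range(spec.n_genes)},
        clusters={systematic[i]: int(clusters[i]) for i in range(spec.n_genes)},
        anti_phase_pairs=[
            tuple(sorted((systematic[a], systematic[b]))) for a, b in anti_pairs
        ],
        true_values=true_values,
        masked_true_values=masked_truth,
        perturbed_database=spec.perturbed_database,
        perturbed_genes=perturbed_genes,
    )
    return datasets, catalog, truth


def _profiles(phases: np.ndarray, times: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    amp = spec.amplitude * (1.0 - spec.damping) ** (times / spec.cycle_period_min)
    angle = 2 * math.pi * times[None, :] / spec.cycle_period_min + phases[:, None]
    return amp[None, :] * np.sin(angle)


def _inject_missing(
    spec: SyntheticSpec, rng: np.random.Generator, shape: tuple[int, int]
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if spec.missing_rate <= 0:
        return mask
    n_genes, n_s = shape
    target = round(spec.missing_rate * n_genes * n_s)
    cap = spec.max_missing_per_gene if spec.max_missing_per_gene is not None else n_s
    cells = [(i, j) for i in range(n_genes) for j in range(n_s)]
    order = rng.permutation(len(cells))
    per_gene = np.zeros(n_genes, dtype=int)
    placed = 0
    for k in order:
        if placed >= target:
            break
        i, j = cells[k]
        if per_gene[i] < cap:
            mask[i, j] = True
            per_gene[i] += 1
            placed += 1
    return mask


def _database_gene_ids(spec, rng, d, systematic, standard, aliases):
    if not spec.alias_scramble:
        return list(systematic)
    ids = []
    for i in range(spec.n_genes):
        tier = rng.integers(0, 3)
        if tier == 0:
            ids.append(systematic[i])
        elif tier == 1:
            ids.append(standard[i])
        else:
            ids.append(aliases[i][0])
    return ids


def perturb_database(
    datasets: list[ExpressionDataset],
    truth: GroundTruth,
    index: int,
    mode: str = "decorrelate_subset",
    genes: list[str] | None = None,
    seed: int = 0,
    spec: SyntheticSpec | None = None,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Rewrite selected gene profiles of one database after generation.

    ``decorrelate_subset`` redraws the selected genes' profiles with
    independent random phases; ``reshuffle_genes`` permutes the selected
    rows among themselves.  The returned ground truth records the
    perturbed database and genes so tests can assert which pairs must
    surface as outliers.  Selecting no genes is the identity.
    """
    if not (0 <= index < len(datasets)):
        raise ValueError("database index out of range")
    if mode not in ("decorrelate_subset", "reshuffle_genes"):
        raise ValueError(f"unknown mode {mode!r}")
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    out = [ds.copy() for ds in datasets]
    ds = out[index]
    gene_list = list(ds.gene_ids) if genes is None else list(genes)
    rows = [ds.gene_ids.index(g) for g in gene_list]
    if not rows:
        return out, truth
    if mode == "reshuffle_genes":
        perm = rng.permutation(len(rows))
        ds.values[rows] = ds.values[[rows[p] for p in perm]]
    else:
        new_phases = rng.uniform(0, 2 * math.pi, len(rows))
        profiles = _profiles(new_phases, ds.sample_times, spec)
        if ds.scale == "log10-ratio":
            profiles = profiles * math.log10(2.0)
        ds.values[rows] = profiles + rng.normal(0, spec.noise_sd, profiles.shape)
    new_truth = GroundTruth(
        phases=dict(truth.phases),
        clusters=dict(truth.clusters),
        anti_phase_pairs=list(truth.anti_phase_pairs),
        true_values=[v.copy() for v in truth.true_values],
        masked_true_values=[dict(m) for m in truth.masked_true_values],
        perturbed_database=index,
        perturbed_genes=gene_list,
    )
    return out, new_truth
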
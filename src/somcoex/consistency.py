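"""Cross-database co-expression consistency from trained maps.

After one map is trained per database, each gene is assigned to its best
matching unit (BMU).  For every unordered pair of genes present in all
databases, the grid-centroid distance between the pair's units is
computed in each database.  A pair behaves differently in one database
when that database's distance is a quartile outlier relative to the
pair's other distances: with Q1 and Q3 the first and third quartiles
(linear interpolation between order statistics) and IQR = Q3 - Q1, any
distance outside [Q1 - k*IQR, Q3 + k*IQR] (Tukey fences, default
k = 1.5) is flagged.  Consistently close pairs are candidate positive
relationships; consistently far pairs suggest opposite regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .io_formats import ExpressionDataset
from .som import HexGrid, SomModel, find_bmu

__all__ = [
    "BmuTable",
    "PairDistanceRecord",
    "PairOutlierReport",
    "assign_bmus",
    "common_genes",
    "pair_distance_table",
    "flag_outliers",
    "outlier_report",
    "consistent_pairs",
    "opposite_pairs",
    "write_outlier_report",
    "write_outlier_summary",
    "write_pair_list",
]


@dataclass
class BmuTable:
    """Per-database gene → unit assignment (and the induced clusters)."""

    database_name: str
    assignments: dict[str, int]

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for gene, unit in self.assignments.items():
            out.setdefault(unit, []).append(gene)
        return out

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class PairDistanceRecord:
    gene_a: str
    gene_b: str
    distances: np.ndarray  # one per database, fixed order
    fences: tuple[float, float] | None = None
    outlier_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.gene_a > self.gene_b:
            raise ValueError("pair must be ordered gene_a < gene_b")
        self.distances = np.asarray(self.distances, dtype=float)


@dataclass
class PairOutlierReport:
    database_names: list[str]
    records: list[PairDistanceRecord] = field(default_factory=list)

    @property
    def total_pairs(self) -> int:
        return len(self.records)

    @property
    def per_database_outlier_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(self.database_names, 0)
        for rec in self.records:
            if rec.outlier_flags is None:
                continue
            for name, flag in zip(self.database_names, rec.outlier_flags):
                counts[name] += bool(flag)
        return counts


def assign_bmus(model: SomModel, data: ExpressionDataset) -> BmuTable:
    """Map each gene profile to its best matching unit."""
    if data.missing_mask.any():
        raise ValueError("data must be fully observed")
    if data.n_samples != model.dim:
        raise ValueError(
            f"data has {data.n_samples} samples, model expects {model.dim}"
        )
    assignments = {
        gene: find_bmu(profile, model)
        for gene, profile in zip(data.gene_ids, data.values)
    }
    return BmuTable(database_name=data.database_name, assignments=assignments)


def common_genes(tables: list[BmuTable]) -> list[str]:
    """Sorted intersection of gene ids present in every table."""
    if len(tables) < 2:
        raise ValueError("need at least 2 tables")
    common = set(tables[0].assignments)
    for t in tables[1:]:
        common &= set(t.assignments)
    return sorted(common)


def pair_distance_table(
    tables: list[BmuTable], grid: HexGrid, genes: list[str] | None = None
) -> list[PairDistanceRecord]:
    """One distance record per unordered pair of common genes."""
    genes = common_genes(tables) if genes is None else sorted(genes)
    for t in tables:
        missing = [g for g in genes if g not in t.assignments]
        if missing:
            raise ValueError(
                f"genes absent from {t.database_name}: {missing[:5]} (pre-filter via common_genes)"
            )
    dist = grid.pairwise_distances()
    units = np.array([[t.assignments[g] - 1 for g in genes] for t in tables])
    records = []
    for ia, ib in combinations(range(len(genes)), 2):
        d = dist[units[:, ia], units[:, ib]]
        records.append(PairDistanceRecord(genes[ia], genes[ib], d))
    return records


def flag_outliers(
    distances: np.ndarray, multiplier: float = 1.5
) -> tuple[tuple[float, float], np.ndarray]:
    """Tukey fences over one pair's per-database distances.

    Q1/Q3 by linear interpolation between order statistics; a distance is
    flagged when it falls outside [Q1 - m*IQR, Q3 + m*IQR].  Requires at
    least 4 databases (quartiles of fewer values are meaningless).
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 4:
        raise ValueError("quartile fences need at least 4 distances")
    q1, q3 = np.quantile(d, [0.25, 0.75])  # linear interpolation default
    iqr = q3 - q1
    lower, upper = q1 - multiplier * iqr, q3 + multiplier * iqr
    flags = (d < lower) | (d > upper)
    return (float(lower), float(upper)), flags


def outlier_report(
    tables: list[BmuTable], grid: HexGrid, multiplier: float = 1.5
) -> PairOutlierReport:
    """Full pipeline: common genes → pair distances → per-pair fences."""
    if len(tables) < 4:
        raise ValueError("outlier analysis needs at least 4 databases")
    records = pair_distance_table(tables, grid)
    for rec in records:
        rec.fences, rec.outlier_flags = flag_outliers(rec.distances, multiplier)
    return PairOutlierReport(
        database_names=[t.database_name for t in tables], records=records
    )


def consistent_pairs(
    tables: list[BmuTable], grid: HexGrid, radius_threshold: float
) -> list[tuple[str, str]]:
    """Pairs at distance <= threshold in every database: candidate positives."""
    records = pair_distance_table(tables, grid)
    return [
        (r.gene_a, r.gene_b)
        for r in records
        if np.all(r.distances <= radius_threshold)
    ]


def opposite_pairs(
    tables: list[BmuTable], grid: HexGrid, far_threshold: float
) -> list[tuple[str, str]]:
    """Pairs at distance >= threshold in every database: candidate negatives."""
    records = pair_distance_table(tables, grid)
    return [
        (r.gene_a, r.gene_b)
        for r in records
        if np.all(r.distances >= far_threshold)
    ]


def write_outlier_report(report: PairOutlierReport, path: str | Path) -> Path:
    """Per-pair TSV: distances per database, fences, flags."""
    path = Path(path)
    names = report.database_names
    with open(path, "w", encoding="utf-8") as fh:
        head = ["gene_a", "gene_b"] + [f"dist_{n}" for n in names]
        head += ["fence_lower", "fence_upper"] + [f"outlier_{n}" for n in names]
        fh.write("\t".join(head) + "\n")
        for rec in report.records:
            row = [rec.gene_a, rec.gene_b]
            row += [f"{d:.6g}" for d in rec.distances]
            lo, hi = rec.fences if rec.fences else (float("nan"), float("nan"))
            row += [f"{lo:.6g}", f"{hi:.6g}"]
            flags = rec.outlier_flags if rec.outlier_flags is not None else [False] * len(names)
            row += [str(int(f)) for f in flags]
            fh.write("\t".join(row) + "\n")
    return path


def write_outlier_summary(report: PairOutlierReport, path: str | Path) -> Path:
    """Per-database outlier-pair counts, one column per database."""
    path = Path(path)
    counts = report.per_database_outlier_counts
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("database\t" + "\t".join(report.database_names) + "\n")
        fh.write(
            "outlier_pairs\t"
            + "\t".join(str(counts[n]) for n in report.database_names)
            + "\n"
        )
        fh.write(f"total_pairs\t{report.total_pairs}\n")
    return path


def write_pair_list(
    pairs: list[tuple[str, str]],
    tables: list[BmuTable],
    grid: HexGrid,
    path: str | Path,
) -> Path:
    """Two-column pair TSV with per-database distances alongside."""
    path = Path(path)
    dist = grid.pairwise_distances()
    with open(path, "w", encoding="utf-8") as fh:
        names = [t.database_name for t in tables]
        fh.write("\t".join(["gene_a", "gene_b"] + [f"dist_{n}" for n in names]) + "\n")
        for a, b in pairs:
            ds = [dist[t.assignments[a] - 1, t.assignments[b] - 1] for t in tables]
            fh.write("\t".join([a, b] + [f"{d:.6g}" for d in ds]) + "\n")
    return path
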
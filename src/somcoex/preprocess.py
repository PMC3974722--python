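"""Per-database preprocessing: names → filter → impute → rescale.

The pipeline order is fixed.  Gene identifiers are first rewritten to
systematic names through the catalog (databases label genes inconsistently
with standard names, systematic names or aliases).  Genes with missing
values at more than ``max_missing_per_gene`` time points (default 2) are
excluded; remaining gaps are imputed with an expectation-maximization
estimator under a multivariate normal over time samples; finally each
profile is rescaled linearly to [0, 1] ("expression level fractions"),
which makes log2- and log10-ratio databases exactly comparable because the
min-max map is invariant to affine transforms of its input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import ExpressionDataset, GeneCatalog, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "FilterReport",
    "standardize_names",
    "filter_missing",
    "impute_em",
    "rescale_fraction",
    "preprocess_dataset",
]


@dataclass(frozen=True)
class PreprocessConfig:
    max_missing_per_gene: int = 2
    em_max_iter: int = 100
    em_tol: float = 1e-6
    scaling_mode: str = "per_gene_minmax"  # or "per_database_minmax"

    def __post_init__(self) -> None:
        if self.max_missing_per_gene < 0:
            raise ValueError("max_missing_per_gene must be >= 0")
        if self.em_tol <= 0:
            raise ValueError("em_tol must be positive")
        if self.scaling_mode not in ("per_gene_minmax", "per_database_minmax"):
            raise ValueError(f"unknown scaling_mode {self.scaling_mode!r}")


@dataclass
class FilterReport:
    """Missing-data bookkeeping for one database."""

    database_name: str
    present_in_db: int
    missing_0: int
    missing_1: int
    missing_2: int
    excluded: int

    @property
    def retained(self) -> int:
        return self.present_in_db - self.excluded

    def to_row(self) -> dict:
        return {
            "database": self.database_name,
            "present_in_db": self.present_in_db,
            "missing_1": self.missing_1,
            "missing_2": self.missing_2,
            "excluded": self.excluded,
            "retained": self.retained,
        }


def write_filter_reports(reports: list[FilterReport], path) -> None:
    """Serialize reports as a TSV, one column per database."""
    rows = [
        ("database", [r.database_name for r in reports]),
        ("genes present in database", [r.present_in_db for r in reports]),
        ("genes with 1 missing time point", [r.missing_1 for r in reports]),
        ("genes with 2 missing time points", [r.missing_2 for r in reports]),
        ("genes excluded (>2 missing)", [r.excluded for r in reports]),
        ("genes retained", [r.retained for r in reports]),
    ]
    with open(path, "w", encoding="utf-8") as fh:
        for name, vals in rows:
            fh.write(name + "\t" + "\t".join(str(v) for v in vals) + "\n")


def standardize_names(
    dataset: ExpressionDataset, catalog: GeneCatalog
) -> tuple[ExpressionDataset, list[str]]:
    """Rewrite gene ids to systematic names; drop and return unmatched ids.

    Two rows resolving to the same systematic name raise
    :class:`ValidationError` (an ambiguous duplicate cannot be attributed).
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    keep: list[int] = []
    new_ids: list[str] = []
    unmatched: list[str] = []
    seen: dict[str, str] = {}
    for i, gid in enumerate(dataset.gene_ids):
        rec = catalog.resolve(gid)
        if rec is None:
            unmatched.append(gid)
            continue
        if rec.systematic_name in seen:
            raise ValidationError(
                f"rows {seen[rec.systematic_name]!r} and {gid!r} both resolve to "
                f"{rec.systematic_name!r}"
            )
        seen[rec.systematic_name] = gid
        keep.append(i)
        new_ids.append(rec.systematic_name)
    out = dataset.subset(keep)
    out.gene_ids = new_ids
    out.validate()
    return out, unmatched


def filter_missing(
    dataset: ExpressionDataset, config: PreprocessConfig = PreprocessConfig()
) -> tuple[ExpressionDataset, FilterReport]:
    """Drop genes whose missing count exceeds ``max_missing_per_gene``."""
    counts = dataset.missing_mask.sum(axis=1)
    keep = [i for i, c in enumerate(counts) if c <= config.max_missing_per_gene]
    report = FilterReport(
        database_name=dataset.database_name,
        present_in_db=dataset.n_genes,
        missing_0=int((counts == 0).sum()),
        missing_1=int((counts == 1).sum()),
        missing_2=int((counts == 2).sum()),
        excluded=int((counts > config.max_missing_per_gene).sum()),
    )
    return dataset.subset(keep), report


def impute_em(
    dataset: ExpressionDataset, config: PreprocessConfig = PreprocessConfig()
) -> ExpressionDataset:
    """Fill missing entries by EM under a multivariate normal over samples.

    Genes are treated as draws from N(mu, Sigma) over the time samples of
    one database.  The covariance starts diagonal (observed per-sample
    variances), so the first E-step fills each gap with its sample's
    observed mean; subsequent iterations alternate conditional-expectation
    fills with mean/covariance re-estimation until the imputed entries
    change by less than ``em_tol`` (relative) or ``em_max_iter`` is hit.
    Observed values are never altered.  With fewer than 3 genes the
    covariance is unidentifiable and per-sample mean imputation is used
    with a logged warning.
    """
    out = dataset.copy()
    mask = out.missing_mask
    if not mask.any():
        out.missing_mask = np.zeros_like(mask)
        return out
    X = out.values.copy()
    n_genes, n_samples = X.shape
    col_means = np.array([
        X[~mask[:, j], j].mean() if (~mask[:, j]).any() else 0.0
        for j in range(n_samples)
    ])
    if n_genes < 3:
        logger.warning("impute_em: fewer than 3 genes; per-sample mean imputation")
        for j in range(n_samples):
            X[mask[:, j], j] = col_means[j]
        out.values = X
        out.missing_mask = np.zeros_like(mask)
        return out

    X[mask] = np.take(col_means, np.nonzero(mask)[1])
    mu = X.mean(axis=0)
    # diagonal start: per-sample variances of the observed entries
    var = np.array([
        X[~mask[:, j], j].var() if (~mask[:, j]).sum() > 1 else 1.0
        for j in range(n_samples)
    ])
    sigma = np.diag(np.maximum(var, 1e-12))
    # convergence is judged on successive imputed vectors, seeded at zero so
    # the first E-step (which reproduces the column means under the diagonal
    # start) registers as a full-magnitude change
    prev = np.zeros(int(mask.sum()))
    missing_rows = np.nonzero(mask.any(axis=1))[0]
    for _ in range(max(config.em_max_iter, 1)):
        # E-step: conditional expectation of missing given observed
        for i in missing_rows:
            m = mask[i]
            o = ~m
            s_oo = sigma[np.ix_(o, o)]
            s_mo = sigma[np.ix_(m, o)]
            resid = X[i, o] - mu[o]
            X[i, m] = mu[m] + s_mo @ np.linalg.solve(s_oo, resid)
        # M-step: re-estimate mean and covariance from the completed data
        mu = X.mean(axis=0)
        centered = X - mu
        sigma = centered.T @ centered / max(n_genes - 1, 1)
        sigma[np.diag_indices_from(sigma)] += 1e-6 * np.trace(sigma) / n_samples
        cur = X[mask]
        rel = np.max(np.abs(cur - prev)) / (np.max(np.abs(prev)) + 1.0)
        prev = cur.copy()
        if rel < config.em_tol:
            break
    # clamp imputations to the gene's observed range +/- 3 observed sd
    for i in missing_rows:
        o = ~mask[i]
        vals = dataset.values[i, o]
        if vals.size:
            sd = vals.std()
            lo, hi = vals.min() - 3 * sd, vals.max() + 3 * sd
            X[i, mask[i]] = np.clip(X[i, mask[i]], lo, hi)
    # observed entries are restored bit-identically
    X[~mask] = dataset.values[~mask]
    out.values = X
    out.missing_mask = np.zeros_like(mask)
    return out


def rescale_fraction(
    dataset: ExpressionDataset, config: PreprocessConfig = PreprocessConfig()
) -> ExpressionDataset:
    """Map values linearly to [0, 1] expression fractions.

    Default mode scales each gene so its minimum maps to 0 and maximum to
    1; a constant profile maps to 0.5 everywhere.  Because min-max scaling
    is invariant to positive affine transforms, log2- and log10-ratio
    inputs of the same measurements produce identical fractions.
    """
    if dataset.missing_mask.any():
        raise ValueError("rescale_fraction requires fully observed data")
    out = dataset.copy()
    X = out.values
    if config.scaling_mode == "per_database_minmax":
        lo, hi = X.min(), X.max()
        out.values = np.full_like(X, 0.5) if hi == lo else (X - lo) / (hi - lo)
    else:
        lo = X.min(axis=1, keepdims=True)
        hi = X.max(axis=1, keepdims=True)
        span = hi - lo
        flat = (span == 0).ravel()
        span = np.where(span == 0, 1.0, span)
        scaled = (X - lo) / span
        scaled[flat] = 0.5
        out.values = scaled
    out.scale = "fraction01"
    out.validate()
    return out


def preprocess_dataset(
    dataset: ExpressionDataset,
    catalog: GeneCatalog | None,
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[ExpressionDataset, FilterReport, list[str]]:
    """Run the fixed pipeline standardize → filter → impute → rescale."""
    unmatched: list[str] = []
    if catalog is not None and len(catalog) > 0:
        dataset, unmatched = standardize_names(dataset, catalog)
    dataset, report = filter_missing(dataset, config)
    dataset = impute_em(dataset, config)
    dataset = rescale_fraction(dataset, config)
    return dataset, report, unmatched
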
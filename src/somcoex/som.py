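"""Hexagonal-lattice self-organizing map.

The map is a sheet of ``n_rows x n_cols`` units on a hexagonal lattice
(default 20 x 20 = 400 units).  Units are labeled 1..K row-major; unit
centroids use the unit-edge-length convention, so lattice neighbors are at
Euclidean distance exactly 1:

* row ``r`` (0-based) sits at ``y = r * sqrt(3)/2``;
* column ``c`` sits at ``x = c + 0.5 * (r % 2)`` (odd rows shifted right).

Training is the classical sequential (online) Kohonen rule: for each
presented profile the best matching unit (BMU) is the weight vector at
minimum Euclidean distance; every unit then moves toward the input by

    w_j(n+1) = w_j(n) + eta(n) * h_{j,i}(n) * (x - w_j(n))

with a Gaussian neighborhood h = exp(-d^2 / (2 sigma^2)) over lateral
(grid-centroid) distances d.  The learning rate follows the 'inv'
inverse-time schedule eta(n) = eta0 / (1 + 100 n / T); the radius shrinks
linearly from ``sigma0`` to ``sigma_final`` across epochs.  The number of
epochs follows the rule ``ceil(m * K / n_genes)`` with multiplier m = 10,
one epoch presenting every gene once.  Weights are initialized on the
plane spanned by the two leading principal components of the data.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_formats import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "HexGrid",
    "TrainingConfig",
    "SomModel",
    "unit_distance",
    "pca_initialize",
    "find_bmu",
    "neighborhood_value",
    "update_weight",
    "epochs_for",
    "train",
    "quantization_error",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class HexGrid:
    """Hexagonal sheet with row-major unit labels 1..K."""

    n_rows: int = 20
    n_cols: int = 20

    @property
    def n_units(self) -> int:
        return self.n_rows * self.n_cols

    def coords(self) -> np.ndarray:
        """(K, 2) array of unit centroids in label order."""
        r = np.repeat(np.arange(self.n_rows), self.n_cols)
        c = np.tile(np.arange(self.n_cols), self.n_rows)
        x = c + 0.5 * (r % 2)
        y = r * (math.sqrt(3.0) / 2.0)
        return np.column_stack([x, y]).astype(float)

    def label_to_rc(self, label: int) -> tuple[int, int]:
        self._check_label(label)
        i = label - 1
        return divmod(i, self.n_cols)

    def rc_to_label(self, r: int, c: int) -> int:
        return r * self.n_cols + c + 1

    def _check_label(self, label: int) -> None:
        if not (1 <= label <= self.n_units):
            raise ValueError(f"unit label {label} outside 1..{self.n_units}")

    def pairwise_distances(self) -> np.ndarray:
        """(K, K) centroid distance matrix (symmetric, zero diagonal).

        Squared distances are formed as dx^2 + 0.75*dr^2 (0.75 = (sqrt(3)/2)^2
        is exact in binary floats), so lattice-adjacent units come out at
        distance exactly 1.0.
        """
        r = np.repeat(np.arange(self.n_rows), self.n_cols)
        c = np.tile(np.arange(self.n_cols), self.n_rows)
        x = c + 0.5 * (r % 2)
        dx = x[:, None] - x[None, :]
        dr = r[:, None] - r[None, :]
        return np.sqrt(dx ** 2 + 0.75 * dr.astype(float) ** 2)

    def diameter(self) -> float:
        return float(self.pairwise_distances().max())


def unit_distance(grid: HexGrid, a: int, b: int) -> float:
    """Euclidean distance between centroids of units ``a`` and ``b``.

    Lattice-adjacent units are at distance exactly 1; e.g. on the 20 x 20
    sheet units 2 and 22 sit in adjacent rows one half-column apart, at
    distance 1 even though their labels differ by 20.
    """
    grid._check_label(a)
    grid._check_label(b)
    ra, ca = grid.label_to_rc(a)
    rb, cb = grid.label_to_rc(b)
    dx = (ca + 0.5 * (ra % 2)) - (cb + 0.5 * (rb % 2))
    return math.sqrt(dx ** 2 + 0.75 * (ra - rb) ** 2)


@dataclass(frozen=True)
class TrainingConfig:
    """Schedule and geometry parameters of one SOM run."""

    n_rows: int = 20
    n_cols: int = 20
    sigma0: float = 3.0
    sigma_final: float = 1.0
    lr0: float = 0.5
    lr_schedule: str = "inv"
    epochs_multiplier: float = 10.0
    rng_seed: int = 0
    presentation_order: str = "shuffled_per_epoch"  # or "fixed"

    def __post_init__(self) -> None:
        if not (self.sigma0 >= self.sigma_final > 0):
            raise ValueError("require sigma0 >= sigma_final > 0")
        if not (0 < self.lr0 <= 1):
            raise ValueError("lr0 must lie in (0, 1]")
        if self.lr_schedule != "inv":
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")
        if self.presentation_order not in ("fixed", "shuffled_per_epoch"):
            raise ValueError(f"unknown presentation_order {self.presentation_order!r}")

    @property
    def grid(self) -> HexGrid:
        return HexGrid(self.n_rows, self.n_cols)


@dataclass
class SomModel:
    """A trained map: grid geometry plus one weight vector per unit."""

    grid: HexGrid
    weights: np.ndarray  # (K, D)
    config: TrainingConfig
    trained_on: str = ""
    qe_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != self.grid.n_units:
            raise ValueError("weights row count differs from grid units")

    @property
    def dim(self) -> int:
        return self.weights.shape[1]


def epochs_for(grid: HexGrid, n_genes: int, multiplier: float = 10.0) -> int:
    """Epoch count ``ceil(m * K / n_genes)``, clamped to at least 1."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return max(1, math.ceil(multiplier * grid.n_units / n_genes))


def neighborhood_value(d: float, sigma: float) -> float:
    """Gaussian neighborhood exp(-d^2 / (2 sigma^2)); exactly 1 at d = 0."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    return float(out) if out.ndim == 0 else out


def find_bmu(x: np.ndarray, model: SomModel) -> int:
    """Best matching unit label: argmin_j ||x - w_j||, ties to lowest label."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.dim,):
        raise ValueError(f"profile has dim {x.shape}, model expects ({model.dim},)")
    d2 = ((model.weights - x) ** 2).sum(axis=1)
    return int(np.argmin(d2)) + 1  # np.argmin returns the first minimum


def update_weight(w: np.ndarray, x: np.ndarray, eta: float, h: float) -> np.ndarray:
    """One Kohonen step w + eta*h*(x - w); h = eta = 1 jumps to x exactly."""
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    if w.shape != x.shape:
        raise ValueError("weight/profile dimension mismatch")
    if not (0 <= eta <= 1 and 0 <= h <= 1):
        raise ValueError("eta and h must lie in [0, 1]")
    return w + eta * h * (x - w)


def pca_initialize(grid: HexGrid, data: np.ndarray) -> np.ndarray:
    """Weights laid on the plane of the two leading principal components.

    The unit at grid position (r, c) receives
    ``mean + alpha(c) * s1 * pc1 + beta(r) * s2 * pc2`` with alpha and beta
    spanning [-1, 1] linearly across columns and rows and s_k the
    per-component standard deviation, so the initial sheet spans the data
    cloud along its two main axes.  Deterministic given the data; with
    fewer than two informative components the available rank is used and a
    warning logged.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 3 or data.shape[1] < 2:
        raise ValueError("need at least 3 profiles of dimension >= 2")
    mean = data.mean(axis=0)
    centered = data - mean
    # SVD of the centered data; right singular vectors are the PC directions
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    n = data.shape[0]
    sd = s / math.sqrt(max(n - 1, 1))
    tol = max(data.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if rank < 2:
        logger.warning("pca_initialize: data rank %d < 2; using available rank", rank)
    alpha = np.linspace(-1.0, 1.0, grid.n_cols) if grid.n_cols > 1 else np.zeros(1)
    beta = np.linspace(-1.0, 1.0, grid.n_rows) if grid.n_rows > 1 else np.zeros(1)
    weights = np.tile(mean, (grid.n_units, 1))
    r = np.repeat(np.arange(grid.n_rows), grid.n_cols)
    c = np.tile(np.arange(grid.n_cols), grid.n_rows)
    if rank >= 1:
        weights += np.outer(alpha[c], sd[0] * vt[0])
    if rank >= 2:
        weights += np.outer(beta[r], sd[1] * vt[1])
    return weights


def quantization_error(data: np.ndarray, weights: np.ndarray) -> float:
    """Mean over profiles of the distance to the nearest weight vector."""
    data = np.asarray(data, dtype=float)
    d2 = ((data[:, None, :] - weights[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.min(axis=1)).mean())


def train(data: ExpressionDataset | np.ndarray, config: TrainingConfig,
          database_name: str | None = None) -> SomModel:
    """Train a map on fully observed [0, 1]-fraction profiles.

    Sequential training with PCA initialization; per epoch ``n`` the radius
    decays linearly from ``sigma0`` to ``sigma_final`` and the learning
    rate follows ``lr0 / (1 + 100 n / T)``.  Bit-deterministic given the
    config (including seed and presentation order).
    """
    if isinstance(data, ExpressionDataset):
        if data.missing_mask.any():
            raise ValueError("training data must be fully observed (impute first)")
        if data.scale != "fraction01":
            raise ValueError("training data must be on the fraction01 scale")
        name = database_name or data.database_name
        matrix = np.asarray(data.values, dtype=float)
    else:
        name = database_name or ""
        matrix = np.asarray(data, dtype=float)
    if matrix.size == 0:
        raise ValueError("empty dataset")
    n_genes, dim = matrix.shape
    if dim == 1:
        logger.warning("training on 1-dimensional profiles")
    grid = config.grid
    weights = pca_initialize(grid, matrix) if n_genes >= 3 else np.tile(
        matrix.mean(axis=0), (grid.n_units, 1)
    )
    lateral = grid.pairwise_distances()
    n_epochs = epochs_for(grid, n_genes, config.epochs_multiplier)
    rng = np.random.default_rng(config.rng_seed)
    qe_history = [quantization_error(matrix, weights)]
    for epoch in range(n_epochs):
        frac = epoch / max(n_epochs - 1, 1)
        sigma = config.sigma0 + (config.sigma_final - config.sigma0) * frac
        eta = config.lr0 / (1.0 + 100.0 * epoch / n_epochs)
        if config.presentation_order == "shuffled_per_epoch":
            order = rng.permutation(n_genes)
        else:
            order = np.arange(n_genes)
        for gi in order:
            x = matrix[gi]
            bmu = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
            h = np.exp(-(lateral[bmu] ** 2) / (2.0 * sigma ** 2))
            weights += (eta * h)[:, None] * (x - weights)
        qe_history.append(quantization_error(matrix, weights))
    return SomModel(grid=grid, weights=weights, config=config,
                    trained_on=name, qe_history=qe_history)


# ---------------------------------------------------------------------------
# persistence: JSON header + TSV weight matrix
# ---------------------------------------------------------------------------

def save_model(model: SomModel, header_path: str | Path, weights_path: str | Path) -> None:
    header = {
        "n_rows": model.grid.n_rows,
        "n_cols": model.grid.n_cols,
        "trained_on": model.trained_on,
        "config": asdict(model.config),
        "qe_history": model.qe_history,
    }
    with open(header_path, "w", encoding="utf-8") as fh:
        json.dump(header, fh, indent=1)
    with open(weights_path, "w", encoding="utf-8") as fh:
        fh.write("unit\t" + "\t".join(f"w{i}" for i in range(model.dim)) + "\n")
        for label, row in enumerate(model.weights, start=1):
            fh.write(str(label) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def load_model(header_path: str | Path, weights_path: str | Path) -> SomModel:
    with open(header_path, encoding="utf-8") as fh:
        header = json.load(fh)
    rows = []
    with open(weights_path, encoding="utf-8") as fh:
        next(fh)  # header line
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in fields[1:]])
    config = TrainingConfig(**header["config"])
    return SomModel(
        grid=HexGrid(header["n_rows"], header["n_cols"]),
        weights=np.array(rows, dtype=float),
        config=config,
        trained_on=header["trained_on"],
        qe_history=list(header.get("qe_history", [])),
    )
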
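"""Readers and writers for expression matrices and gene catalogs.

Two on-disk dialects are supported for gene x time-point expression
matrices:

``tsv``
    Header row of sample labels; first column gene id; one row per gene.
    Empty fields, ``NA`` and ``NaN`` (case-insensitive) are missing.

``som_toolbox_data``
    The SOM Toolbox data-file convention: first non-comment line is the
    integer dimensionality, optional ``#n`` (component names) and ``#l``
    directive lines, then one whitespace-separated vector per row with a
    trailing gene label.  ``x`` is additionally treated as missing.

Gene catalogs are CSV files with columns ``standard_name``,
``systematic_name`` and ``aliases`` (semicolon-separated).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "GeneCatalog",
    "GeneRecord",
    "ParseError",
    "ValidationError",
    "read_expression_table",
    "write_expression_table",
    "read_gene_catalog",
    "write_gene_catalog",
]

#: scales an ExpressionDataset may carry
SCALES = ("log2-ratio", "log10-ratio", "fraction01")

MISSING_TOKENS = {"", "na", "nan"}
MISSING_TOKENS_SOM = MISSING_TOKENS | {"x"}

_TIME_PATTERN = re.compile(r"(?:^|[^0-9])(\d+)\s*(?:min)?\s*$", re.IGNORECASE)


class ParseError(ValueError):
    """Raised when a file cannot be parsed; the message names the line."""


class ValidationError(ValueError):
    """Raised when parsed content violates a dataset/catalog invariant."""


@dataclass
class ExpressionDataset:
    """A gene x time-point expression matrix from one database.

    Parameters
    ----------
    database_name : str
        Label of the source experiment (e.g. ``alpha30``).
    gene_ids : list of str
        Unique gene identifiers, one per matrix row.
    sample_times : ndarray
        Minutes since release, strictly increasing, one per column.
    values : ndarray, shape (n_genes, n_samples)
        Expression values; entries under ``missing_mask`` are undefined.
    missing_mask : ndarray of bool, same shape as ``values``
    scale : {"log2-ratio", "log10-ratio", "fraction01"}
    phase_labels : list of str, optional
        Cell-cycle phase tag per sample (M/G1, G1, S, G2, M).
    """

    database_name: str
    gene_ids: list[str]
    sample_times: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray
    scale: str = "log2-ratio"
    phase_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_genes, n_samples = len(self.gene_ids), len(self.sample_times)
        if self.values.shape != (n_genes, n_samples):
            raise ValidationError(
                f"values shape {self.values.shape} != ({n_genes}, {n_samples})"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValidationError("missing_mask shape differs from values")
        if n_samples > 1 and not np.all(np.diff(self.sample_times) > 0):
            raise ValidationError("sample_times must be strictly increasing")
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        seen: set[str] = set()
        for g in self.gene_ids:
            key = g.strip().lower()
            if key in seen:
                raise ValidationError(f"duplicate gene id {g!r}")
            seen.add(key)
        if self.scale == "fraction01":
            obs = self.values[~self.missing_mask]
            if obs.size and (obs.min() < -1e-12 or obs.max() > 1 + 1e-12):
                raise ValidationError("fraction01 values must lie in [0, 1]")
        if self.phase_labels is not None and len(self.phase_labels) != n_samples:
            raise ValidationError("phase_labels length differs from samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_times)

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            database_name=self.database_name,
            gene_ids=list(self.gene_ids),
            sample_times=self.sample_times.copy(),
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            scale=self.scale,
            phase_labels=list(self.phase_labels) if self.phase_labels else None,
        )

    def subset(self, indices: Sequence[int]) -> "ExpressionDataset":
        """Dataset restricted to the given gene rows, order preserved."""
        idx = list(indices)
        return ExpressionDataset(
            database_name=self.database_name,
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_times=self.sample_times.copy(),
            values=self.values[idx].copy(),
            missing_mask=self.missing_mask[idx].copy(),
            scale=self.scale,
            phase_labels=list(self.phase_labels) if self.phase_labels else None,
        )

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            self.database_name == other.database_name
            and self.gene_ids == other.gene_ids
            and np.allclose(self.sample_times, other.sample_times)
            and np.array_equal(self.missing_mask, other.missing_mask)
            and np.allclose(
                np.where(self.missing_mask, 0.0, self.values),
                np.where(other.missing_mask, 0.0, other.values),
            )
            and self.scale == other.scale
        )


@dataclass(frozen=True)
class GeneRecord:
    standard_name: str
    systematic_name: str
    aliases: tuple[str, ...] = ()


@dataclass
class GeneCatalog:
    """Standard/systematic/alias gene-name mapping.

    Lookup by any name (case-insensitive, trimmed) resolves to at most one
    record; resolution priority is systematic name, then standard name,
    then aliases.
    """

    records: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[str, GeneRecord] = {}
        self._build_index()

    @staticmethod
    def _key(name: str) -> str:
        return name.strip().lower()

    def _build_index(self) -> None:
        # systematic first, then standard, then aliases: earlier tiers win,
        # collisions across records within a tier are ambiguous
        self._index.clear()
        owner: dict[str, GeneRecord] = {}
        systematic_seen: set[str] = set()
        for rec in self.records:
            k = self._key(rec.systematic_name)
            if k in systematic_seen:
                raise ValidationError(f"duplicate systematic name {rec.systematic_name!r}")
            systematic_seen.add(k)
        for tier in ("systematic", "standard", "alias"):
            for rec in self.records:
                if tier == "systematic":
                    names: Iterable[str] = [rec.systematic_name]
                elif tier == "standard":
                    names = [rec.standard_name] if rec.standard_name else []
                else:
                    names = rec.aliases
                for name in names:
                    k = self._key(name)
                    if not k:
                        continue
                    if k in owner and owner[k] is not rec:
                        raise ValidationError(
                            f"gene name {name!r} resolves to both "
                            f"{owner[k].systematic_name!r} and {rec.systematic_name!r}"
                        )
                    if k not in owner:
                        owner[k] = rec
        self._index = owner

    def __len__(self) -> int:
        return len(self.records)

    def resolve(self, name: str) -> GeneRecord | None:
        """Record for any standard/systematic/alias name, or None."""
        return self._index.get(self._key(name))


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def _parse_value(token: str, missing_tokens: set[str]) -> tuple[float, bool]:
    t = token.strip()
    if t.lower() in missing_tokens:
        return (np.nan, True)
    try:
        return (float(t), False)
    except ValueError as exc:
        raise ParseError(f"cannot parse value {token!r}") from exc


def _times_from_labels(labels: Sequence[str]) -> np.ndarray:
    """Sample times from header labels; integer-minute pattern or index units."""
    times = []
    for lab in labels:
        lab = lab.split("|")[0]  # drop any trailing phase tag
        m = _TIME_PATTERN.search(lab.strip())
        if m is None:
            logger.warning(
                "sample labels carry no integer-minute pattern; using 0,1,2,... index units"
            )
            return np.arange(len(labels), dtype=float)
        times.append(float(m.group(1)))
    arr = np.array(times)
    if len(arr) > 1 and not np.all(np.diff(arr) > 0):
        logger.warning("parsed sample times not increasing; using index units")
        return np.arange(len(labels), dtype=float)
    return arr


def read_expression_table(
    path: str | Path,
    dialect: str = "tsv",
    database_name: str | None = None,
) -> ExpressionDataset:
    """Read an expression matrix in the ``tsv`` or ``som_toolbox_data`` dialect.

    Missing cells (empty fields, ``NA``/``NaN``, plus ``x`` in the toolbox
    dialect) are flagged in ``missing_mask``; all other values are returned
    untouched.  Raises :class:`ParseError` naming the offending line for
    malformed rows and :class:`ValidationError` for duplicate gene ids.
    """
    path = Path(path)
    name = database_name or path.stem
    if dialect == "tsv":
        return _read_tsv(path, name)
    if dialect == "som_toolbox_data":
        return _read_som_toolbox(path, name)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path: Path, name: str) -> ExpressionDataset:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    labels = header[1:]
    n_samples = len(labels)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    mask_rows: list[list[bool]] = []
    scale = "log2-ratio"
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if line.startswith("#"):
            # scale is recorded in a trailing comment by write_expression_table;
            # absent in external files, where log2-ratio is assumed
            if line.startswith("# scale:"):
                scale = line[len("# scale:"):].strip()
            continue
        fields = line.split("\t")
        if len(fields) != n_samples + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {n_samples + 1} fields, got {len(fields)}"
            )
        gene_ids.append(fields[0].strip())
        vals, miss = zip(*(_parse_value(t, MISSING_TOKENS) for t in fields[1:]))
        rows.append(list(vals))
        mask_rows.append(list(miss))
    return ExpressionDataset(
        database_name=name,
        gene_ids=gene_ids,
        sample_times=_times_from_labels(labels),
        values=np.array(rows, dtype=float).reshape(len(gene_ids), n_samples),
        missing_mask=np.array(mask_rows, dtype=bool).reshape(len(gene_ids), n_samples),
        scale=scale,
        phase_labels=_phases_from_labels(labels),
    )


def _phases_from_labels(labels: Sequence[str]) -> list[str] | None:
    phases = []
    for lab in labels:
        parts = lab.split("|")
        if len(parts) == 2:
            phases.append(parts[1].strip())
        else:
            return None
    return phases


def _read_som_toolbox(path: Path, name: str) -> ExpressionDataset:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    dim: int | None = None
    component_names: list[str] | None = None
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    mask_rows: list[list[bool]] = []
    declared_scale: str | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#c") or line.startswith("%"):
            if line.startswith("#c scale:"):
                declared_scale = line[len("#c scale:"):].strip()
            continue
        if dim is None:
            try:
                dim = int(line.split()[0])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: first line must declare dimensionality") from exc
            continue
        if line.startswith("#n"):
            component_names = line.split()[1:]
            continue
        if line.startswith("#l"):
            continue
        tokens = line.split()
        if len(tokens) == dim + 1:
            label = tokens[-1]
            data_tokens = tokens[:-1]
        elif len(tokens) == dim:
            label = f"row{len(gene_ids) + 1}"
            data_tokens = tokens
        else:
            raise ParseError(
                f"{path}:{lineno}: expected {dim} components (+ optional label), got {len(tokens)}"
            )
        try:
            vals, miss = zip(*(_parse_value(t, MISSING_TOKENS_SOM) for t in data_tokens))
        except ParseError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        gene_ids.append(label.strip())
        rows.append(list(vals))
        mask_rows.append(list(miss))
    if dim is None:
        raise ParseError(f"{path}: no dimensionality line found")
    labels = component_names if component_names and len(component_names) == dim else [str(i) for i in range(dim)]
    values = np.array(rows, dtype=float).reshape(len(gene_ids), dim)
    mask = np.array(mask_rows, dtype=bool).reshape(len(gene_ids), dim)
    obs = values[~mask]
    if declared_scale in SCALES:
        scale = declared_scale
    else:
        # external toolbox files carry no scale; values in [0, 1] are fractions
        scale = (
            "fraction01"
            if obs.size and obs.min() >= 0 and obs.max() <= 1
            else "log2-ratio"
        )
    return ExpressionDataset(
        database_name=name,
        gene_ids=gene_ids,
        sample_times=_times_from_labels(labels),
        values=values,
        missing_mask=mask,
        scale=scale,
        phase_labels=_phases_from_labels(labels),
    )


def write_expression_table(
    dataset: ExpressionDataset, path: str | Path, dialect: str = "tsv"
) -> Path:
    """Write a dataset so that :func:`read_expression_table` recovers it."""
    path = Path(path)
    dataset.validate()
    if dialect == "tsv":
        _write_tsv(dataset, path)
    elif dialect == "som_toolbox_data":
        _write_som_toolbox(dataset, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def _sample_labels(dataset: ExpressionDataset) -> list[str]:
    labels = []
    for i, t in enumerate(dataset.sample_times):
        lab = f"{int(t)}min" if float(t).is_integer() else f"{t}min"
        if dataset.phase_labels is not None:
            lab = f"{lab}|{dataset.phase_labels[i]}"
        labels.append(lab)
    return labels


def _format_value(v: float, missing: bool, sentinel: str) -> str:
    return sentinel if missing else repr(float(v))


def _write_tsv(dataset: ExpressionDataset, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(_sample_labels(dataset)) + "\n")
        for g, row, mrow in zip(dataset.gene_ids, dataset.values, dataset.missing_mask):
            cells = [_format_value(v, m, "NA") for v, m in zip(row, mrow)]
            fh.write(g + "\t" + "\t".join(cells) + "\n")
        fh.write(f"# scale: {dataset.scale}\n")


def _write_som_toolbox(dataset: ExpressionDataset, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{dataset.n_samples}\n")
        fh.write(f"#c scale: {dataset.scale}\n")
        fh.write("#n " + " ".join(_sample_labels(dataset)) + "\n")
        for g, row, mrow in zip(dataset.gene_ids, dataset.values, dataset.missing_mask):
            cells = [_format_value(v, m, "x") for v, m in zip(row, mrow)]
            fh.write(" ".join(cells) + " " + g + "\n")


# ---------------------------------------------------------------------------
# gene catalogs
# ---------------------------------------------------------------------------

def read_gene_catalog(path: str | Path) -> GeneCatalog:
    """Read a gene catalog CSV (standard_name, systematic_name, aliases).

    Aliases are semicolon-separated.  Duplicate systematic names or a name
    resolving to two records raise :class:`ValidationError`; an empty file
    yields an empty catalog with a logged warning.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            logger.warning("%s: empty gene catalog", path)
            return GeneCatalog([])
        cols = {c.strip().lower(): c for c in reader.fieldnames}
        if "systematic_name" not in cols:
            raise ParseError(f"{path}: missing systematic_name column")
        for row in reader:
            systematic = (row[cols["systematic_name"]] or "").strip()
            standard = (row.get(cols.get("standard_name", ""), "") or "").strip()
            raw_aliases = (row.get(cols.get("aliases", ""), "") or "").strip()
            aliases = tuple(a.strip() for a in raw_aliases.split(";") if a.strip())
            if not systematic:
                continue
            records.append(GeneRecord(standard, systematic, aliases))
    if not records:
        logger.warning("%s: empty gene catalog", path)
    return GeneCatalog(records)


def write_gene_catalog(catalog: GeneCatalog, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["standard_name", "systematic_name", "aliases"])
        for rec in catalog.records:
            writer.writerow([rec.standard_name, rec.systematic_name, ";".join(rec.aliases)])
    return path
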
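"""Tabular input/output and validated domain containers.

All on-disk formats are plain text: tab-delimited expression matrices
(first column gene id, remaining columns numeric), 2-3 column edge lists,
GMT gene sets, and tab-delimited result tables with ``#`` header comments.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("turnpoint")

#: accepted missing-value spellings (case-insensitive); anything else that
#: fails to parse as a float is a hard error, not a silent NA.
NA_STRINGS = frozenset({"", "na", "nan"})


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


class ParseError(ValueError):
    """Raised when a file cell cannot be interpreted."""


# ---------------------------------------------------------------------------
# time grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing observation times (hours), at least three."""

    times: tuple[float, ...]

    def __init__(self, times) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in times))
        t = np.asarray(self.times, dtype=float)
        if t.size < 3:
            raise ValidationError(
                f"need at least 3 time points, got {t.size}"
            )
        if not np.all(np.isfinite(t)):
            raise ValidationError("non-finite time stamp")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("time stamps must be strictly increasing")

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def intervals(self) -> np.ndarray:
        """Interval widths Delta-h (hours), length T-1."""
        return np.diff(np.asarray(self.times, dtype=float))

    @property
    def span(self) -> float:
        return self.times[-1] - self.times[0]


# ---------------------------------------------------------------------------
# expression series
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSeries:
    """gene x time x replicate intensity array with a missingness mask.

    ``mask`` is True where the value is missing.  ``scale`` records the
    transform state: 'linear' (non-negative intensities) or 'log'
    (log10 intensities, any sign).
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray  # (G, T, R) float
    mask: np.ndarray  # (G, T, R) bool, True = missing
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValidationError("values must be gene x time x replicate")
        if self.mask.shape != self.values.shape:
            raise ValidationError("mask shape differs from values shape")
        if self.scale not in ("linear", "log"):
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted(
                {g for g in self.gene_ids if self.gene_ids.count(g) > 1}
            )
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValidationError("gene_ids length differs from values rows")
        obs = self.values[~self.mask]
        if not np.all(np.isfinite(obs)):
            raise ValidationError("non-finite unmasked value")
        if self.scale == "linear" and obs.size and obs.min() < 0:
            raise ValidationError("negative intensity on linear scale")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def n_reps(self) -> int:
        return self.values.shape[2]

    # -- transforms ---------------------------------------------------------

    def to_linear(self) -> "ExpressionSeries":
        if self.scale == "linear":
            return self
        vals = np.power(10.0, self.values)
        return ExpressionSeries(self.gene_ids, vals, self.mask.copy(), "linear")

    def to_log10(self) -> "ExpressionSeries":
        if self.scale == "log":
            return self
        obs = self.values[~self.mask]
        if obs.size and obs.min() <= 0:
            raise ValidationError("cannot log-transform non-positive values")
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.log10(self.values)
        return ExpressionSeries(self.gene_ids, vals, self.mask.copy(), "log")

    def consensus_linear(self) -> np.ndarray:
        """Geometric mean over replicates, (G, T), requires no missing cells."""
        if self.mask.any():
            raise ValidationError("consensus requires a fully observed series")
        logv = self.to_log10().values
        return np.power(10.0, logv.mean(axis=2))

    def subset(self, gene_ids) -> "ExpressionSeries":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionSeries(
            tuple(gene_ids),
            self.values[rows],
            self.mask[rows],
            self.scale,
        )


# ---------------------------------------------------------------------------
# column layout for expression tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnLayout:
    """Mapping from data columns to (time index, replicate index)."""

    n_times: int
    n_reps: int
    assignments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        expect = {(t, r) for t in range(self.n_times) for r in range(self.n_reps)}
        got = set(self.assignments)
        if got != expect or len(self.assignments) != len(expect):
            raise ValidationError(
                "layout must assign every (time, replicate) cell exactly once"
            )

    @classmethod
    def time_major(cls, n_times: int, n_reps: int) -> "ColumnLayout":
        """Columns ordered t0r0, t0r1, ..., t1r0, ... (the default layout)."""
        assign = tuple(
            (t, r) for t in range(n_times) for r in range(n_reps)
        )
        return cls(n_times, n_reps, assign)

    @classmethod
    def replicate_major(cls, n_times: int, n_reps: int) -> "ColumnLayout":
        assign = tuple(
            (t, r) for r in range(n_reps) for t in range(n_times)
        )
        return cls(n_times, n_reps, assign)

    def __len__(self) -> int:
        return len(self.assignments)


# ---------------------------------------------------------------------------
# paired dataset
# ---------------------------------------------------------------------------


@dataclass
class PairedDataset:
    """Template layer (mRNA or constant DNA) + product layer on one grid."""

    template: ExpressionSeries
    product: ExpressionSeries
    grid: TimeGrid

    def __post_init__(self) -> None:
        if self.template.gene_ids != self.product.gene_ids:
            raise ValidationError("template and product gene ids differ")
        for s in (self.template, self.product):
            if s.n_times != self.grid.n_times:
                raise ValidationError("series length differs from time grid")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return self.template.gene_ids


@dataclass(frozen=True)
class PairReport:
    """Genes dropped when intersecting the two layers of a PairedDataset."""

    dropped_template: tuple[str, ...]
    dropped_product: tuple[str, ...]


def pair_series(
    template: ExpressionSeries, product: ExpressionSeries, grid: TimeGrid
) -> tuple[PairedDataset, PairReport]:
    """Intersect gene lists and build a PairedDataset plus a drop report."""
    product_set = set(product.gene_ids)
    shared = [g for g in template.gene_ids if g in product_set]
    if not shared:
        raise ValidationError("no genes shared between template and product")
    shared_set = set(shared)
    report = PairReport(
        dropped_template=tuple(
            g for g in template.gene_ids if g not in shared_set
        ),
        dropped_product=tuple(
            g for g in product.gene_ids if g not in shared_set
        ),
    )
    if report.dropped_template or report.dropped_product:
        logger.info(
            "pair_series dropped=%d(template)+%d(product) kept=%d",
            len(report.dropped_template),
            len(report.dropped_product),
            len(shared),
        )
    return (
        PairedDataset(template.subset(shared), product.subset(shared), grid),
        report,
    )


def make_rna_level_dataset(
    rna: ExpressionSeries, grid: TimeGrid
) -> PairedDataset:
    """Pair an RNA series with a constant unit template (DNA copy number)."""
    template = ExpressionSeries(
        rna.gene_ids,
        np.ones_like(rna.values),
        np.zeros(rna.values.shape, dtype=bool),
        "linear",
    )
    return PairedDataset(template, rna, grid)


# ---------------------------------------------------------------------------
# expression table reader
# ---------------------------------------------------------------------------


def _parse_cell(raw: str, row: str, col: str) -> float:
    text = raw.strip()
    if text.lower() in NA_STRINGS:
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"malformed numeric cell {raw!r} at gene {row!r}, column {col!r}"
        ) from None


def filter_missing_cap(
    series: ExpressionSeries, cap: int = 2
) -> tuple[ExpressionSeries, tuple[str, ...]]:
    """Drop genes with more than ``cap`` missing time points in any replicate."""
    per_rep_missing = series.mask.sum(axis=1)  # (G, R)
    bad = (per_rep_missing > cap).any(axis=1)
    excluded = tuple(g for g, b in zip(series.gene_ids, bad) if b)
    if excluded:
        logger.warning(
            "missing-cap filter cap=%d excluded=%d genes: %s",
            cap,
            len(excluded),
            ",".join(excluded[:10]),
        )
    kept = [g for g, b in zip(series.gene_ids, bad) if not b]
    return series.subset(kept), excluded


def read_expression_table(
    path,
    layout: ColumnLayout,
    scale: str = "linear",
    max_missing_per_rep: int | None = 2,
    return_excluded: bool = False,
):
    """Read a tab-delimited gene x (time x replicate) matrix.

    The first column holds gene ids; the remaining columns are mapped to
    (time, replicate) cells through ``layout``.  Empty cells, 'NA' and 'NaN'
    (case-insensitive) are treated as missing; any other non-numeric cell is
    a :class:`ParseError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] != len(layout) + 1:
        raise ValidationError(
            f"table has {df.shape[1] - 1} data columns, layout expects "
            f"{len(layout)}"
        )
    gene_ids = [str(g).strip() for g in df.iloc[:, 0]]
    if len(set(gene_ids)) != len(gene_ids):
        seen, dupes = set(), []
        for g in gene_ids:
            if g in seen:
                dupes.append(g)
            seen.add(g)
        raise ValidationError(f"duplicate gene ids in table: {dupes[:5]}")
    n_genes = len(gene_ids)
    values = np.full((n_genes, layout.n_times, layout.n_reps), np.nan)
    data_cols = list(df.columns[1:])
    for j, col in enumerate(data_cols):
        t, r = layout.assignments[j]
        raw = df[col].astype(object)
        for i in range(n_genes):
            cell = raw.iloc[i]
            values[i, t, r] = _parse_cell(
                "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell),
                gene_ids[i],
                col,
            )
    mask = ~np.isfinite(values)
    values = np.where(mask, np.nan, values)
    series = ExpressionSeries(tuple(gene_ids), values, mask, scale)
    excluded: tuple[str, ...] = ()
    if max_missing_per_rep is not None:
        series, excluded = filter_missing_cap(series, max_missing_per_rep)
    if return_excluded:
        return series, excluded
    return series


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Network:
    """Undirected gene-gene network without self-loops."""

    edges: frozenset

    def __init__(self, edges) -> None:
        norm = set()
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValidationError(f"self-loop edge {a!r}")
            norm.add((a, b) if a < b else (b, a))
        object.__setattr__(self, "edges", frozenset(norm))

    @property
    def genes(self) -> frozenset:
        out = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return frozenset(out)

    def restrict(self, gene_ids) -> tuple["Network", dict]:
        """Drop edges with endpoints outside ``gene_ids``; report coverage."""
        keep = set(gene_ids)
        kept_edges = [e for e in self.edges if e[0] in keep and e[1] in keep]
        net_genes = self.genes
        matched = net_genes & keep
        coverage = {
            "network_genes": len(net_genes),
            "dataset_genes": len(keep),
            "matched_genes": len(matched),
            "network_coverage": (
                len(matched) / len(net_genes) if net_genes else 0.0
            ),
            "dataset_coverage": len(matched) / len(keep) if keep else 0.0,
            "edges_kept": len(kept_edges),
            "edges_total": len(self.edges),
        }
        return Network(kept_edges), coverage

    def adjacency(self, gene_ids) -> list[np.ndarray]:
        """Neighbor index arrays aligned with ``gene_ids`` order."""
        index = {g: i for i, g in enumerate(gene_ids)}
        nbrs: list[list[int]] = [[] for _ in gene_ids]
        for a, b in self.edges:
            if a in index and b in index:
                nbrs[index[a]].append(index[b])
                nbrs[index[b]].append(index[a])
        return [np.asarray(sorted(n), dtype=int) for n in nbrs]


def read_network_edges(path, min_score: float = 0.0) -> Network:
    """Read a 2-3 column tab-separated edge list (optional STRING-like score)."""
    edges = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ParseError(
                    f"edge line {ln} has {len(parts)} columns, expected 2-3"
                )
            a, b = parts[0].strip(), parts[1].strip()
            if a == b:
                logger.warning("dropping self-loop edge %r at line %d", a, ln)
                continue
            if len(parts) == 3:
                try:
                    score = float(parts[2])
                except ValueError:
                    raise ParseError(
                        f"malformed score {parts[2]!r} at line {ln}"
                    ) from None
                if not 0 <= score <= 1000:
                    raise ValidationError(
                        f"score {score} outside [0, 1000] at line {ln}"
                    )
                if score < min_score:
                    continue
            edges.append((a, b))
    return Network(edges)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSetCollection:
    sets: dict
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gene_sets_gmt(path) -> GeneSetCollection:
    """Read the standard GMT format: name <tab> description <tab> genes..."""
    sets: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"GMT line {ln} has fewer than 1 gene"
                )
            name = parts[0].strip()
            if name in sets:
                raise ValidationError(f"duplicate gene set name {name!r}")
            genes = tuple(g.strip() for g in parts[2:] if g.strip())
            if not genes:
                raise ValidationError(f"GMT line {ln} has fewer than 1 gene")
            sets[name] = genes
    return GeneSetCollection(sets, source=str(path))


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

TABLE_FLOAT_FORMAT = "%.10g"


def config_digest(config) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, comments=()) -> None:
    """Write a tab-delimited table with '#' header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=TABLE_FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_results(tables: dict, out_dir, config=None, version: str | None = None) -> dict:
    """Write named result tables under ``out_dir``; returns name -> path."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    comments = [f"turnpoint {version or __version__}"]
    if config is not None:
        comments.append(f"config_hash={config_digest(config)}")
    paths = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        write_table(df, p, comments=comments)
        paths[name] = p
    return paths
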
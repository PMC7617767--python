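"""Domain containers and readers/writers for the standard interchange formats.

Formats handled: GMT gene-set collections (mSigDB dialect), RNK pre-ranked
lists (two tab-separated columns, descending metric), dense TSV expression
matrices (header row = sample ids, first column = gene id), Matrix Market
coordinate triplets with sidecar row/column identifier files, and
tab-delimited differential-expression result tables.

Gene identifiers are opaque, case-sensitive strings throughout; any
cross-species mapping is explicit (see :func:`vmsig.signatures.map_orthologs`).
All loaders validate their type invariants and reject rather than coerce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "GeneSet",
    "GeneSetCollection",
    "DEResultTable",
    "ExpressionMatrix",
    "CountMatrix",
    "RankedList",
    "read_gmt",
    "write_gmt",
    "read_de_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_count_matrix",
    "read_rnk",
    "write_rnk",
]


class FormatError(ValueError):
    """A file violates its format contract (malformed line, bad dimensions)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers.

    Parameters
    ----------
    name
        Non-empty set name (unique within a collection).
    members
        Non-empty, duplicate-free gene identifiers.
    description
        Free-text description (GMT column 2).
    """

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def intersect(self, universe: Iterable[str]) -> frozenset[str]:
        """Members present in ``universe``."""
        return self.members & frozenset(universe)


class GeneSetCollection:
    """An ordered collection of :class:`GeneSet` with unique names."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: list[GeneSet] = list(sets)
        names = [s.name for s in self._sets]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate gene set names: {sorted(dupes)}")
        self._by_name = {s.name: s for s in self._sets}

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __getitem__(self, key: int | str) -> GeneSet:
        if isinstance(key, str):
            return self._by_name[key]
        return self._sets[key]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._sets]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneSetCollection({len(self)} sets)"


class DEResultTable:
    """Per-gene differential-expression statistics for one comparison.

    Holds columns ``gene`` (unique identifiers), ``log2fc`` (finite, log2
    units), ``pvalue`` and ``fdr`` (both in [0, 1] where present).  These
    tables are the outputs of upstream DE model fits (DESeq2, Limma) and the
    raw material for signature derivation.
    """

    COLUMNS = ("gene", "log2fc", "pvalue", "fdr")

    def __init__(self, comparison_name: str, data: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"DE table missing columns {missing}")
        df = data.loc[:, list(self.COLUMNS)].reset_index(drop=True).copy()
        df["gene"] = df["gene"].astype(str)
        if df["gene"].duplicated().any():
            dupes = df.loc[df["gene"].duplicated(), "gene"].unique()[:5]
            raise ValueError(f"duplicate gene identifiers in DE table: {list(dupes)} ...")
        if not np.isfinite(df["log2fc"].to_numpy(dtype=float)).all():
            raise ValueError("log2fc values must be finite")
        for col in ("pvalue", "fdr"):
            vals = df[col].to_numpy(dtype=float)
            ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
            if not ok.all():
                raise ValueError(f"{col} values must lie in [0, 1]")
        self.comparison_name = comparison_name
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.data["gene"])

    def indexed(self) -> pd.DataFrame:
        """The table indexed by gene identifier."""
        return self.data.set_index("gene")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DEResultTable({self.comparison_name!r}, {len(self)} genes)"


class ExpressionMatrix:
    """A real-valued genes x samples matrix with a declared value scale.

    ``value_scale`` is one of ``linear``, ``log``, ``zscore`` and records how
    downstream consumers must interpret the values (e.g. marker fold changes
    linearise ``log`` values first).
    """

    SCALES = ("linear", "log", "zscore")

    def __init__(self, values: pd.DataFrame, value_scale: str = "linear"):
        if value_scale not in self.SCALES:
            raise ValueError(f"value_scale must be one of {self.SCALES}")
        if values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        arr = values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("expression matrix contains missing values")
        self.values = values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        self.values.index.name = None
        self.values.columns.name = None
        self.value_scale = value_scale

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.value_scale)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples, scale={self.value_scale})"


class CountMatrix:
    """A sparse non-negative integer genes x cells count matrix."""

    def __init__(
        self,
        counts: scipy.sparse.spmatrix | np.ndarray,
        gene_ids: Sequence[str],
        cell_ids: Sequence[str],
    ):
        mat = scipy.sparse.csr_matrix(counts)
        gene_ids = pd.Index([str(g) for g in gene_ids])
        cell_ids = pd.Index([str(c) for c in cell_ids])
        if gene_ids.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if cell_ids.duplicated().any():
            raise ValueError("duplicate cell identifiers")
        if mat.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match identifier lengths "
                f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
            )
        data = mat.data
        if data.size and (data < 0).any():
            raise ValueError("counts must be non-negative")
        if data.size and not np.allclose(data, np.round(data)):
            raise ValueError("counts must be integral")
        mat.data = np.asarray(np.round(data), dtype=np.int64)
        mat.eliminate_zeros()
        self.counts = mat
        self.gene_ids = gene_ids
        self.cell_ids = cell_ids

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def cell_totals(self) -> np.ndarray:
        """Library size (total counts) per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def to_frame(self) -> pd.DataFrame:
        """Dense genes x cells DataFrame (small matrices only)."""
        return pd.DataFrame(
            self.counts.toarray(), index=self.gene_ids, columns=self.cell_ids
        )

    def subset(
        self,
        genes: Sequence[str] | None = None,
        cells: Sequence[str] | None = None,
    ) -> "CountMatrix":
        gi = (
            self.gene_ids.get_indexer(pd.Index(genes))
            if genes is not None
            else np.arange(len(self.gene_ids))
        )
        ci = (
            self.cell_ids.get_indexer(pd.Index(cells))
            if cells is not None
            else np.arange(len(self.cell_ids))
        )
        if (np.asarray(gi) < 0).any() or (np.asarray(ci) < 0).any():
            raise KeyError("unknown gene or cell identifiers in subset request")
        sub = self.counts[gi, :][:, ci]
        return CountMatrix(sub, self.gene_ids[gi], self.cell_ids[ci])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, c = self.shape
        return f"CountMatrix({g} genes x {c} cells, nnz={self.counts.nnz})"


class RankedList:
    """Genes ordered by a real ranking metric, non-increasing.

    Ties in the metric preserve the order in which pairs were supplied
    (stable sort); genes are unique.
    """

    def __init__(self, pairs: Iterable[tuple[str, float]] | pd.Series):
        if isinstance(pairs, pd.Series):
            series = pairs.astype(float)
            series.index = series.index.astype(str)
        else:
            pairs = list(pairs)
            series = pd.Series(
                [float(m) for _, m in pairs],
                index=pd.Index([str(g) for g, _ in pairs]),
                dtype=float,
            )
        if series.index.duplicated().any():
            raise ValueError("duplicate genes in ranked list")
        if not np.isfinite(series.to_numpy()).all():
            raise ValueError("ranking metrics must be finite")
        self.series = series.sort_values(ascending=False, kind="stable")

    @property
    def genes(self) -> pd.Index:
        return self.series.index

    @property
    def metrics(self) -> np.ndarray:
        return self.series.to_numpy()

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.series.items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RankedList):
            return NotImplemented
        return self.series.equals(other.series)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RankedList({len(self)} genes)"


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set collection (name, description, members per line).

    Duplicate members within a line are collapsed with a logged warning;
    a line with fewer than three tab-separated fields or a duplicate set
    name raises :class:`FormatError`.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >=3"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if len(set(members)) < len(members):
                logger.warning(
                    "%s:%d: gene set %r has %d duplicate members (collapsed)",
                    path, lineno, name, len(members) - len(set(members)),
                )
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name=name, description=description, members=frozenset(members)))
    try:
        return GeneSetCollection(sets)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_gmt(collection: GeneSetCollection | Iterable[GeneSet], path: str | Path) -> None:
    """Write a gene-set collection in GMT format (members sorted for determinism)."""
    path = Path(path)
    with path.open("w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------

_DE_KEYS = ("gene", "log2fc", "pvalue", "fdr")


def read_de_table(
    path: str | Path,
    column_map: Mapping[str, str],
    comparison_name: str | None = None,
    sep: str = "\t",
) -> DEResultTable:
    """Read a tab-delimited DE result table using a column mapping.

    ``column_map`` maps each of ``gene``, ``log2fc``, ``pvalue``, ``fdr`` to a
    column name in the file.  Rows whose mapped numeric columns do not parse
    are dropped (logged count); duplicate gene rows keep the smallest-FDR row
    (ties: smallest p-value, then first occurrence).
    """
    path = Path(path)
    missing_keys = [k for k in _DE_KEYS if k not in column_map]
    if missing_keys:
        raise ValueError(f"column_map missing keys {missing_keys}")
    raw = pd.read_csv(path, sep=sep)
    missing_cols = [column_map[k] for k in _DE_KEYS if column_map[k] not in raw.columns]
    if missing_cols:
        raise ValueError(
            f"{path}: mapped columns {missing_cols} not found; "
            f"available columns: {list(raw.columns)}"
        )
    df = pd.DataFrame({k: raw[column_map[k]] for k in _DE_KEYS})
    for col in ("log2fc", "pvalue", "fdr"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df["log2fc"].isna() | df["pvalue"].isna() | df["fdr"].isna()
    if bad.any():
        logger.warning("%s: dropped %d rows with unparseable numerics", path, int(bad.sum()))
        df = df.loc[~bad]
    df["gene"] = df["gene"].astype(str)
    if df["gene"].duplicated().any():
        n_before = len(df)
        df = (
            df.assign(_order=np.arange(len(df)))
            .sort_values(["gene", "fdr", "pvalue", "_order"], kind="stable")
            .drop_duplicates("gene", keep="first")
            .sort_values("_order")
            .drop(columns="_order")
        )
        logger.warning(
            "%s: collapsed %d duplicate gene rows (kept min fdr, then min p, then first)",
            path, n_before - len(df),
        )
    return DEResultTable(comparison_name or path.stem, df)


# ---------------------------------------------------------------------------
# Expression / count matrices
# ---------------------------------------------------------------------------


def _read_ids(path: Path, what: str) -> list[str]:
    ids = [line.rstrip("\n") for line in path.open() if line.strip()]
    if not ids:
        raise FormatError(f"{path}: empty {what} identifier file")
    return ids


def read_expression_matrix(
    path: str | Path,
    format: str = "tsv_dense",
    value_scale: str = "linear",
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix | CountMatrix:
    """Read a genes x samples matrix.

    ``format='tsv_dense'``: header row of sample identifiers, first column of
    gene identifiers; returns an :class:`ExpressionMatrix` on ``value_scale``.
    ``format='mtx_triplet'``: Matrix Market coordinate file with sidecar
    identifier files (``genes_path``, ``cells_path``, defaulting to
    ``<stem>.genes.txt`` / ``<stem>.cells.txt`` next to the matrix); entries
    absent from the triplet list are zero; returns a :class:`CountMatrix`.
    """
    path = Path(path)
    if format == "tsv_dense":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.isna().any().any():
            raise FormatError(f"{path}: missing values in dense matrix")
        return ExpressionMatrix(df, value_scale=value_scale)
    if format == "mtx_triplet":
        genes_path = Path(genes_path) if genes_path else path.with_suffix("").with_suffix(".genes.txt")
        cells_path = Path(cells_path) if cells_path else path.with_suffix("").with_suffix(".cells.txt")
        mat = scipy.io.mmread(str(path))
        genes = _read_ids(genes_path, "row")
        cells = _read_ids(cells_path, "column")
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"{path}: matrix shape {mat.shape} does not match identifier files "
                f"({len(genes)} rows, {len(cells)} columns)"
            )
        try:
            return CountMatrix(mat, genes, cells)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    raise ValueError(f"unknown format {format!r}")


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a dense TSV matrix (first column gene id, header = sample ids)."""
    m.values.to_csv(Path(path), sep="\t", index_label="gene")


def write_count_matrix(
    cm: CountMatrix,
    path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> None:
    """Write Matrix Market triplets plus sidecar identifier files."""
    path = Path(path)
    genes_path = Path(genes_path) if genes_path else path.with_suffix("").with_suffix(".genes.txt")
    cells_path = Path(cells_path) if cells_path else path.with_suffix("").with_suffix(".cells.txt")
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.counts))
    genes_path.write_text("".join(f"{g}\n" for g in cm.gene_ids))
    cells_path.write_text("".join(f"{c}\n" for c in cm.cell_ids))


# ---------------------------------------------------------------------------
# RNK
# ---------------------------------------------------------------------------


def read_rnk(path: str | Path) -> RankedList:
    """Read a two-column RNK file (gene<TAB>metric, no header)."""
    path = Path(path)
    pairs: list[tuple[str, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            try:
                metric = float(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable metric {fields[1]!r}") from exc
            pairs.append((fields[0], metric))
    if not pairs:
        logger.warning("%s: empty ranked list", path)
        return RankedList(pd.Series(dtype=float))
    return RankedList(pairs)


def write_rnk(ranked: RankedList, path: str | Path) -> None:
    """Write a RankedList as RNK.

    Metrics are written with Python's shortest round-trip float representation
    so that ``read_rnk(write_rnk(x)) == x`` exactly.
    """
    path = Path(path)
    if len(ranked) == 0:
        logger.warning("%s: writing empty ranked list", path)
    with path.open("w") as fh:
        for gene, metric in ranked:
            fh.write(f"{gene}\t{metric!r}\n")
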
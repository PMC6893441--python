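"""Tabular I/O and validated in-memory containers.

Every table the pipeline touches — expression matrices, cohort annotations,
ChIP-Seq binding-score tables, ortholog maps and gene lists — is read and
written here, as tab-separated UTF-8 with a header row and a configurable
missing-value token (default ``NA``).  Gene symbols are canonicalized
uniformly (uppercase, whitespace-stripped) so joins between expression,
panel and score tables never fail on case or stray whitespace; no alias
resolution is attempted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "canonical_symbol",
    "ExpressionMatrix",
    "CohortAnnotation",
    "BindingScoreTable",
    "OrthologMap",
    "GeneList",
    "read_expression_matrix",
    "write_expression_matrix",
    "median_center",
    "read_annotation",
    "write_annotation",
    "read_binding_table",
    "read_binding_manifest",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_gene_list",
    "write_gene_list",
]

DEFAULT_MISSING = "NA"


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


def canonical_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: uppercase, surrounding whitespace stripped."""
    return str(symbol).strip().upper()


def _check_unique(symbols: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for s in symbols:
        if s in seen:
            raise ValidationError(f"duplicate {what} {s!r}")
        seen.add(s)


# ---------------------------------------------------------------------------
# expression matrix


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values.

    Rows are gene symbols (unique after canonicalization), columns sample
    identifiers.  Missing values are allowed and stored as NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy(deep=False)
        df.index = pd.Index([canonical_symbol(g) for g in df.index], name="gene")
        df.columns = pd.Index([str(c).strip() for c in df.columns], name="sample")
        _check_unique(df.index, "gene symbol")
        _check_unique(df.columns, "sample id")
        self.data = df.astype(float)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __contains__(self, gene: str) -> bool:
        return canonical_symbol(gene) in self.data.index

    def gene_values(self, gene: str) -> np.ndarray:
        """Per-sample values of one gene (raises KeyError if absent)."""
        return self.data.loc[canonical_symbol(gene)].to_numpy()


def read_expression_matrix(
    path: str | os.PathLike,
    sep: str = "\t",
    missing: str = DEFAULT_MISSING,
) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene symbols, header of sample ids)."""
    df = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str,
        keep_default_na=False, na_values=[],
    )
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        cell = raw.where(raw.str.strip() != missing)
        num = pd.to_numeric(cell, errors="coerce")
        bad = num.isna() & cell.notna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"non-numeric cell at gene {gene!r}, sample {col!r} in {path}"
            )
        values[col] = num
    return ExpressionMatrix(values)


def write_expression_matrix(
    mat: ExpressionMatrix,
    path: str | os.PathLike,
    sep: str = "\t",
    missing: str = DEFAULT_MISSING,
) -> None:
    mat.data.to_csv(path, sep=sep, na_rep=missing)


def median_center(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's median (over non-missing samples) from its row.

    Idempotent; missing entries are preserved.  A gene with no observed
    value has no defined median and raises a ``ValidationError``.
    """
    values = mat.data.to_numpy(copy=True)
    observed = np.isfinite(values).sum(axis=1)
    if (observed == 0).any():
        gene = mat.gene_symbols[int(np.argmax(observed == 0))]
        raise ValidationError(f"gene {gene!r} has no observed values; median undefined")
    med = np.nanmedian(values, axis=1, keepdims=True)
    return ExpressionMatrix(
        pd.DataFrame(values - med, index=mat.data.index, columns=mat.data.columns)
    )


# ---------------------------------------------------------------------------
# cohort annotation


@dataclass
class CohortAnnotation:
    """Sample-to-cohort assignment (two distinct labels for screening ops)."""

    labels: pd.Series  # index: sample_id, values: cohort label

    def __post_init__(self) -> None:
        s = self.labels.copy(deep=False)
        s.index = pd.Index([str(i).strip() for i in s.index], name="sample")
        _check_unique(s.index, "sample id")
        self.labels = s.astype(str)

    @property
    def cohorts(self) -> list[str]:
        """Distinct cohort labels, sorted for determinism."""
        return sorted(self.labels.unique())

    def samples(self, cohort: str) -> list[str]:
        return list(self.labels.index[self.labels == cohort])


def read_annotation(path: str | os.PathLike, sep: str = "\t") -> CohortAnnotation:
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"annotation {path} needs (sample_id, cohort) columns")
    return CohortAnnotation(pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values))


def write_annotation(ann: CohortAnnotation, path: str | os.PathLike, sep: str = "\t") -> None:
    pd.DataFrame(
        {"sample_id": ann.labels.index, "cohort": ann.labels.values}
    ).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# binding-score tables


@dataclass
class BindingScoreTable:
    """One ChIP-Seq dataset's gene-level binding scores (higher = stronger)."""

    dataset_id: str
    species: str
    replicate_group: str
    scores: pd.Series  # index: gene symbol, values: float score

    def __post_init__(self) -> None:
        s = self.scores
        s.index = pd.Index([canonical_symbol(g) for g in s.index], name="gene")
        _check_unique(s.index, f"gene symbol in dataset {self.dataset_id!r}")
        s = s.astype(float)
        if not np.isfinite(s.to_numpy()).all():
            raise ValidationError(f"non-finite score in dataset {self.dataset_id!r}")
        self.scores = s
        self.species = self.species.strip().lower()

    def __len__(self) -> int:
        return len(self.scores)


def read_binding_table(
    path: str | os.PathLike,
    dataset_id: str,
    species: str,
    replicate_group: str,
    sep: str = "\t",
) -> BindingScoreTable:
    """Read a (gene, score) TSV into a BindingScoreTable."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValidationError(f"score table {path} needs (gene, score) columns")
    return BindingScoreTable(
        dataset_id=dataset_id,
        species=species,
        replicate_group=replicate_group,
        scores=pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values),
    )


def read_binding_manifest(path: str | os.PathLike, sep: str = "\t") -> list[BindingScoreTable]:
    """Load all binding-score tables listed in a manifest TSV.

    The manifest has columns ``dataset_id, species, replicate_group, path``;
    score-table paths are resolved relative to the manifest's directory.
    """
    manifest = pd.read_csv(path, sep=sep, dtype=str)
    required = {"dataset_id", "species", "replicate_group", "path"}
    if not required.issubset(manifest.columns):
        raise ValidationError(
            f"manifest {path} missing columns {sorted(required - set(manifest.columns))}"
        )
    base = os.path.dirname(os.fspath(path))
    tables = []
    for row in manifest.itertuples(index=False):
        table_path = row.path
        if not os.path.isabs(table_path):
            table_path = os.path.join(base, table_path)
        if not os.path.exists(table_path):
            raise FileNotFoundError(
                f"score table for dataset {row.dataset_id!r} not found: {table_path}"
            )
        tables.append(
            read_binding_table(
                table_path, row.dataset_id, row.species, row.replicate_group, sep=sep
            )
        )
    return tables


# ---------------------------------------------------------------------------
# ortholog map


@dataclass
class OrthologMap:
    """Source-species symbol -> human symbol mapping.

    Many-to-one (several source symbols collapsing to one human symbol) is
    allowed; one-to-many is an input error.  Symbols absent from the map are
    simply unmapped.
    """

    pairs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = {
            canonical_symbol(k): canonical_symbol(v) for k, v in self.pairs.items()
        }

    def get(self, source_symbol: str) -> str | None:
        return self.pairs.get(canonical_symbol(source_symbol))

    def __contains__(self, source_symbol: str) -> bool:
        return canonical_symbol(source_symbol) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def read_ortholog_map(path: str | os.PathLike, sep: str = "\t") -> OrthologMap:
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"ortholog map {path} needs (source, human) columns")
    pairs: dict[str, str] = {}
    for src, hum in zip(df.iloc[:, 0], df.iloc[:, 1]):
        src_c, hum_c = canonical_symbol(src), canonical_symbol(hum)
        if src_c in pairs and pairs[src_c] != hum_c:
            raise ValidationError(
                f"source symbol {src_c!r} maps to both {pairs[src_c]!r} and {hum_c!r}"
            )
        pairs[src_c] = hum_c
    return OrthologMap(pairs)


def write_ortholog_map(omap: OrthologMap, path: str | os.PathLike, sep: str = "\t") -> None:
    pd.DataFrame(
        sorted(omap.pairs.items()), columns=["source_symbol", "human_symbol"]
    ).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# gene lists


@dataclass
class GeneList:
    """Ordered list of unique gene symbols with a free-text label."""

    symbols: list[str]
    label: str = ""

    def __post_init__(self) -> None:
        self.symbols = [canonical_symbol(s) for s in self.symbols]
        _check_unique(self.symbols, f"gene symbol in list {self.label!r}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return canonical_symbol(symbol) in set(self.symbols)


def read_gene_list(path: str | os.PathLike, label: str = "") -> GeneList:
    """Read a plain-text gene list, one symbol per line; blank lines and
    ``#`` comments are ignored."""
    symbols = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.append(line)
    return GeneList(symbols, label=label or os.path.basename(os.fspath(path)))


def write_gene_list(genes: GeneList | Sequence[str], path: str | os.PathLike) -> None:
    symbols = list(genes)
    with open(path, "w", encoding="utf-8") as fh:
        for s in symbols:
            fh.write(s + "\n")
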
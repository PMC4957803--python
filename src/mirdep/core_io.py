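"""Data model and readers for expression matrices, sample sheets and gene sets.

Expression values are log2-scale intensities (probes x samples), the output of an
upstream normalisation such as RMA.  Probes are the unit of analysis throughout;
gene symbols are annotations and are never collapsed automatically, because a
single transcript is commonly interrogated by several probes.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOTYPES = ("WT", "KO")
CONDITIONS = ("M0", "M1", "M2")

SERIES_MATRIX_BEGIN = "!series_matrix_table_begin"
SERIES_MATRIX_END = "!series_matrix_table_end"


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class ExpressionMatrix:
    """Log2 expression intensities with probe and sample annotations.

    Attributes
    ----------
    values
        DataFrame of log2 intensities, index = probe ids, columns = sample ids.
    gene_symbols
        Optional Series mapping probe id -> gene symbol (many probes may map to
        one symbol).
    samples
        Optional DataFrame indexed by sample id with columns ``genotype``,
        ``condition`` and ``replicate`` (populated by :func:`join_sample_sheet`).
    """

    values: pd.DataFrame
    gene_symbols: pd.Series | None = None
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe id(s): {dupes}")
        vals = self.values.to_numpy(dtype=float, copy=False)
        if vals.size and not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise FormatError(
                f"non-finite expression value at probe {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        if self.gene_symbols is not None:
            self.gene_symbols = self.gene_symbols.reindex(self.values.index)

    # -- introspection -------------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def is_annotated(self) -> bool:
        return self.samples is not None

    def group_samples(self, genotype: str, condition: str) -> list[str]:
        """Sample ids belonging to one genotype x condition cell."""
        if self.samples is None:
            raise ValueError("matrix has no sample annotations; join a sample sheet first")
        mask = (self.samples["genotype"] == genotype) & (self.samples["condition"] == condition)
        return self.samples.index[mask].tolist()

    def group_sizes(self) -> pd.Series:
        """Tally of samples per genotype x condition cell."""
        if self.samples is None:
            raise ValueError("matrix has no sample annotations; join a sample sheet first")
        return self.samples.groupby(["genotype", "condition"], observed=True).size()

    def symbols_for(self, probes) -> pd.Series:
        if self.gene_symbols is None:
            return pd.Series(list(probes), index=list(probes))
        return self.gene_symbols.reindex(probes)

    # -- I/O -----------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        if self.gene_symbols is not None:
            out.insert(0, "gene_symbol", self.gene_symbols)
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t")


def _parse_table(text: str, source: str) -> tuple[pd.DataFrame, pd.Series | None]:
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [str(c).strip('"') for c in df.columns]
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    symbol_col = None
    for col in df.columns:
        stripped = df[col].str.strip('"')
        try:
            # astype, unlike to_numeric, parses floats with correct rounding
            numeric[col] = stripped.astype(float)
        except (ValueError, TypeError):
            if symbol_col is None and col.lower() in ("gene_symbol", "symbol", "gene"):
                symbol_col = col
                continue
            bad = pd.to_numeric(stripped, errors="coerce").isna() & df[col].notna()
            row = df.index[np.flatnonzero(bad)[0]]
            raise FormatError(
                f"{source}: non-numeric value {df.loc[row, col]!r} at row {row!r}, column {col!r}"
            ) from None
    symbols = df[symbol_col].str.strip('"') if symbol_col else None
    if symbol_col:
        numeric = numeric.drop(columns=[symbol_col])
    return numeric, symbols


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read an expression matrix from TSV or GEO series-matrix text.

    The series-matrix dialect is recognised by its table begin/end marker lines;
    all ``!``-prefixed metadata lines are ignored.  The plain-TSV dialect expects
    probe ids in the first column, sample ids in the header and an optional
    ``gene_symbol`` column.
    """
    path = Path(path)
    text = path.read_text()
    if SERIES_MATRIX_BEGIN in text:
        lines = text.splitlines()
        try:
            start = next(i for i, l in enumerate(lines) if l.startswith(SERIES_MATRIX_BEGIN))
            end = next(i for i, l in enumerate(lines) if l.startswith(SERIES_MATRIX_END))
        except StopIteration:
            raise FormatError(f"{path}: series-matrix table markers unbalanced") from None
        table = "\n".join(lines[start + 1 : end])
    else:
        table = "\n".join(l for l in text.splitlines() if l and not l.startswith("!"))
    values, symbols = _parse_table(table, str(path))
    return ExpressionMatrix(values=values, gene_symbols=symbols)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet CSV (sample_id, genotype, condition[, replicate])."""
    sheet = pd.read_csv(path, dtype=str)
    required = {"sample_id", "genotype", "condition"}
    missing = required - set(sheet.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing column(s) {sorted(missing)}")
    sheet = sheet.set_index("sample_id")
    if "replicate" not in sheet.columns:
        sheet["replicate"] = (
            sheet.groupby(["genotype", "condition"], observed=True).cumcount() + 1
        )
    return _validate_sheet(sheet)


def _validate_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    if sheet.index.duplicated().any():
        dupes = sheet.index[sheet.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample id(s) in sheet: {dupes}")
    bad_gt = set(sheet["genotype"]) - set(GENOTYPES)
    if bad_gt:
        raise FormatError(f"unknown genotype label(s): {sorted(bad_gt)}; expected {GENOTYPES}")
    bad_cond = set(sheet["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise FormatError(f"unknown condition label(s): {sorted(bad_cond)}; expected {CONDITIONS}")
    return sheet


def join_sample_sheet(matrix: ExpressionMatrix, sheet: pd.DataFrame) -> ExpressionMatrix:
    """Attach genotype/condition annotations to every sample of the matrix.

    Every matrix sample must appear in the sheet; sheet rows for samples absent
    from the matrix are ignored with a warning (a superset sheet is harmless).
    """
    sheet = _validate_sheet(sheet)
    missing = [s for s in matrix.sample_ids if s not in sheet.index]
    if missing:
        raise FormatError(f"sample(s) missing from sample sheet: {missing}")
    extra = [s for s in sheet.index if s not in matrix.sample_ids]
    if extra:
        logger.warning("sample sheet contains %d sample(s) not in the matrix: %s", len(extra), extra)
    samples = sheet.loc[list(matrix.sample_ids)].copy()
    return ExpressionMatrix(
        values=matrix.values, gene_symbols=matrix.gene_symbols, samples=samples
    )


@dataclass
class GeneSet:
    """An ordered, de-duplicated collection of probe ids or gene symbols."""

    name: str
    members: list[str] = field(default_factory=list)
    direction: str = "none"  # {up, down, none}
    # provenance tags, e.g. which screening criterion admitted each member
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "none"):
            raise ValueError(f"direction must be up/down/none, got {self.direction!r}")
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(str(m), None)
        self.members = list(seen)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, item: str) -> bool:
        low = str(item).lower()
        return any(m.lower() == low for m in self.members)

    def match(self, candidates) -> list[str]:
        """Members of `candidates` matching this set, case-insensitively."""
        wanted = {m.lower() for m in self.members}
        return [c for c in candidates if str(c).lower() in wanted]


def read_gene_set(path: str | Path, name: str | None = None, direction: str = "none") -> GeneSet:
    """Read a gene set from plain text, one symbol/probe per line.

    Lines are stripped and de-duplicated preserving first-occurrence order;
    blank lines and ``#`` comments are skipped.  An empty file is an error.
    """
    path = Path(path)
    members = [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not members:
        raise FormatError(f"{path}: gene-set file is empty")
    return GeneSet(name=name or path.stem, members=members, direction=direction)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(gene_set.members) + "\n")
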
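"""Readers and writers for DepMap-dialect tables and the pipeline's own outputs.

DepMap distributes per-event mutation tables ("CCLE_mutation.csv"-like),
depletion-score matrices in two orientations (the CRISPR gene-effect file is
cells x genes, the shRNA dependency file is genes x cells), and expression
matrices on a log2(TPM+1) scale where an exact zero means the gene is not
expressed.  All matrices label genes as ``"SYMBOL (EntrezID)"``; the files
only share bare HUGO symbols, so labels are reduced to the symbol on read.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from gi_refine.exceptions import AlignmentError, ConfigurationError, FormatError

logger = logging.getLogger(__name__)

#: tokens (case-insensitive) treated as a missing value in matrix bodies
MISSING_TOKENS = frozenset({"", "na", "nan", "null"})

_GENE_SUFFIX_RE = re.compile(r"\s*\([^()]*\)\s*$")

#: column-name candidates for the three required variant-table fields
DEFAULT_VARIANT_DIALECT = {
    "cell_col": ("DepMap_ID", "depmap_id", "cell_id", "Tumor_Sample_Barcode"),
    "gene_col": ("Hugo_Symbol", "hugo_symbol", "gene", "Gene"),
    "class_col": ("Variant_Classification", "variant_classification"),
}

GI_TABLE_COLUMNS = [
    "mutated_gene",
    "target_gene",
    "direction",
    "t_stat",
    "p_value",
    "fdr",
    "n_case",
    "n_control",
    "n_masked_case",
    "n_masked_control",
]


def strip_gene_label(label: str) -> str:
    """Reduce a ``"SYMBOL (EntrezID)"`` label to the bare symbol.

    Idempotent: a single trailing parenthetical token is removed, so a label
    without one is returned unchanged (modulo surrounding whitespace).
    """
    return _GENE_SUFFIX_RE.sub("", str(label)).strip()


@dataclass(frozen=True)
class VariantTable:
    """Per-event mutation records: (cell_id, gene, variant_classification)."""

    records: pd.DataFrame  # columns: cell_id, gene, variant_classification

    def __post_init__(self) -> None:
        missing = [c for c in ("cell_id", "gene", "variant_classification") if c not in self.records.columns]
        if missing:
            raise ConfigurationError(f"VariantTable missing columns: {missing}")
        if (self.records["cell_id"].astype(str).str.len() == 0).any():
            raise FormatError("VariantTable contains empty cell_id values")
        if (self.records["gene"].astype(str).str.len() == 0).any():
            raise FormatError("VariantTable contains empty gene symbols")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def cells(self) -> list[str]:
        return sorted(self.records["cell_id"].unique())


@dataclass(frozen=True)
class ScoreMatrix:
    """Genes x cells real-valued matrix; NaN marks a missing entry.

    ``role`` is ``"depletion"`` (loss-of-function viability effect; low =
    cells die when the gene is perturbed) or ``"expression"``
    (log2(TPM+1)-scale; an exact zero means nonexpressed).
    """

    data: pd.DataFrame  # index: genes, columns: cells, dtype float
    role: str = "depletion"

    def __post_init__(self) -> None:
        if self.role not in ("depletion", "expression"):
            raise ConfigurationError(f"unknown ScoreMatrix role {self.role!r}")
        if self.data.index.has_duplicates:
            dups = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise FormatError(f"duplicate gene symbols: {dups}")
        if self.data.columns.has_duplicates:
            dups = sorted(self.data.columns[self.data.columns.duplicated()].unique())
            raise FormatError(f"duplicate cell IDs: {dups}")
        if self.role == "expression":
            vals = self.data.to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] < 0):
                raise FormatError("expression matrix contains negative values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def cells(self) -> list[str]:
        return list(self.data.columns)

    def subset_cells(self, cells: Sequence[str]) -> "ScoreMatrix":
        return ScoreMatrix(self.data.loc[:, list(cells)], role=self.role)


@dataclass(frozen=True)
class CellAlignment:
    """Cell IDs shared by all aligned sources, with per-source index maps."""

    shared_cells: tuple[str, ...]
    index_maps: dict[str, dict[str, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.shared_cells)


def _sniff_read(path, **kwargs) -> pd.DataFrame:
    """Read a delimited text file with an auto-sniffed separator."""
    return pd.read_csv(path, sep=None, engine="python", **kwargs)


def read_variant_table(path, dialect_config: Mapping | None = None) -> VariantTable:
    """Read a per-event mutation table (CCLE_mutation.csv dialect).

    ``dialect_config`` may override the candidate column names for
    ``cell_col``, ``gene_col`` and ``class_col``; each value is either a
    single column name or a sequence of candidates tried in order.
    """
    dialect = dict(DEFAULT_VARIANT_DIALECT)
    if dialect_config:
        for key, val in dialect_config.items():
            if key not in dialect:
                raise ConfigurationError(f"unknown variant-dialect key {key!r}")
            dialect[key] = (val,) if isinstance(val, str) else tuple(val)

    df = _sniff_read(path, dtype=str, keep_default_na=False)
    if df.empty:
        raise FormatError(f"{path}: no variant records after the header")

    resolved = {}
    for key, candidates in dialect.items():
        for cand in candidates:
            if cand in df.columns:
                resolved[key] = cand
                break
        else:
            raise ConfigurationError(
                f"{path}: none of the candidate columns {candidates} for "
                f"{key!r} are present (found {list(df.columns)})"
            )

    records = pd.DataFrame(
        {
            "cell_id": df[resolved["cell_col"]].str.strip(),
            "gene": df[resolved["gene_col"]].map(strip_gene_label),
            "variant_classification": df[resolved["class_col"]],
        }
    )
    return VariantTable(records)


def _detect_cell_axis(df: pd.DataFrame, cell_prefix: str) -> str:
    """Return 'rows' or 'columns' depending on which axis looks like cells."""

    def frac(labels) -> float:
        labels = [str(x) for x in labels]
        if not labels:
            return 0.0
        return sum(x.startswith(cell_prefix) for x in labels) / len(labels)

    row_frac, col_frac = frac(df.index), frac(df.columns)
    row_hit, col_hit = row_frac >= 0.5, col_frac >= 0.5
    if row_hit == col_hit:
        raise FormatError(
            "cannot auto-detect matrix orientation: cell-ID prefix "
            f"{cell_prefix!r} matches {row_frac:.0%} of rows and "
            f"{col_frac:.0%} of columns; pass an explicit orientation"
        )
    return "rows" if row_hit else "columns"


def read_score_matrix(
    path,
    role: str,
    orientation: str = "auto",
    cell_prefix: str = "ACH-",
    drop_incomplete_genes: bool = False,
) -> ScoreMatrix:
    """Read a depletion or expression matrix into canonical genes x cells form.

    ``orientation`` is ``"cells_by_genes"`` (Achilles gene-effect dialect),
    ``"genes_by_cells"`` (D2 combined dependency dialect) or ``"auto"``,
    which assigns the cell axis to whichever label set is dominated by
    ``cell_prefix``.  Blank and ``NA``/``NaN`` body cells become NaN;
    ``drop_incomplete_genes`` additionally removes every gene row that still
    carries a missing value (row-wise complete analysis).
    """
    if orientation not in ("auto", "cells_by_genes", "genes_by_cells"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")

    raw = _sniff_read(path, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.map(lambda x: str(x).strip())
    raw.columns = [str(c).strip() for c in raw.columns]

    if orientation == "auto":
        axis = _detect_cell_axis(raw, cell_prefix)
        orientation = "cells_by_genes" if axis == "rows" else "genes_by_cells"
    if orientation == "cells_by_genes":
        raw = raw.T  # canonical: genes are rows

    # numeric conversion with coordinates on failure
    def to_float(token: str, gene: str, cell: str) -> float:
        if token.strip().lower() in MISSING_TOKENS:
            return math.nan
        try:
            return float(token)
        except ValueError:
            raise FormatError(
                f"{path}: non-numeric value {token!r} at gene {gene!r}, cell {cell!r}"
            ) from None

    values = np.empty(raw.shape, dtype=float)
    for j, cell in enumerate(raw.columns):
        col = raw.iloc[:, j]
        for i, (gene, token) in enumerate(zip(raw.index, col)):
            values[i, j] = to_float(token, gene, cell)

    genes = [strip_gene_label(g) for g in raw.index]
    counts = pd.Series(genes).value_counts()
    dups = sorted(counts[counts > 1].index)
    if dups:
        raise FormatError(f"{path}: duplicate gene symbols after suffix stripping: {dups}")

    df = pd.DataFrame(values, index=genes, columns=list(raw.columns))
    if drop_incomplete_genes:
        df = df.dropna(axis=0, how="any")
    return ScoreMatrix(df, role=role)


def _cells_of(source) -> set[str]:
    if isinstance(source, ScoreMatrix):
        return set(source.cells)
    if isinstance(source, VariantTable):
        return set(source.records["cell_id"])
    if hasattr(source, "calls"):  # MutationMatrix, avoiding a circular import
        return set(source.calls.columns)
    return set(source)


def align_cells(*sources, names: Sequence[str] | None = None) -> CellAlignment:
    """Intersect cell IDs across >=2 sources; deterministic (sorted) order.

    Sources may be :class:`ScoreMatrix`, :class:`VariantTable`,
    mutation matrices, or plain iterables of cell IDs.
    """
    if len(sources) < 2:
        raise ConfigurationError("align_cells needs at least two sources")
    cell_sets = [_cells_of(s) for s in sources]
    shared = sorted(set.intersection(*cell_sets))
    if not shared:
        raise AlignmentError("no cell IDs shared by all sources")
    if names is None:
        names = [f"source_{i}" for i in range(len(sources))]
    index_maps = {}
    for name, cells in zip(names, cell_sets):
        ordered = sorted(cells)
        pos = {c: i for i, c in enumerate(ordered)}
        index_maps[name] = {c: pos[c] for c in shared}
    return CellAlignment(tuple(shared), index_maps)


def write_gi_table(gi_table, path) -> None:
    """Write a GI table as TSV with ``#``-prefixed metadata header lines."""
    meta = {
        "label": gi_table.label,
        "m_tests": gi_table.m_tests,
        "n_skipped": gi_table.n_skipped,
        "config": gi_table.config,
    }
    with open(path, "w") as fh:
        fh.write(f"# gi-refine GI table\n# meta={json.dumps(meta, sort_keys=True)}\n")
        gi_table.records.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_gi_table(path):
    """Read a GI table written by :func:`write_gi_table` (lossless)."""
    from gi_refine.screen import GITable  # deferred: screen imports io

    meta = {"label": "", "m_tests": 0, "n_skipped": 0, "config": {}}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        stripped = line[1:].strip()
        if stripped.startswith("meta="):
            meta.update(json.loads(stripped[len("meta="):]))
    from io import StringIO

    body = "".join(lines[body_start:])
    if body.strip():
        records = pd.read_csv(StringIO(body), sep="\t", dtype={"mutated_gene": str, "target_gene": str})
    else:
        records = pd.DataFrame(columns=GI_TABLE_COLUMNS)
    for col in ("n_case", "n_control", "n_masked_case", "n_masked_control"):
        if col in records.columns and len(records):
            records[col] = records[col].astype(int)
    return GITable(
        records=records,
        label=meta["label"],
        m_tests=int(meta["m_tests"]),
        n_skipped=int(meta["n_skipped"]),
        config=meta["config"],
    )
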
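"""Functional-mutation calling and recurrence filtering.

A gene is called functionally mutated in a cell line if at least one of its
variant events carries a deleterious classification; genes functionally
mutated in more than a threshold fraction of cell lines (default 3%) are
the recurrently mutated genes taken forward to GI screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from gi_refine.exceptions import ConfigurationError
from gi_refine.io import VariantTable

logger = logging.getLogger(__name__)

#: The 12 variant classifications treated as deleterious, in normalized
#: (lower-case, underscore-separated) spelling.  User-overridable.
DEFAULT_DELETERIOUS_VOCABULARY = frozenset(
    {
        "de_novo_start_out_of_frame",
        "frame_shift_del",
        "frame_shift_ins",
        "in_frame_del",
        "nonsense_mutation",
        "nonstop_mutation",
        "splice_site",
        "start_codon_del",
        "start_codon_ins",
        "stop_codon_del",
        "stop_codon_ins",
        "missense_mutation",
    }
)


def normalize_classification(label: str) -> str:
    """Normalize a variant classification for case/separator-insensitive comparison."""
    return str(label).strip().lower().replace(" ", "_").replace("-", "_")


@dataclass(frozen=True)
class MutationMatrix:
    """Binary functional-mutation calls (genes x cells) with event provenance.

    ``calls`` entries are 0/1; ``provenance`` holds the count of deleterious
    events behind each call, so every 1 in ``calls`` is backed by a count >= 1.
    """

    calls: pd.DataFrame       # int8, genes x cells
    provenance: pd.DataFrame  # int64 counts, same shape

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.provenance.index) or not self.calls.columns.equals(
            self.provenance.columns
        ):
            raise ConfigurationError("calls and provenance must share gene/cell labels")

    @property
    def genes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def cells(self) -> list[str]:
        return list(self.calls.columns)

    def frequency(self) -> pd.Series:
        """Per-gene fraction of cells called functionally mutated."""
        return self.calls.sum(axis=1) / self.calls.shape[1]


@dataclass(frozen=True)
class RecurrentGeneSet:
    """Genes whose mutation frequency passes the recurrence filter."""

    genes: tuple[str, ...]
    threshold: float
    n_cells: int
    strict: bool = True

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def call_functional_mutations(
    variant_table: VariantTable,
    vocabulary: Iterable[str] | None = None,
    cell_universe: Sequence[str] | None = None,
) -> MutationMatrix:
    """Collapse per-event variant records into binary functional-mutation calls.

    An entry (gene, cell) is 1 iff at least one record for that pair has a
    classification in ``vocabulary`` (compared after normalization).
    Classifications outside the vocabulary count as non-deleterious; each
    unknown label is logged once.  Cells in ``cell_universe`` without any
    record yield all-zero columns.
    """
    vocab = {normalize_classification(v) for v in (vocabulary or DEFAULT_DELETERIOUS_VOCABULARY)}
    if not vocab:
        raise ConfigurationError("deleterious vocabulary must be nonempty")

    records = variant_table.records
    if cell_universe is None:
        cells = sorted(records["cell_id"].unique())
    else:
        cells = sorted(dict.fromkeys(cell_universe))
        if not cells:
            raise ConfigurationError("cell_universe must be nonempty")

    normalized = records["variant_classification"].map(normalize_classification)
    deleterious = normalized.isin(vocab)
    for label in sorted(set(normalized[~deleterious])):
        logger.info("variant classification %r treated as non-deleterious", label)

    genes = sorted(records["gene"].unique())
    cell_set = set(cells)
    hits = records.loc[deleterious & records["cell_id"].isin(cell_set), ["gene", "cell_id"]]
    counts = hits.groupby(["gene", "cell_id"]).size()

    provenance = pd.DataFrame(0, index=genes, columns=cells, dtype=np.int64)
    if len(counts):
        wide = counts.unstack(fill_value=0)
        provenance.loc[wide.index, wide.columns] = wide
    calls = (provenance > 0).astype(np.int8)
    return MutationMatrix(calls=calls, provenance=provenance)


def select_recurrent_genes(
    mutation_matrix: MutationMatrix,
    threshold: float = 0.03,
    strict: bool = True,
    denominator_cells: Sequence[str] | None = None,
) -> RecurrentGeneSet:
    """Select genes functionally mutated in more than ``threshold`` of cells.

    The comparison is strict (> threshold) by default; ``strict=False`` uses
    >=.  ``denominator_cells`` restricts both the mutation counts and the
    denominator to a cell subset (e.g. screen-aligned cells); by default the
    full profiled cell universe is used, mirroring a recurrence filter that
    runs before screen alignment.
    """
    if not 0 <= threshold < 1:
        raise ConfigurationError("recurrence threshold must be in [0, 1)")
    calls = mutation_matrix.calls
    if denominator_cells is not None:
        cells = [c for c in dict.fromkeys(denominator_cells) if c in calls.columns]
        calls = calls.loc[:, cells]
    n_cells = calls.shape[1]
    if n_cells == 0:
        raise ConfigurationError("recurrence filter needs a nonempty cell universe")
    freq = calls.sum(axis=1) / n_cells
    keep = freq > threshold if strict else freq >= threshold
    return RecurrentGeneSet(
        genes=tuple(sorted(calls.index[keep])),
        threshold=threshold,
        n_cells=n_cells,
        strict=strict,
    )
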
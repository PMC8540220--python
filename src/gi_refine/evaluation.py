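"""Recall/precision evaluation of sensitive GIs against reference SLI sets.

Reference sets (SynLethDB- or MiSL-style) are unordered gene pairs; a
predicted GI (mutated gene Q, target K) matches a reference pair {A, B}
when {Q, K} == {A, B}.  Only sensitive GIs are evaluated by default, since
synthetic lethality corresponds to the sensitive direction; self-GIs
(Q == K) are excluded because reference sets contain no self-pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from gi_refine.exceptions import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

STAGE_ORDER = ("INIT", "RP2", "RP1")


@dataclass(frozen=True)
class ReferencePairSet:
    """Canonicalized, deduplicated unordered gene pairs."""

    pairs: frozenset  # of frozenset({a, b}), a != b
    source: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    def genes(self) -> set:
        out: set = set()
        for p in self.pairs:
            out |= set(p)
        return out


def make_reference(pairs: Iterable, source: str = "") -> ReferencePairSet:
    """Build a reference set from (a, b) iterables, dropping self-pairs."""
    canon = set()
    n_self = 0
    for a, b in pairs:
        if a == b:
            n_self += 1
            continue
        canon.add(frozenset((str(a), str(b))))
    if n_self:
        logger.info("dropped %d self-pair(s) from reference set", n_self)
    return ReferencePairSet(frozenset(canon), source=source)


def load_reference_pairs(path, source: str = "") -> ReferencePairSet:
    """Load a two-column TSV of gene pairs; malformed rows raise with line number."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise FormatError(f"{path}:{lineno}: expected two gene symbols")
            if lineno == 1 and {fields[0].lower(), fields[1].lower()} & {"gene1", "gene2", "genea", "geneb"}:
                continue
            pairs.append((fields[0], fields[1]))
    return make_reference(pairs, source=source or str(path))


@dataclass(frozen=True)
class EvalMetrics:
    """Counts and rates for one prediction set against one reference."""

    stage: str
    n_predicted: int
    n_reference: int
    n_hits: int
    precision: float | None  # None when nothing was predicted
    recall: float


def evaluate(
    gi_table,
    reference: ReferencePairSet,
    stage_label: str = "",
    sensitive_only: bool = True,
    ordered: bool = False,
    restrict_reference_to: Iterable | None = None,
) -> EvalMetrics:
    """Score predicted GI pairs against a reference pair set.

    ``restrict_reference_to`` optionally limits the recall denominator to
    reference pairs whose genes all belong to the given universe (e.g. the
    genes testable in the screen); the default uses the full reference set.
    """
    if len(reference) == 0:
        raise ConfigurationError("reference pair set is empty")
    ref_pairs = reference.pairs
    if restrict_reference_to is not None:
        universe = set(restrict_reference_to)
        ref_pairs = frozenset(p for p in ref_pairs if set(p) <= universe)
        if not ref_pairs:
            raise ConfigurationError("reference is empty after universe restriction")

    df = gi_table.records
    if sensitive_only:
        df = df[df["direction"] == "sensitive"]
    df = df[df["mutated_gene"] != df["target_gene"]]
    if ordered:
        predicted = {(q, k) for q, k in zip(df["mutated_gene"], df["target_gene"])}
        hits = {p for p in predicted if frozenset(p) in ref_pairs}
    else:
        predicted = {frozenset((q, k)) for q, k in zip(df["mutated_gene"], df["target_gene"])}
        hits = predicted & ref_pairs

    n_pred, n_ref, n_hits = len(predicted), len(ref_pairs), len(hits)
    return EvalMetrics(
        stage=stage_label or gi_table.label,
        n_predicted=n_pred,
        n_reference=n_ref,
        n_hits=n_hits,
        precision=(n_hits / n_pred) if n_pred else None,
        recall=n_hits / n_ref,
    )


def stage_comparison(
    gi_tables: Mapping[str, "object"],
    reference: ReferencePairSet,
    sensitive_only: bool = True,
) -> pd.DataFrame:
    """Evaluate the INIT / RP2 / RP1 stage tables and check their nesting.

    The predicted pair sets must nest (RP1 within RP2 within INIT); a
    violation signals an upstream bug and raises.  Recall is then forced to
    be non-increasing along the stages, which is asserted.
    """
    stages = [s for s in STAGE_ORDER if s in gi_tables]
    if not stages:
        raise ConfigurationError(f"gi_tables must use stage labels among {STAGE_ORDER}")
    pair_sets = {s: gi_tables[s].pairs(sensitive_only=False) for s in stages}
    for outer, inner in zip(stages, stages[1:]):
        if not pair_sets[inner] <= pair_sets[outer]:
            raise ConfigurationError(f"stage nesting violated: {inner} is not a subset of {outer}")

    metrics = [
        evaluate(gi_tables[s], reference, stage_label=s, sensitive_only=sensitive_only)
        for s in stages
    ]
    recalls = [m.recall for m in metrics]
    assert all(a >= b for a, b in zip(recalls, recalls[1:])), "recall must be non-increasing"
    return pd.DataFrame(
        {
            "stage": [m.stage for m in metrics],
            "n_predicted": [m.n_predicted for m in metrics],
            "n_reference": [m.n_reference for m in metrics],
            "n_hits": [m.n_hits for m in metrics],
            "precision": [m.precision for m in metrics],
            "recall": [m.recall for m in metrics],
        }
    )


def write_reference_pairs(reference: ReferencePairSet, path) -> None:
    """Write a reference pair set as a two-column TSV (sorted, canonical)."""
    rows = sorted(tuple(sorted(p)) for p in reference.pairs)
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\n")
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")
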
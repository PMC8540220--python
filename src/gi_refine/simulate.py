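"""Synthetic screen generator with known planted truth.

Generates all five pipeline inputs — variant records, a depletion matrix, an
expression matrix, a gene network and a reference pair set — from one seeded
configuration, so every stage of the pipeline can be exercised and checked
against the planted ground truth without external downloads.

Statistical structure of the depletion model: a screened gene's score in a
cell is Normal(0, sigma) baseline; a planted GI (Q, K, sensitive) subtracts
the effect size delta in every cell carrying a functional mutation of Q
(resistant adds it).  Each mutated gene is mutated in an exact
``round(pi * n_cells)`` cells, so the recurrence filter is passed by
construction.  On the network, the planted true SPs of each mutated gene
form a clique; every other target gene is attached to a dedicated dummy
neighbor node, which keeps it representable in an edge-list file while
leaving it at infinite distance from all true SPs (designated decoy SPs
are therefore >= 3 edges from every other SP, as are any false positives
the screen may produce).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from gi_refine.exceptions import ConfigurationError
from gi_refine.evaluation import ReferencePairSet, make_reference, write_reference_pairs
from gi_refine.io import ScoreMatrix, VariantTable
from gi_refine.network import GeneNetwork, from_edges, write_network

#: DepMap-style spellings cycled through for planted deleterious events
_DELETERIOUS_SPELLINGS = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
    "In_Frame_Del",
    "Nonstop_Mutation",
    "Start_Codon_Del",
    "Start_Codon_Ins",
    "Stop_Codon_Del",
    "Stop_Codon_Ins",
    "De_novo_Start_OutOfFrame",
)


class PlantedGI(NamedTuple):
    mutated_gene: str
    target_gene: str
    direction: str


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic screen.

    Defaults describe a screen of 10 recurrently mutated genes against 500
    screened genes over 200 cell lines, each mutated gene functionally
    mutated in 10% of lines, with 2 planted sensitive partners per mutated
    gene (20 planted GIs among 5000 assessed pairs) at effect size 1.0 over
    Gaussian noise sigma 0.2, and 5% exact-zero expression entries.
    """

    n_cells: int = 200
    n_target_genes: int = 500
    n_mutated_genes: int = 10
    sps_per_mutated: int = 2
    mutation_frequency: float = 0.1
    depletion_sigma: float = 0.2
    effect_size: float = 1.0
    resistant_fraction: float = 0.0   # fraction of planted GIs given the resistant direction
    noise: str = "gaussian"           # or "student_t"
    student_t_df: float = 3.0
    expression_mean: float = 6.0
    expression_sd: float = 2.0
    nonexpressed_fraction: float = 0.05
    n_always_nonexpressed: int = 2
    n_confound_pairs: int = 0         # pairs whose signal lives only in nonexpressed cells
    decoys_per_mutated: int = 2
    n_background_nodes: int = 50
    background_edge_density: float = 0.05
    reference_truth_fraction: float = 0.8
    n_reference_noise_pairs: int = 50
    missing_fraction: float = 0.0     # NaN entries sprinkled into the depletion matrix
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.mutation_frequency < 1:
            raise ConfigurationError("mutation_frequency must lie in (0, 1)")
        if self.depletion_sigma <= 0:
            raise ConfigurationError("depletion_sigma must be positive")
        if not 0 <= self.nonexpressed_fraction < 1:
            raise ConfigurationError("nonexpressed_fraction must lie in [0, 1)")
        if self.noise not in ("gaussian", "student_t"):
            raise ConfigurationError(f"unknown noise model {self.noise!r}")
        n_mut_cells = round(self.mutation_frequency * self.n_cells)
        if n_mut_cells < 1 or n_mut_cells >= self.n_cells:
            raise ConfigurationError("mutation_frequency leaves no mutant or no wild-type cells")
        if n_mut_cells / self.n_cells <= 0.03:
            raise ConfigurationError(
                "mutation_frequency must exceed the 3% recurrence threshold by construction"
            )
        reserved = self.n_mutated_genes * (self.sps_per_mutated + self.decoys_per_mutated)
        reserved += self.n_confound_pairs + self.n_always_nonexpressed
        if reserved > self.n_target_genes:
            raise ConfigurationError(
                f"config reserves {reserved} special target genes but only "
                f"{self.n_target_genes} exist"
            )


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth consistent with the emitted matrices and network."""

    gis: tuple                      # PlantedGI tuples (detectable effects only)
    true_sp_map: dict               # Q -> tuple of planted SPs (mutually adjacent)
    decoy_sps: dict                 # Q -> tuple of isolated designated decoys
    confound_pairs: tuple           # (Q, K) whose signal is masked by exclusion
    always_nonexpressed: tuple
    mutant_cells: dict              # Q -> tuple of cell IDs carrying the mutation

    def to_json(self, path) -> None:
        payload = {
            "gis": [list(g) for g in self.gis],
            "true_sp_map": {q: list(v) for q, v in self.true_sp_map.items()},
            "decoy_sps": {q: list(v) for q, v in self.decoy_sps.items()},
            "confound_pairs": [list(p) for p in self.confound_pairs],
            "always_nonexpressed": list(self.always_nonexpressed),
            "mutant_cells": {q: list(v) for q, v in self.mutant_cells.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            gis=tuple(PlantedGI(*g) for g in d["gis"]),
            true_sp_map={q: tuple(v) for q, v in d["true_sp_map"].items()},
            decoy_sps={q: tuple(v) for q, v in d["decoy_sps"].items()},
            confound_pairs=tuple(tuple(p) for p in d["confound_pairs"]),
            always_nonexpressed=tuple(d["always_nonexpressed"]),
            mutant_cells={q: tuple(v) for q, v in d["mutant_cells"].items()},
        )


@dataclass(frozen=True)
class SyntheticScreen:
    """All generated inputs plus the planted truth."""

    config: SynthConfig
    variants: VariantTable
    depletion: ScoreMatrix
    expression: ScoreMatrix
    network: GeneNetwork
    reference: ReferencePairSet
    truth: PlantedTruth

    def write(self, outdir) -> dict[str, str]:
        """Emit all inputs as files in the dialects the readers expect.

        The depletion matrix is written cells x genes (Achilles gene-effect
        dialect) and the expression matrix genes x cells (D2-style), both
        with ``"SYMBOL (ID)"`` gene labels, so orientation auto-detection
        and label stripping are exercised end to end.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "variants": str(outdir / "mutations.csv"),
            "depletion": str(outdir / "depletion.csv"),
            "expression": str(outdir / "expression.csv"),
            "network": str(outdir / "network.tsv"),
            "reference": str(outdir / "reference_pairs.tsv"),
            "truth": str(outdir / "truth.json"),
        }
        rec = self.variants.records
        pd.DataFrame(
            {
                "DepMap_ID": rec["cell_id"],
                "Hugo_Symbol": [_labelled(g) for g in rec["gene"]],
                "Variant_Classification": rec["variant_classification"],
            }
        ).to_csv(paths["variants"], index=False)

        dep = self.depletion.data.copy()
        dep.index = [_labelled(g) for g in dep.index]
        dep.T.to_csv(paths["depletion"], float_format="%.10g")  # cells x genes

        expr = self.expression.data.copy()
        expr.index = [_labelled(g) for g in expr.index]
        expr.to_csv(paths["expression"], float_format="%.10g")  # genes x cells

        write_network(self.network, paths["network"])
        write_reference_pairs(self.reference, paths["reference"])
        self.truth.to_json(paths["truth"])
        return paths


def _labelled(gene: str) -> str:
    """Attach a stable fake Entrez-style numeric suffix to a gene symbol."""
    return f"{gene} ({zlib.crc32(gene.encode()) % 90000 + 10000})"


def _noise(rng: np.random.Generator, cfg: SynthConfig, shape) -> np.ndarray:
    if cfg.noise == "gaussian":
        return rng.normal(0.0, cfg.depletion_sigma, shape)
    t = rng.standard_t(cfg.student_t_df, shape)
    scale = cfg.depletion_sigma
    if cfg.student_t_df > 2:  # match the requested marginal sd
        scale /= np.sqrt(cfg.student_t_df / (cfg.student_t_df - 2))
    return t * scale


def generate(config: SynthConfig | None = None, outdir=None) -> SyntheticScreen:
    """Generate a complete synthetic screen; optionally write it to ``outdir``.

    Deterministic in ``config.seed``: the same configuration produces
    byte-identical outputs.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)

    cells = [f"ACH-{i:06d}" for i in range(1, cfg.n_cells + 1)]
    targets = [f"TG{i:04d}" for i in range(1, cfg.n_target_genes + 1)]
    muts = [f"QG{i:02d}" for i in range(1, cfg.n_mutated_genes + 1)]

    # --- special-role target assignment (disjoint, deterministic) ----------
    pool = iter(targets)
    true_sp_map = {q: tuple(next(pool) for _ in range(cfg.sps_per_mutated)) for q in muts}
    decoy_sps = {q: tuple(next(pool) for _ in range(cfg.decoys_per_mutated)) for q in muts}
    confound_pairs = tuple(
        (muts[i % len(muts)], next(pool)) for i in range(cfg.n_confound_pairs)
    )
    always_off = tuple(next(pool) for _ in range(cfg.n_always_nonexpressed))

    # --- mutation calls and variant records --------------------------------
    n_mut_cells = round(cfg.mutation_frequency * cfg.n_cells)
    mutant_cells = {}
    var_rows = []
    for qi, q in enumerate(muts):
        chosen = sorted(rng.choice(cfg.n_cells, size=n_mut_cells, replace=False))
        mutant_cells[q] = tuple(cells[c] for c in chosen)
        for j, c in enumerate(chosen):
            var_rows.append(
                (cells[c], q, _DELETERIOUS_SPELLINGS[(qi + j) % len(_DELETERIOUS_SPELLINGS)])
            )
        # benign records on a few wild-type cells exercise the vocabulary filter
        wild = sorted(set(range(cfg.n_cells)) - set(chosen))
        for c in rng.choice(wild, size=min(3, len(wild)), replace=False):
            var_rows.append((cells[c], q, "Silent"))
    # every profiled line carries at least one (possibly benign) event, so the
    # mutation-profile cell universe covers all cells
    covered = {r[0] for r in var_rows}
    for i, c in enumerate(cells):
        if c not in covered:
            var_rows.append((c, muts[i % len(muts)], "Silent"))
    variants = VariantTable(
        pd.DataFrame(var_rows, columns=["cell_id", "gene", "variant_classification"])
    )

    # --- planted GIs --------------------------------------------------------
    gis = []
    if cfg.effect_size != 0:
        flat = [(q, k) for q in muts for k in true_sp_map[q]]
        n_res = round(cfg.resistant_fraction * len(flat))
        for i, (q, k) in enumerate(flat):
            gis.append(PlantedGI(q, k, "resistant" if i < n_res else "sensitive"))

    # --- depletion matrix ---------------------------------------------------
    dep = _noise(rng, cfg, (cfg.n_target_genes, cfg.n_cells))
    dep_df = pd.DataFrame(dep, index=targets, columns=cells)
    cell_pos = {c: i for i, c in enumerate(cells)}
    for q, k, direction in gis:
        idx = [cell_pos[c] for c in mutant_cells[q]]
        shift = -cfg.effect_size if direction == "sensitive" else cfg.effect_size
        dep_df.loc[k, dep_df.columns[idx]] += shift
    for q, k in confound_pairs:
        idx = [cell_pos[c] for c in mutant_cells[q]]
        dep_df.loc[k, dep_df.columns[idx]] -= max(cfg.effect_size, 1.0)
    if cfg.missing_fraction > 0:
        hole = rng.random(dep_df.shape) < cfg.missing_fraction
        dep_df = dep_df.mask(pd.DataFrame(hole, index=dep_df.index, columns=dep_df.columns))

    # --- expression matrix --------------------------------------------------
    expr = rng.normal(cfg.expression_mean, cfg.expression_sd, (cfg.n_target_genes, cfg.n_cells))
    expr = np.clip(expr, 0.1, None)
    zero = rng.random(expr.shape) < cfg.nonexpressed_fraction
    expr[zero] = 0.0
    expr_df = pd.DataFrame(expr, index=targets, columns=cells)
    for g in always_off:
        expr_df.loc[g, :] = 0.0
    for q, k in confound_pairs:
        # the depletion difference is carried entirely by nonexpressed cells
        expr_df.loc[k, :] = np.clip(expr_df.loc[k, :], 0.5, None)
        expr_df.loc[k, list(mutant_cells[q])] = 0.0

    # --- network ------------------------------------------------------------
    edges = []
    for q in muts:
        sps = true_sp_map[q]
        edges.extend((sps[i], sps[j]) for i in range(len(sps)) for j in range(i + 1, len(sps)))
    clique_genes = {g for sps in true_sp_map.values() for g in sps}
    for g in targets:
        if g not in clique_genes:
            edges.append((g, f"NBR_{g}"))
    bg = [f"BG{i:03d}" for i in range(1, cfg.n_background_nodes + 1)]
    for i in range(len(bg)):
        for j in range(i + 1, len(bg)):
            if rng.random() < cfg.background_edge_density:
                edges.append((bg[i], bg[j]))
    network = from_edges(edges, directed=False, nodes=targets + bg)

    # --- reference pair set -------------------------------------------------
    truth_pairs = [(q, k) for q, k, d in gis if d == "sensitive"]
    n_keep = round(cfg.reference_truth_fraction * len(truth_pairs))
    keep_idx = sorted(rng.choice(len(truth_pairs), size=n_keep, replace=False)) if truth_pairs else []
    ref_pairs = [truth_pairs[i] for i in keep_idx]
    planted_set = {frozenset(p) for p in [(g.mutated_gene, g.target_gene) for g in gis]}
    n_noise = 0
    while n_noise < cfg.n_reference_noise_pairs:
        a, b = rng.choice(cfg.n_target_genes, size=2, replace=False)
        pair = (targets[a], targets[b])
        if frozenset(pair) in planted_set:
            continue
        ref_pairs.append(pair)
        n_noise += 1
    reference = make_reference(ref_pairs, source="synthetic")

    truth = PlantedTruth(
        gis=tuple(gis),
        true_sp_map=true_sp_map,
        decoy_sps=decoy_sps,
        confound_pairs=confound_pairs,
        always_nonexpressed=always_off,
        mutant_cells=mutant_cells,
    )
    screen = SyntheticScreen(
        config=cfg,
        variants=variants,
        depletion=ScoreMatrix(dep_df, role="depletion"),
        expression=ScoreMatrix(expr_df, role="expression"),
        network=network,
        reference=reference,
        truth=truth,
    )
    if outdir is not None:
        screen.write(outdir)
    return screen


def make_expression_confound(config: SynthConfig | None = None, outdir=None) -> SyntheticScreen:
    """Generate a screen with one expression-confounded (Q, K) pair planted.

    The pair's depletion difference exists only in cells where K is
    nonexpressed, so the exclusion procedure erases the signal: the pair is
    reported without exclusion and absent with it — the hallmark of a
    nonexpression-driven false positive.
    """
    cfg = config or SynthConfig()
    if cfg.n_confound_pairs < 1:
        cfg = replace(cfg, n_confound_pairs=1)
    return generate(cfg, outdir=outdir)


def config_from_dict(d: dict) -> SynthConfig:
    known = set(SynthConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
    return SynthConfig(**d)
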
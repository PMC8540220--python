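"""Expression-masked differential-essentiality screening.

For every pair (Q, K) of a recurrently mutated gene Q and a screened gene K,
the depletion scores of K are split into case cells (functional mutation in
Q) and control cells (wild-type Q) and compared with a two-sample t-test.
A lower case mean marks a *sensitive* GI (knockout of K preferentially
kills Q-mutant cells, the synthetic-lethal-like direction); a higher case
mean marks a *resistant* GI.  Before testing, the exclusion procedure masks
every depletion entry whose matched expression value is zero, on the premise
that perturbing a nonexpressed gene cannot affect the cell.  Two-sided
p-values from all performed tests form one family, adjusted by
Benjamini-Hochberg; records with FDR below the threshold (default 0.2) are
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gi_refine.exceptions import ConfigurationError
from gi_refine.io import GI_TABLE_COLUMNS, ScoreMatrix, align_cells
from gi_refine.mutation import MutationMatrix, RecurrentGeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestConfig:
    """Screening parameters.

    fdr_threshold
        Report pairs with BH-adjusted p strictly below this value.
    min_group_size
        Minimum non-missing depletion values required in each of the case
        and control groups; pairs below it are skipped and do not enter the
        BH family.
    t_variant
        ``"welch"`` (unequal variances; group sizes differ wildly between
        mutant and wild-type cells) or ``"student"`` (pooled variance).
    exclusion_enabled
        Apply the nonexpression masking before testing.
    expression_zero_epsilon
        An expression value <= epsilon counts as nonexpressed (default 0.0,
        exact-zero semantics; raise to tolerate TPM noise).
    """

    fdr_threshold: float = 0.2
    min_group_size: int = 3
    t_variant: str = "welch"
    exclusion_enabled: bool = True
    expression_zero_epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold <= 1:
            raise ConfigurationError("fdr_threshold must be in (0, 1]")
        if self.min_group_size < 2:
            raise ConfigurationError("min_group_size must be >= 2")
        if self.t_variant not in ("welch", "student"):
            raise ConfigurationError(f"unknown t_variant {self.t_variant!r}")
        if self.expression_zero_epsilon < 0:
            raise ConfigurationError("expression_zero_epsilon must be >= 0")


class PairResult(NamedTuple):
    t_stat: float
    p_value: float
    direction: str
    n_case: int
    n_control: int


@dataclass(frozen=True)
class GITable:
    """Significant GI records plus the bookkeeping of the full test family."""

    records: pd.DataFrame
    label: str = ""
    m_tests: int = 0       # tests actually performed (the BH family size)
    n_skipped: int = 0     # pairs skipped for group size / degeneracy
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def filtered(self, alpha: float | None = None) -> pd.DataFrame:
        """Records with fdr strictly below ``alpha`` (default: all records)."""
        if alpha is None:
            return self.records
        return self.records[self.records["fdr"] < alpha]

    def pairs(self, sensitive_only: bool = False, include_self: bool = False) -> set[frozenset]:
        """Unordered {Q, K} pairs of the records (self-GIs dropped by default)."""
        df = self.records
        if sensitive_only:
            df = df[df["direction"] == "sensitive"]
        out = set()
        for q, k in zip(df["mutated_gene"], df["target_gene"]):
            if q == k and not include_self:
                continue
            out.add(frozenset((q, k)))
        return out

    def subset(self, keep: "pd.Series | np.ndarray", label: str | None = None) -> "GITable":
        return GITable(
            records=self.records[keep].reset_index(drop=True),
            label=self.label if label is None else label,
            m_tests=self.m_tests,
            n_skipped=self.n_skipped,
            config=self.config,
        )


def bh_fdr(p_values: Sequence[float], m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    ``m_total`` is the size of the test family; it defaults to
    ``len(p_values)`` and may be larger when adjusting a subset of a family
    (never smaller).  The adjusted value of the i-th smallest p is
    ``min_{j >= i} p_(j) * m_total / j``, clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    m = int(m_total) if m_total is not None else p.size
    if m < p.size:
        raise ConfigurationError("family size m_total cannot be smaller than len(p_values)")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def nonexpression_mask(
    depletion: ScoreMatrix, expression: ScoreMatrix, epsilon: float = 0.0
) -> pd.DataFrame:
    """Boolean genes x cells frame: True where the depletion entry is to be masked.

    An entry is masked iff the expression matrix *has* a value for the same
    (gene, cell) and that value is <= epsilon.  Genes or cells absent from
    the expression matrix — and missing expression entries — leave the
    depletion score untouched.
    """
    expr = expression.data.reindex(index=depletion.data.index, columns=depletion.data.columns)
    return expr.le(epsilon) & expr.notna()


def mask_nonexpressed(
    depletion: ScoreMatrix, expression: ScoreMatrix, epsilon: float = 0.0
) -> ScoreMatrix:
    """Return the depletion matrix with nonexpressed entries set to missing."""
    mask = nonexpression_mask(depletion, expression, epsilon)
    return ScoreMatrix(depletion.data.mask(mask), role=depletion.role)


def _group_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row count, mean and unbiased variance ignoring NaNs.

    ``values`` is (n_genes, n_cells); rows with fewer than 2 observations get
    NaN variance.
    """
    finite = ~np.isnan(values)
    n = finite.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nansum(values, axis=1) / n
        dev = values - mean[:, None]
        ss = np.nansum(dev * dev, axis=1)
        var = np.where(n > 1, ss / np.maximum(n - 1, 1), np.nan)
    return n, mean, var


def _t_test_rows(
    case: np.ndarray, control: np.ndarray, t_variant: str, min_group: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sided two-sample t-test over matrix rows.

    Returns (t, p, n_case, n_control, valid).  ``valid`` is False where the
    pair is skipped: a group smaller than ``min_group``, or a degenerate
    zero-variance comparison with equal means (no information either way).
    Zero variance with unequal means yields t = +/-inf, p = 0.
    """
    n1, m1, v1 = _group_stats(case)
    n0, m0, v0 = _group_stats(control)
    valid = (n1 >= min_group) & (n0 >= min_group)

    with np.errstate(invalid="ignore", divide="ignore"):
        if t_variant == "welch":
            se2 = v1 / n1 + v0 / n0
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
        else:
            sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
            se2 = sp2 * (1 / n1 + 1 / n0)
            df = n1 + n0 - 2.0
        diff = m1 - m0
        t = diff / np.sqrt(se2)

    zero_se = se2 == 0
    equal_means = diff == 0
    valid &= ~(zero_se & equal_means)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se & ~equal_means, np.sign(diff) * np.inf, t)
    with np.errstate(invalid="ignore"):
        p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), np.where(df > 0, df, 1.0)))
    valid &= ~np.isnan(np.where(valid, t, 0.0))
    return t, p, n1, n0, valid


def test_pair(
    depletion_row_K: Sequence[float],
    mutation_row_Q: Sequence[int],
    config: TestConfig | None = None,
) -> PairResult | None:
    """Test one (Q, K) pair; returns None when the pair is skipped.

    ``depletion_row_K`` and ``mutation_row_Q`` must share the same cell
    ordering.  Case cells carry the mutation (1); direction is ``sensitive``
    when the case mean is below the control mean.
    """
    config = config or TestConfig()
    dep = np.asarray(depletion_row_K, dtype=float)
    mut = np.asarray(mutation_row_Q)
    if dep.shape != mut.shape:
        raise ConfigurationError("depletion and mutation rows must align on cells")
    case = np.where(mut == 1, dep, np.nan)[None, :]
    control = np.where(mut == 1, np.nan, dep)[None, :]
    t, p, n1, n0, valid = _t_test_rows(case, control, config.t_variant, config.min_group_size)
    if not valid[0]:
        return None
    direction = "sensitive" if t[0] < 0 else "resistant"
    return PairResult(float(t[0]), float(p[0]), direction, int(n1[0]), int(n0[0]))


def characterize_gis(
    depletion: ScoreMatrix,
    expression: ScoreMatrix | None,
    mutation_matrix: MutationMatrix,
    recurrent_genes: RecurrentGeneSet | Sequence[str],
    config: TestConfig | None = None,
    label: str = "screen",
) -> GITable:
    """Screen every (Q in recurrent genes) x (K in depletion genes) pair.

    Cells are aligned (sorted intersection) between the depletion and
    mutation sources; the expression matrix joins optionally through the
    masking step.  All performed tests form one BH family; records with
    fdr < ``config.fdr_threshold`` are returned sorted by (Q, K).
    """
    config = config or TestConfig()
    qs = sorted(set(recurrent_genes) & set(mutation_matrix.genes))
    if not qs:
        raise ConfigurationError("no recurrently mutated genes overlap the mutation matrix")
    if not depletion.genes:
        raise ConfigurationError("depletion matrix has no genes")

    alignment = align_cells(depletion, mutation_matrix, names=["depletion", "mutation"])
    cells = list(alignment.shared_cells)
    dep = depletion.subset_cells(cells)

    if config.exclusion_enabled and expression is not None:
        mask = nonexpression_mask(dep, expression, config.expression_zero_epsilon).to_numpy()
        values = np.where(mask, np.nan, dep.data.to_numpy(dtype=float))
        n_masked_entries = int(mask.sum())
    else:
        mask = np.zeros(dep.data.shape, dtype=bool)
        values = dep.data.to_numpy(dtype=float)
        n_masked_entries = 0

    genes_k = np.array(dep.genes)
    mut_calls = mutation_matrix.calls.loc[:, cells]

    rows = []
    all_p = []
    n_skipped = 0
    for q in qs:
        is_case = mut_calls.loc[q].to_numpy() == 1
        case = np.where(is_case[None, :], values, np.nan)
        control = np.where(is_case[None, :], np.nan, values)
        t, p, n1, n0, valid = _t_test_rows(case, control, config.t_variant, config.min_group_size)
        n_skipped += int((~valid).sum())
        masked_case = mask[:, is_case].sum(axis=1)
        masked_control = mask[:, ~is_case].sum(axis=1)
        idx = np.flatnonzero(valid)
        all_p.append(p[idx])
        for i in idx:
            rows.append(
                (
                    q,
                    genes_k[i],
                    "sensitive" if t[i] < 0 else "resistant",
                    t[i],
                    p[i],
                    n1[i],
                    n0[i],
                    masked_case[i],
                    masked_control[i],
                )
            )

    m_tests = sum(len(p) for p in all_p)
    logger.info(
        "%s: %d tests performed, %d skipped, %d depletion entries masked",
        label, m_tests, n_skipped, n_masked_entries,
    )
    if m_tests == 0:
        records = pd.DataFrame(columns=GI_TABLE_COLUMNS)
    else:
        fdr = bh_fdr(np.concatenate(all_p), m_tests)
        records = pd.DataFrame(
            rows,
            columns=[
                "mutated_gene",
                "target_gene",
                "direction",
                "t_stat",
                "p_value",
                "n_case",
                "n_control",
                "n_masked_case",
                "n_masked_control",
            ],
        )
        records["fdr"] = fdr
        records = records[records["fdr"] < config.fdr_threshold]
        records = records.sort_values(["mutated_gene", "target_gene"], kind="mergesort")
        records = records[GI_TABLE_COLUMNS].reset_index(drop=True)
        for col in ("n_case", "n_control", "n_masked_case", "n_masked_control"):
            records[col] = records[col].astype(int)

    snapshot = asdict(config)
    snapshot["n_masked_entries"] = n_masked_entries
    return GITable(
        records=records,
        label=label,
        m_tests=m_tests,
        n_skipped=n_skipped,
        config=snapshot,
    )
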
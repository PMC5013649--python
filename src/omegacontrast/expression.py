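"""Developmental-stage expression profiling of gene sets.

Works on a gene x stage table of RPKM values covering ten ordered
developmental stages (0-6 h embryo through adult male / female in the fly
scheme; any ten-stage scheme with the same ordering semantics is accepted).
Provides the per-stage expressed fraction (RPKM > 0) and highly-expressed
fraction (RPKM > 50) of a gene set, the five-level expression categories
(none / low / moderate / high / extremely high), chi-squared and Spearman
comparisons of two stage profiles, and transfer of a gene set into a
reference species' gene space through an orthologue map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "N_STAGES",
    "DEFAULT_STAGES",
    "HIGH_RPKM_CUTOFF",
    "ExpressionCategory",
    "ExpressionTable",
    "StageProfile",
    "ProfileComparison",
    "categorize_expression",
    "stage_profile",
    "compare_stage_profiles",
    "transfer_gene_set",
]

N_STAGES = 10
DEFAULT_STAGES = (
    "embryo_0_6h",
    "embryo_6_12h",
    "embryo_12_24h",
    "larva_L1",
    "larva_L2",
    "larva_L3",
    "pupa_early",
    "pupa_late",
    "adult_male",
    "adult_female",
)
HIGH_RPKM_CUTOFF = 50.0


class ExpressionCategory(Enum):
    NONE = "none"
    LOW = "low"  # >0 and <=10
    MODERATE = "moderate"  # >10 and <=50
    HIGH = "high"  # >50 and <=1000
    EXTREMELY_HIGH = "extremely_high"  # >1000


def categorize_expression(rpkm: float) -> ExpressionCategory:
    """Five-level expression category of a single RPKM value."""
    if rpkm < 0:
        raise ValueError(f"RPKM must be non-negative, got {rpkm}")
    if rpkm == 0:
        return ExpressionCategory.NONE
    if rpkm <= 10:
        return ExpressionCategory.LOW
    if rpkm <= 50:
        return ExpressionCategory.MODERATE
    if rpkm <= 1000:
        return ExpressionCategory.HIGH
    return ExpressionCategory.EXTREMELY_HIGH


class ExpressionTable:
    """Gene x stage RPKM matrix with exactly ten ordered stages."""

    def __init__(self, data: pd.DataFrame):
        if data.shape[1] != N_STAGES:
            raise ValueError(f"expression table must have {N_STAGES} stage columns, got {data.shape[1]}")
        if (data.values < 0).any():
            raise ValueError("expression table contains negative RPKM values")
        if data.index.has_duplicates:
            raise ValueError("expression table contains duplicate gene identifiers")
        self.data = data.astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", float_format="%.6g")


@dataclass(frozen=True)
class StageProfile:
    """Per-stage expressed / highly-expressed composition of a gene set."""

    stages: tuple[str, ...]
    n_genes: int
    expressed_counts: tuple[int, ...]  # RPKM > 0
    high_counts: tuple[int, ...]  # RPKM > 50
    missing_genes: tuple[str, ...] = ()

    @property
    def pct_expressed(self) -> tuple[float, ...]:
        return tuple(100.0 * c / self.n_genes for c in self.expressed_counts)

    @property
    def pct_high(self) -> tuple[float, ...]:
        return tuple(100.0 * c / self.n_genes for c in self.high_counts)

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "stages": list(self.stages),
            "pct_expressed": list(self.pct_expressed),
            "pct_high": list(self.pct_high),
            "n_missing": len(self.missing_genes),
        }


@dataclass(frozen=True)
class ProfileComparison:
    chi2_pvalues_expressed: tuple[float, ...]
    chi2_pvalues_high: tuple[float, ...]
    spearman_r_expressed: float
    spearman_p_expressed: float
    spearman_r_high: float
    spearman_p_high: float


def stage_profile(gene_set: Iterable[str], table: ExpressionTable) -> StageProfile:
    """Expressed and >50 RPKM fractions of a gene set at each stage.

    Genes absent from the table are excluded and reported, not an error.
    """
    genes = list(dict.fromkeys(gene_set))
    if not genes:
        raise ValueError("empty gene set")
    present = [g for g in genes if g in table.genes]
    missing = tuple(g for g in genes if g not in table.genes)
    if not present:
        raise ValueError("no genes of the set occur in the expression table")
    sub = table.data.loc[present]
    expressed = tuple(int(c) for c in (sub.values > 0).sum(axis=0))
    high = tuple(int(c) for c in (sub.values > HIGH_RPKM_CUTOFF).sum(axis=0))
    return StageProfile(
        stages=table.stages,
        n_genes=len(present),
        expressed_counts=expressed,
        high_counts=high,
        missing_genes=missing,
    )


def _chi2_2x2(k_a: int, n_a: int, k_b: int, n_b: int) -> float:
    """Two-sided chi-squared p on a 2x2 count table, no continuity correction."""
    table = np.array([[k_a, n_a - k_a], [k_b, n_b - k_b]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (empty row/column); p = 1", stacklevel=3)
        return 1.0
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def compare_stage_profiles(p_a: StageProfile, p_b: StageProfile) -> ProfileComparison:
    """Per-stage chi-squared tests plus Spearman correlation across stages.

    The chi-squared tests compare expressed / not-expressed (and high /
    not-high) counts stage by stage; the Spearman correlations compare the
    ten-value percentage vectors of the two profiles.
    """
    if p_a.stages != p_b.stages:
        raise ValueError("stage profiles cover different stage sets")
    chi_expr = tuple(
        _chi2_2x2(ka, p_a.n_genes, kb, p_b.n_genes)
        for ka, kb in zip(p_a.expressed_counts, p_b.expressed_counts)
    )
    chi_high = tuple(
        _chi2_2x2(ka, p_a.n_genes, kb, p_b.n_genes)
        for ka, kb in zip(p_a.high_counts, p_b.high_counts)
    )
    r_e, p_e = _spearman(p_a.pct_expressed, p_b.pct_expressed)
    r_h, p_h = _spearman(p_a.pct_high, p_b.pct_high)
    return ProfileComparison(
        chi2_pvalues_expressed=chi_expr,
        chi2_pvalues_high=chi_high,
        spearman_r_expressed=r_e,
        spearman_p_expressed=p_e,
        spearman_r_high=r_h,
        spearman_p_high=p_h,
    )


def _spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    if len(set(x)) == 1 or len(set(y)) == 1:
        # rank correlation undefined for a constant vector
        warnings.warn("constant percentage vector; Spearman undefined, returning r=nan", stacklevel=3)
        return float("nan"), 1.0
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def transfer_gene_set(
    gene_set: Iterable[str], ortho_map: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    """Map a gene set into a reference gene space via an orthologue map.

    Returns (mapped reference genes, unmapped source genes); order follows
    the input set.
    """
    mapped: list[str] = []
    unmapped: list[str] = []
    for g in dict.fromkeys(gene_set):
        if g in ortho_map:
            mapped.append(ortho_map[g])
        else:
            unmapped.append(g)
    return mapped, unmapped
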
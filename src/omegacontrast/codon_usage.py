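"""Optimal-codon identification and frequency-of-optimal-codons (Fop).

Optimal codons are the synonymous codons preferentially used by highly
expressed genes. They are identified here by contrasting within-amino-acid
relative codon usage between a highly expressed and a lowly expressed gene
class: for each amino acid with two or more codons, the codon with the
largest positive usage increase in the high class is declared optimal when a
2x2 chi-squared test (that codon versus the amino acid's other codons, high
versus low class) is significant. Fop of a gene is then the fraction of its
codons, among amino acids that have an optimal codon, that are optimal; low
Fop is a classic correlate of fast protein evolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .codon_core import STANDARD_CODE, STOP_SYMBOL
from .sequence_qc import CodingSequence

__all__ = [
    "OptimalCodonCall",
    "OptimalCodonTable",
    "FopResult",
    "FopDistribution",
    "codon_usage_counts",
    "identify_optimal_codons",
    "compute_fop",
    "fop_distribution",
    "write_optimal_codon_tsv",
]

logger = logging.getLogger(__name__)

# amino acid -> synonymous codon family, single-codon families excluded
_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in STANDARD_CODE.codon_to_aa.items():
    if _aa != STOP_SYMBOL:
        _FAMILIES.setdefault(_aa, ())
        _FAMILIES[_aa] = tuple(sorted((*_FAMILIES[_aa], _codon)))
DEGENERATE_FAMILIES = {aa: cs for aa, cs in _FAMILIES.items() if len(cs) > 1}


@dataclass(frozen=True)
class OptimalCodonCall:
    amino_acid: str
    codon: str
    delta_usage: float  # relative-usage difference, high minus low class
    p_value: float


@dataclass(frozen=True)
class OptimalCodonTable:
    """At most one optimal codon per degenerate amino-acid family."""

    calls: tuple[OptimalCodonCall, ...]

    def __post_init__(self) -> None:
        aas = [c.amino_acid for c in self.calls]
        if len(aas) != len(set(aas)):
            raise ValueError("more than one optimal codon for an amino acid")

    @property
    def optimal_codons(self) -> frozenset[str]:
        return frozenset(c.codon for c in self.calls)

    @property
    def amino_acids(self) -> frozenset[str]:
        return frozenset(c.amino_acid for c in self.calls)


@dataclass(frozen=True)
class FopResult:
    gene_id: str
    n_optimal: int
    n_counted: int

    @property
    def fop(self) -> float | None:
        if self.n_counted == 0:
            return None
        return self.n_optimal / self.n_counted


@dataclass(frozen=True)
class FopDistribution:
    n_genes: int
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    normality_p: float
    degenerate: bool
    histogram_counts: tuple[int, ...]
    histogram_edges: tuple[float, ...]


def _iter_codons(sequence: str) -> Iterable[str]:
    for i in range(0, len(sequence) - len(sequence) % 3, 3):
        yield sequence[i : i + 3]


def codon_usage_counts(seqs: Iterable[CodingSequence]) -> dict[str, dict[str, int]]:
    """Sense-codon counts grouped by amino acid; stop codons are skipped."""
    counts: dict[str, dict[str, int]] = {
        aa: {c: 0 for c in codons} for aa, codons in _FAMILIES.items()
    }
    for cds in seqs:
        for codon in _iter_codons(cds.sequence):
            aa = STANDARD_CODE.codon_to_aa.get(codon)
            if aa is None or aa == STOP_SYMBOL:
                continue
            counts[aa][codon] += 1
    return counts


def identify_optimal_codons(
    high_expr: Iterable[CodingSequence],
    low_expr: Iterable[CodingSequence],
    alpha: float = 0.05,
) -> OptimalCodonTable:
    """Call one optimal codon per amino acid from a high/low expression contrast.

    For each amino acid with >= 2 codons present in both classes, the codon
    with the largest increase in within-family relative usage in the high
    class is the candidate; it is declared optimal iff the increase is
    strictly positive, unique, and the 2x2 chi-squared test (candidate vs
    rest of family, high vs low class) gives p < alpha.
    """
    hi = codon_usage_counts(high_expr)
    lo = codon_usage_counts(low_expr)
    calls: list[OptimalCodonCall] = []
    for aa, codons in sorted(DEGENERATE_FAMILIES.items()):
        hi_total = sum(hi[aa].values())
        lo_total = sum(lo[aa].values())
        if hi_total == 0 or lo_total == 0:
            logger.info("amino acid %s absent from one expression class; no call", aa)
            continue
        deltas = {
            c: hi[aa][c] / hi_total - lo[aa][c] / lo_total for c in codons
        }
        best_delta = max(deltas.values())
        best_codons = [c for c, d in deltas.items() if d == best_delta]
        if best_delta <= 0 or len(best_codons) != 1:
            continue
        cand = best_codons[0]
        table = np.array(
            [
                [hi[aa][cand], hi_total - hi[aa][cand]],
                [lo[aa][cand], lo_total - lo[aa][cand]],
            ],
            dtype=float,
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            continue
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
        if p < alpha:
            calls.append(
                OptimalCodonCall(amino_acid=aa, codon=cand, delta_usage=best_delta, p_value=float(p))
            )
    return OptimalCodonTable(calls=tuple(calls))


def compute_fop(cds: CodingSequence, table: OptimalCodonTable) -> FopResult:
    """Per-gene frequency of optimal codons.

    Counts only codons whose amino acid has an optimal codon in ``table``;
    methionine, tryptophan (single-codon families) and stop codons never
    contribute. A gene with no countable codons is flagged by
    ``n_counted = 0`` (fop undefined).
    """
    if not table.calls:
        raise ValueError("optimal codon table is empty")
    counted_aas = table.amino_acids
    optimal = table.optimal_codons
    n_counted = 0
    n_optimal = 0
    for codon in _iter_codons(cds.sequence):
        aa = STANDARD_CODE.codon_to_aa.get(codon)
        if aa is None or aa == STOP_SYMBOL or aa not in counted_aas:
            continue
        n_counted += 1
        if codon in optimal:
            n_optimal += 1
    return FopResult(gene_id=cds.gene_id, n_optimal=n_optimal, n_counted=n_counted)


def fop_distribution(
    genome: Iterable[CodingSequence], table: OptimalCodonTable, n_bins: int = 20
) -> FopDistribution:
    """Distribution summary (moments, normality, histogram) of per-gene Fop."""
    fops = [
        r.fop
        for r in (compute_fop(cds, table) for cds in genome)
        if r.fop is not None
    ]
    if len(fops) < 30:
        raise ValueError(f"need >= 30 genes with defined Fop, got {len(fops)}")
    x = np.asarray(fops, dtype=float)
    degenerate = bool(np.all(x == x[0]))
    if degenerate:
        normality_p = float("nan")
        skew = kurt = float("nan")
    else:
        normality_p = float(stats.shapiro(x[:5000]).pvalue)
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x))
    counts, edges = np.histogram(x, bins=n_bins, range=(0.0, 1.0))
    return FopDistribution(
        n_genes=len(fops),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if len(fops) > 1 else 0.0,
        skewness=skew,
        kurtosis=kurt,
        normality_p=normality_p,
        degenerate=degenerate,
        histogram_counts=tuple(int(c) for c in counts),
        histogram_edges=tuple(float(e) for e in edges),
    )


def write_optimal_codon_tsv(table: OptimalCodonTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("amino_acid\tcodon\tdelta_usage\tp_value\n")
        for call in table.calls:
            fh.write(f"{call.amino_acid}\t{call.codon}\t{call.delta_usage:.6g}\t{call.p_value:.3g}\n")
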
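"""Nei-Gojobori (1986) dN/dS estimation on gap-free codon alignments.

The estimator has four steps:

1. Potential sites. Each codon contributes s(c) synonymous and n(c) = 3 - s(c)
   nonsynonymous sites, where s(c) sums, over the three positions, the
   fraction of single-base changes that are silent. Per alignment, S and N
   are the averages of the two sequences' totals, so N + S = 3L exactly.
2. Observed differences. For a codon pair differing at k positions (k <= 3),
   all k! orderings of single-base steps are enumerated; orderings passing
   through a stop codon are discarded; synonymous and nonsynonymous step
   counts are averaged over the remaining orderings, so Sd + Nd = k.
3. Proportions pS = Sd/S and pN = Nd/N.
4. Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p), applied to each
   proportion, with p >= 3/4 flagged as saturated.

omega = dN/dS is reported only for records with dS > 0 and no saturation;
records with dS = 0 are flagged and excluded from omega summaries (but kept
in audit tables). All per-codon quantities are exact rationals; floats enter
only at the Jukes-Cantor step.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from pathlib import Path
from typing import Iterable

import pandas as pd

from .codon_alignment import CodonAlignment
from .codon_core import STANDARD_CODE, InvalidSequenceError, synonymous_site_count
from .codon_core import canonicalize

__all__ = [
    "DnDsRecord",
    "SaturationError",
    "FLAG_OK",
    "FLAG_DS_ZERO",
    "FLAG_SATURATED",
    "count_sites",
    "count_differences",
    "jukes_cantor",
    "compute_dnds",
    "records_to_dataframe",
    "write_dnds_tsv",
]

logger = logging.getLogger(__name__)

FLAG_OK = "ok"
FLAG_DS_ZERO = "ds_zero"
FLAG_SATURATED = "saturated"

_SITE_SUM_TOLERANCE = 1e-9


class SaturationError(ValueError):
    """Observed proportion of differences is outside the Jukes-Cantor domain."""


@dataclass(frozen=True)
class DnDsRecord:
    """Per-orthologue-pair NG86 counts, rates and status flag."""

    gene_a: str
    gene_b: str
    n_codons: int
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float | None
    dS: float | None
    omega: float | None
    flag: str

    @property
    def pair_id(self) -> str:
        return f"{self.gene_a}|{self.gene_b}"


def count_sites(alignment: CodonAlignment) -> tuple[Fraction, Fraction]:
    """Potential (N, S) site counts of an alignment, averaged over sequences."""
    if len(alignment) == 0:
        raise ValueError("cannot count sites of an empty alignment")
    s_a = sum((synonymous_site_count(c) for c in alignment.codons_a), Fraction(0))
    s_b = sum((synonymous_site_count(c) for c in alignment.codons_b), Fraction(0))
    S = (s_a + s_b) / 2
    N = Fraction(3 * len(alignment)) - S
    return N, S


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> tuple[Fraction, Fraction]:
    """Pathway-averaged (Nd, Sd) differences between two sense codons.

    Orderings of the single-base steps that pass through a stop codon are
    excluded from the average. If every ordering is blocked (possible only
    for some three-difference pairs), the average falls back to all
    orderings, counting steps into or out of stop codons as nonsynonymous;
    each fallback is logged.
    """
    codon_a = canonicalize(codon_a)
    codon_b = canonicalize(codon_b)
    for c in (codon_a, codon_b):
        if c not in STANDARD_CODE.codon_to_aa or STANDARD_CODE.is_stop(c):
            raise InvalidSequenceError(f"difference counting requires sense codons, got {c!r}")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_positions)
    if k == 0:
        return Fraction(0), Fraction(0)

    pathways = _enumerate_pathways(codon_a, codon_b, diff_positions, allow_stops=False)
    if not pathways:
        logger.debug(
            "all substitution pathways between %s and %s pass through stops; "
            "falling back to stop-permissive averaging",
            codon_a,
            codon_b,
        )
        pathways = _enumerate_pathways(codon_a, codon_b, diff_positions, allow_stops=True)

    n_total = Fraction(0)
    s_total = Fraction(0)
    for nd, sd in pathways:
        n_total += nd
        s_total += sd
    n_paths = len(pathways)
    return n_total / n_paths, s_total / n_paths


def _enumerate_pathways(
    codon_a: str, codon_b: str, diff_positions: list[int], allow_stops: bool
) -> list[tuple[int, int]]:
    """(Nd, Sd) step counts for each admissible ordering of the differences."""
    table = STANDARD_CODE.codon_to_aa
    results: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_positions):
        current = codon_a
        nd = sd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if table[nxt] == "*" and not allow_stops:
                blocked = True
                break
            if table[nxt] != "*" and table[current] != "*" and table[nxt] == table[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            results.append((nd, sd))
    return results


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - (4/3)p)."""
    if p < 0:
        raise ValueError(f"proportion must be non-negative, got {p}")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} >= 3/4: distance saturated")
    if p == 0:
        return 0.0
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def compute_dnds(alignment: CodonAlignment, gene_a: str = "?", gene_b: str = "?") -> DnDsRecord:
    """Full NG86 estimate for one gap-free codon alignment."""
    N, S = count_sites(alignment)
    Nd = Fraction(0)
    Sd = Fraction(0)
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        nd, sd = count_differences(ca, cb)
        Nd += nd
        Sd += sd
    L = len(alignment)
    assert abs(float(N + S) - 3 * L) < _SITE_SUM_TOLERANCE

    pN = float(Nd / N) if N > 0 else 0.0
    pS = float(Sd / S) if S > 0 else 0.0

    flag = FLAG_OK
    dN: float | None = None
    dS: float | None = None
    try:
        dN = jukes_cantor(pN)
        dS = jukes_cantor(pS)
    except SaturationError:
        flag = FLAG_SATURATED
    if flag == FLAG_OK and dS == 0.0:
        flag = FLAG_DS_ZERO

    omega = dN / dS if flag == FLAG_OK else None
    return DnDsRecord(
        gene_a=gene_a,
        gene_b=gene_b,
        n_codons=L,
        N=float(N),
        S=float(S),
        Nd=float(Nd),
        Sd=float(Sd),
        pN=pN,
        pS=pS,
        dN=dN,
        dS=dS,
        omega=omega,
        flag=flag,
    )


def records_to_dataframe(records: Iterable[DnDsRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene_a": r.gene_a,
            "gene_b": r.gene_b,
            "L_codons": r.n_codons,
            "N": r.N,
            "S": r.S,
            "Nd": r.Nd,
            "Sd": r.Sd,
            "dN": r.dN,
            "dS": r.dS,
            "omega": r.omega,
            "flag": r.flag,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "L_codons", "N", "S", "Nd", "Sd", "dN", "dS", "omega", "flag"],
    )


def write_dnds_tsv(records: Iterable[DnDsRecord], path: str | Path) -> None:
    records_to_dataframe(records).to_csv(path, sep="\t", index=False, float_format="%.6g")
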
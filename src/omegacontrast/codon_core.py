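"""Standard genetic code machinery.

Everything downstream — orthology scoring, codon alignment, NG86 counting,
codon-usage statistics — rests on three primitives defined here: translation
under the standard nuclear code, classification of single-nucleotide changes
as synonymous / nonsynonymous / nonsense, and the per-codon fractional count
of synonymous sites (the NG86 "potential sites" definition, in which each
codon position contributes the fraction of its three possible single-base
changes that are silent).

Only the standard nuclear genetic code is supported; all taxa this pipeline
is aimed at use it. Sequences carrying other codes are rejected at input
rather than silently mistranslated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from functools import lru_cache
from typing import Mapping

__all__ = [
    "BASES",
    "STOP_SYMBOL",
    "STOP_CODONS",
    "GeneticCode",
    "STANDARD_CODE",
    "ChangeClass",
    "InvalidSequenceError",
    "canonicalize",
    "translate",
    "classify_change",
    "position_nonsynonymous_fraction",
    "first_position_nonsynonymous_fraction",
    "synonymous_site_count",
    "nonsynonymous_site_count",
]

BASES = "ACGT"
STOP_SYMBOL = "*"
STOP_CODONS = ("TAA", "TAG", "TGA")

# Standard code (NCBI table 1) spelled out in TCAG nesting order.
_TCAG = "TCAG"
_AA_STRING = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"


class InvalidSequenceError(ValueError):
    """A nucleotide sequence violates the coding-sequence contract."""


@dataclass(frozen=True)
class GeneticCode:
    """A codon-to-amino-acid table with its sense/stop partition."""

    codon_to_aa: Mapping[str, str]
    sense_codons: tuple[str, ...] = field(init=False)
    stop_codons: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"genetic code must have 64 codons, got {len(self.codon_to_aa)}")
        stops = tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa == STOP_SYMBOL))
        sense = tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa != STOP_SYMBOL))
        object.__setattr__(self, "stop_codons", stops)
        object.__setattr__(self, "sense_codons", sense)

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == STOP_SYMBOL


def _build_standard_table() -> dict[str, str]:
    return {
        b1 + b2 + b3: aa
        for (b1, b2, b3), aa in zip(itertools.product(_TCAG, repeat=3), _AA_STRING)
    }


STANDARD_CODE = GeneticCode(codon_to_aa=_build_standard_table())


class ChangeClass(Enum):
    """Class of a single-nucleotide change away from a sense codon."""

    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    NONSENSE = "nonsense"


def canonicalize(sequence: str) -> str:
    """Uppercase a nucleotide sequence and map RNA U to T.

    Does not validate the alphabet; callers that require strict ACGT should
    check separately (``sequence_qc`` does).
    """
    return sequence.upper().replace("U", "T")


def translate(cds: str) -> str:
    """Translate a coding nucleotide sequence under the standard code.

    Stop codons are rendered as ``*``. The sequence must consist only of
    A/C/G/T (after canonicalization) and have length divisible by three;
    violations raise :class:`InvalidSequenceError` naming the offending
    position.
    """
    seq = canonicalize(cds)
    if len(seq) % 3 != 0:
        raise InvalidSequenceError(
            f"sequence length {len(seq)} is not a multiple of 3"
        )
    for i, base in enumerate(seq):
        if base not in BASES:
            raise InvalidSequenceError(f"invalid nucleotide {base!r} at position {i}")
    table = STANDARD_CODE.codon_to_aa
    return "".join(table[seq[i : i + 3]] for i in range(0, len(seq), 3))


def classify_change(codon: str, position: int, new_base: str) -> ChangeClass:
    """Classify the single-base change ``codon[position-1] -> new_base``.

    ``position`` is 1-based (1..3). The starting codon must be a sense codon
    and ``new_base`` must differ from the current base at that position.
    """
    codon = canonicalize(codon)
    new_base = canonicalize(new_base)
    if position not in (1, 2, 3):
        raise ValueError(f"position must be 1..3, got {position}")
    if codon not in STANDARD_CODE.codon_to_aa:
        raise InvalidSequenceError(f"not a codon: {codon!r}")
    if STANDARD_CODE.is_stop(codon):
        raise InvalidSequenceError(f"stop codon {codon} has no change class")
    if new_base not in BASES:
        raise InvalidSequenceError(f"invalid nucleotide {new_base!r}")
    if codon[position - 1] == new_base:
        raise ValueError(
            f"new base {new_base} equals existing base at position {position} of {codon}"
        )
    mutated = codon[: position - 1] + new_base + codon[position:]
    if STANDARD_CODE.is_stop(mutated):
        return ChangeClass.NONSENSE
    if STANDARD_CODE.codon_to_aa[mutated] == STANDARD_CODE.codon_to_aa[codon]:
        return ChangeClass.SYNONYMOUS
    return ChangeClass.NONSYNONYMOUS


def position_nonsynonymous_fraction(position: int) -> float:
    """Percentage of single-base changes at ``position`` that alter the protein.

    Enumerates all 61 sense codons x 3 alternative bases (183 changes) at the
    given codon position and returns the percentage that do not preserve the
    amino acid. Changes that create a stop codon are counted as altering the
    protein. At the first position this comes to 175/183 ~ 96%; at the second
    position every change is amino-acid-altering (100%).
    """
    total = 0
    changing = 0
    for codon in STANDARD_CODE.sense_codons:
        current = codon[position - 1]
        for base in BASES:
            if base == current:
                continue
            total += 1
            if classify_change(codon, position, base) is not ChangeClass.SYNONYMOUS:
                changing += 1
    return 100.0 * changing / total


def first_position_nonsynonymous_fraction() -> float:
    """Percentage of first-codon-position changes that alter the amino acid."""
    return position_nonsynonymous_fraction(1)


@lru_cache(maxsize=None)
def synonymous_site_count(codon: str) -> Fraction:
    """NG86 synonymous site count s(c) of a sense codon, as an exact rational.

    Each position contributes (number of synonymous single-base changes at
    that position) / 3. Nonsense changes count toward the nonsynonymous side,
    so s(c) + n(c) = 3 holds exactly for every sense codon.
    """
    codon = canonicalize(codon)
    if codon not in STANDARD_CODE.codon_to_aa or STANDARD_CODE.is_stop(codon):
        raise InvalidSequenceError(f"synonymous sites undefined for {codon!r}")
    syn = 0
    for pos in (1, 2, 3):
        for base in BASES:
            if base == codon[pos - 1]:
                continue
            if classify_change(codon, pos, base) is ChangeClass.SYNONYMOUS:
                syn += 1
    return Fraction(syn, 3)


def nonsynonymous_site_count(codon: str) -> Fraction:
    """NG86 nonsynonymous site count n(c) = 3 - s(c)."""
    return Fraction(3) - synonymous_site_count(codon)
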
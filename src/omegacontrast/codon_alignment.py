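"""Codon-level pairwise alignment by protein alignment and back-translation.

For each orthologue pair the two proteins are globally aligned
(Needleman-Wunsch, BLOSUM62, affine gaps), the alignment is projected back
onto the underlying codons, and every column containing a gap in either
sequence is deleted (complete-deletion convention). The result is a gap-free
codon alignment suitable for NG86 counting. This is what "codon level"
alignment tools do internally for a pair of coding sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .codon_core import STANDARD_CODE, InvalidSequenceError, canonicalize

__all__ = ["CodonAlignment", "align_proteins_global", "backtranslate_and_drop_gaps", "align_cds_pair"]

# Gap of length L costs open + L*extend = 10 + L (see orthology module for
# the biopython open-score convention).
_GAP_OPEN = 10
_GAP_EXTEND = 1

GAP = "-"


@dataclass(frozen=True)
class CodonAlignment:
    """Column-aligned, gap-free codon sequences for one orthologue pair."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]
    n_columns_dropped: int = 0

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon alignment columns must pair off exactly")
        for codon in (*self.codons_a, *self.codons_b):
            if codon not in STANDARD_CODE.codon_to_aa or STANDARD_CODE.is_stop(codon):
                raise InvalidSequenceError(f"codon alignment contains non-sense codon {codon!r}")

    def __len__(self) -> int:
        return len(self.codons_a)


def make_global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -(_GAP_OPEN + _GAP_EXTEND)
    aligner.extend_gap_score = -_GAP_EXTEND
    return aligner


_ALIGNER = make_global_aligner()


def align_proteins_global(p_a: str, p_b: str) -> tuple[str, str]:
    """Global protein alignment; returns the two gapped sequences.

    The first optimal alignment reported by the dynamic program is used,
    which makes the traceback deterministic for a fixed scoring scheme.
    """
    if not p_a or not p_b:
        raise ValueError("cannot align an empty protein sequence")
    alignment = _ALIGNER.align(p_a, p_b)[0]
    return str(alignment[0]), str(alignment[1])


def backtranslate_and_drop_gaps(
    aligned_a: str,
    aligned_b: str,
    cds_a: str,
    cds_b: str,
    gene_a: str = "?",
    gene_b: str = "?",
) -> CodonAlignment:
    """Project a gapped protein alignment onto codons and delete gap columns.

    ``cds_a`` / ``cds_b`` must be the ungapped coding sequences whose
    translations were aligned (length exactly 3x the ungapped protein
    length); a mismatch raises an error naming the gene.
    """
    cds_a = canonicalize(cds_a)
    cds_b = canonicalize(cds_b)
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned proteins differ in length")
    for aligned, cds, gene in ((aligned_a, cds_a, gene_a), (aligned_b, cds_b, gene_b)):
        n_res = sum(1 for c in aligned if c != GAP)
        if len(cds) != 3 * n_res:
            raise ValueError(
                f"gene {gene}: CDS length {len(cds)} != 3 x {n_res} aligned residues"
            )
    codons_a: list[str] = []
    codons_b: list[str] = []
    dropped = 0
    ia = ib = 0
    for ca, cb in zip(aligned_a, aligned_b):
        codon_a = cds_a[3 * ia : 3 * ia + 3] if ca != GAP else None
        codon_b = cds_b[3 * ib : 3 * ib + 3] if cb != GAP else None
        if ca != GAP:
            ia += 1
        if cb != GAP:
            ib += 1
        if codon_a is None or codon_b is None:
            dropped += 1
            continue
        codons_a.append(codon_a)
        codons_b.append(codon_b)
    return CodonAlignment(
        codons_a=tuple(codons_a), codons_b=tuple(codons_b), n_columns_dropped=dropped
    )


def align_cds_pair(cds_a: str, cds_b: str, gene_a: str = "?", gene_b: str = "?") -> CodonAlignment:
    """Convenience: translate, align globally, back-translate, drop gap columns."""
    from .codon_core import translate

    aligned_a, aligned_b = align_proteins_global(translate(cds_a), translate(cds_b))
    return backtranslate_and_drop_gaps(aligned_a, aligned_b, cds_a, cds_b, gene_a, gene_b)
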
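"""Reciprocal-best-hit orthology between two species' CDS sets.

Orthologues are called by translating each QC-passed CDS, scoring all
candidate cross-species protein pairs with local (Smith-Waterman) alignment
under BLOSUM62 with affine gaps, and keeping a pair only when each gene is
the other's unique top-scoring hit with score at least ``min_score``. This
emulates the classic reciprocal-BLASTX protocol with an in-process scorer:
an e-value cutoff depends on database size, so the acceptance criterion is a
raw score threshold instead (default 50).

A shared-k-mer prefilter prunes the candidate set for speed; the accept /
reject decision for any surviving candidate is always made on the full
alignment score. Genes whose best hit is tied between two or more partners
are conservatively left unpaired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .codon_core import translate
from .sequence_qc import CodingSequence

__all__ = [
    "OrthologuePair",
    "make_local_aligner",
    "score_translated_pair",
    "select_longest_isoforms",
    "reciprocal_best_hits",
    "write_ortho_map",
    "read_ortho_map",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 50.0

# BLAST-style affine gap cost: a gap of length L costs open + L*extend
# = 11 + L. Biopython charges open_gap_score for the first gap position and
# extend_gap_score for each subsequent one, hence the -12 below.
_GAP_OPEN = 11
_GAP_EXTEND = 1


@dataclass(frozen=True)
class OrthologuePair:
    gene_a: str
    gene_b: str
    score: float


def make_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "local"
    aligner.open_gap_score = -(_GAP_OPEN + _GAP_EXTEND)
    aligner.extend_gap_score = -_GAP_EXTEND
    return aligner


_ALIGNER = make_local_aligner()


def score_translated_pair(query: str, target: str) -> float:
    """Local alignment score of two protein sequences (BLOSUM62, 11/1 gaps).

    Symmetric in its arguments. Empty sequences are rejected.
    """
    if not query or not target:
        raise ValueError("cannot score an empty protein sequence")
    return float(_ALIGNER.score(query, target))


def gene_prefix(gene_id: str) -> str:
    """Isoform grouping key: the identifier up to the first '.'."""
    return gene_id.split(".", 1)[0]


def select_longest_isoforms(seqs: list[CodingSequence]) -> list[CodingSequence]:
    """Keep only the longest sequence per gene-id prefix.

    Mirrors the behaviour of best-hit searches over isoform-redundant CDS
    sets, which effectively retain the longest isoform per gene. Ties in
    length are broken by identifier order for determinism.
    """
    best: dict[str, CodingSequence] = {}
    for cds in seqs:
        key = gene_prefix(cds.gene_id)
        cur = best.get(key)
        # longer wins; equal length -> lexicographically smaller id wins
        if cur is None or len(cds) > len(cur) or (len(cds) == len(cur) and cds.gene_id < cur.gene_id):
            best[key] = cds
    return [best[k] for k in sorted(best)]


def _kmer_set(protein: str, k: int) -> set[str]:
    return {protein[i : i + k] for i in range(len(protein) - k + 1)}


def reciprocal_best_hits(
    set_a: list[CodingSequence],
    set_b: list[CodingSequence],
    min_score: float = DEFAULT_MIN_SCORE,
    prefilter_k: int = 4,
    prefilter_min_shared: int = 2,
    collapse_isoforms: bool = True,
) -> list[OrthologuePair]:
    """Reciprocal best hits between two QC-passed CDS sets.

    Returns a partial matching: each gene appears in at most one pair, and a
    pair is emitted only when the two genes are each other's unique best
    scoring partner with score >= ``min_score``. Set ``prefilter_min_shared``
    to 0 to disable the k-mer prefilter and score every cross pair.
    """
    if collapse_isoforms:
        set_a = select_longest_isoforms(set_a)
        set_b = select_longest_isoforms(set_b)
    prots_a = [(cds.gene_id, translate(cds.sequence)) for cds in set_a]
    prots_b = [(cds.gene_id, translate(cds.sequence)) for cds in set_b]

    if prefilter_min_shared > 0:
        kmers_b = [(gid, _kmer_set(p, prefilter_k)) for gid, p in prots_b]
        candidates = []
        for ia, (_, pa) in enumerate(prots_a):
            ka = _kmer_set(pa, prefilter_k)
            for ib, (_, kb) in enumerate(kmers_b):
                if len(ka & kb) >= prefilter_min_shared:
                    candidates.append((ia, ib))
    else:
        candidates = [(ia, ib) for ia in range(len(prots_a)) for ib in range(len(prots_b))]

    scores: dict[tuple[int, int], float] = {}
    for ia, ib in candidates:
        scores[(ia, ib)] = score_translated_pair(prots_a[ia][1], prots_b[ib][1])

    best_for_a = _unique_argmax(scores, axis=0, n=len(prots_a))
    best_for_b = _unique_argmax(scores, axis=1, n=len(prots_b))

    pairs: list[OrthologuePair] = []
    for ia, ib in sorted(best_for_a.items()):
        if ib is None:
            continue
        if best_for_b.get(ib) == ia and scores[(ia, ib)] >= min_score:
            pairs.append(
                OrthologuePair(
                    gene_a=prots_a[ia][0],
                    gene_b=prots_b[ib][0],
                    score=scores[(ia, ib)],
                )
            )
    return pairs


def _unique_argmax(
    scores: dict[tuple[int, int], float], axis: int, n: int
) -> dict[int, int | None]:
    """Per row (axis=0) or column (axis=1), the unique best partner or None on tie."""
    best: dict[int, tuple[float, int | None]] = {}
    for (ia, ib), s in scores.items():
        key, partner = (ia, ib) if axis == 0 else (ib, ia)
        cur = best.get(key)
        if cur is None or s > cur[0]:
            best[key] = (s, partner)
        elif s == cur[0] and partner != cur[1]:
            best[key] = (s, None)  # tie for best -> exclude
    return {k: v[1] for k, v in best.items()}


def write_ortho_map(pairs: list[OrthologuePair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.score:g}\n")


def read_ortho_map(path: str | Path) -> list[OrthologuePair]:
    pairs = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_a"):
            raise ValueError(f"{path}: expected ortho-map header 'gene_a\\tgene_b\\tscore'")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            # score column optional: truth maps carry only the two gene ids
            score = float(fields[2]) if len(fields) > 2 and fields[2] else float("nan")
            pairs.append(OrthologuePair(gene_a=fields[0], gene_b=fields[1], score=score))
    return pairs
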
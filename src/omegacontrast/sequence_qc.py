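"""Coding-sequence input and retention filters.

Reads per-species CDS FASTA files and applies the retention rules used
throughout the pipeline: a CDS is kept only if its length is a multiple of
three, its alphabet is strictly A/C/G/T (no ambiguity codes), and it contains
no stop codon before the final codon. A terminal stop codon is permitted and
stripped, so database CDS deposited with and without stops are comparable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .codon_core import BASES, STANDARD_CODE, canonicalize

__all__ = [
    "CodingSequence",
    "QcReport",
    "FastaParseError",
    "read_cds_fasta",
    "apply_cds_filters",
]

logger = logging.getLogger(__name__)

REASON_AMBIGUOUS = "ambiguous"
REASON_INTERNAL_STOP = "internal_stop"
REASON_LENGTH = "length_not_multiple_of_3"


class FastaParseError(ValueError):
    pass


@dataclass(frozen=True)
class CodingSequence:
    """One nucleotide coding sequence with its identifiers."""

    gene_id: str
    sequence: str
    species: str = ""
    genus: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class QcReport:
    """Partition of an input CDS set into retained and rejected classes."""

    n_input: int = 0
    retained: int = 0
    rejected_ambiguous: int = 0
    rejected_internal_stop: int = 0
    rejected_length: int = 0
    reasons: dict[str, str] = field(default_factory=dict)  # gene_id -> reason / "ok"

    def check_conserved(self) -> bool:
        return (
            self.retained
            + self.rejected_ambiguous
            + self.rejected_internal_stop
            + self.rejected_length
            == self.n_input
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "retained": self.retained,
                "rejected_ambiguous": self.rejected_ambiguous,
                "rejected_internal_stop": self.rejected_internal_stop,
                "rejected_length": self.rejected_length,
            },
            indent=2,
            sort_keys=True,
        )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tstatus\treason\n")
            for gene_id in sorted(self.reasons):
                reason = self.reasons[gene_id]
                status = "retained" if reason == "ok" else "rejected"
                fh.write(f"{gene_id}\t{status}\t{reason}\n")


def read_cds_fasta(path: str | Path, species: str = "", genus: str = "") -> list[CodingSequence]:
    """Read a CDS FASTA file into :class:`CodingSequence` records.

    Order is preserved and duplicate identifiers are rejected. Species and
    genus are supplied by the caller (file-level metadata) rather than parsed
    from headers, which avoids depending on any particular header dialect.
    """
    path = Path(path)
    _precheck_fasta(path)
    records: list[CodingSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            CodingSequence(gene_id=rec.id, sequence=str(rec.seq), species=species, genus=genus)
        )
    if not records:
        logger.warning("FASTA file %s contains no records", path)
    return records


def _precheck_fasta(path: Path) -> None:
    """Require the first non-blank line to be a FASTA header."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: expected FASTA header line starting with '>'"
                )
            return


def _classify(sequence: str) -> tuple[str, str]:
    """Return (reason, cleaned_sequence); reason 'ok' means retained."""
    seq = canonicalize(sequence)
    if any(b not in BASES for b in seq):
        return REASON_AMBIGUOUS, seq
    if len(seq) == 0 or len(seq) % 3 != 0:
        return REASON_LENGTH, seq
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if any(STANDARD_CODE.is_stop(c) for c in codons[:-1]):
        return REASON_INTERNAL_STOP, seq
    if STANDARD_CODE.is_stop(codons[-1]):
        seq = seq[:-3]
        if not seq:
            return REASON_LENGTH, seq
    return "ok", seq


def apply_cds_filters(seqs: Iterable[CodingSequence]) -> tuple[list[CodingSequence], QcReport]:
    """Apply the CDS retention filters; returns (retained, report).

    Retained sequences are canonicalized (uppercase, U->T) and have any
    terminal stop codon stripped, so downstream stages see pure sense-codon
    sequences. Filtering is idempotent.
    """
    report = QcReport()
    retained: list[CodingSequence] = []
    for cds in seqs:
        report.n_input += 1
        reason, cleaned = _classify(cds.sequence)
        report.reasons[cds.gene_id] = reason
        if reason == "ok":
            report.retained += 1
            retained.append(
                CodingSequence(
                    gene_id=cds.gene_id,
                    sequence=cleaned,
                    species=cds.species,
                    genus=cds.genus,
                )
            )
        elif reason == REASON_AMBIGUOUS:
            report.rejected_ambiguous += 1
        elif reason == REASON_INTERNAL_STOP:
            report.rejected_internal_stop += 1
        else:
            report.rejected_length += 1
    return retained, report
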
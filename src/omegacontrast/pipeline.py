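"""Stage orchestration: QC -> orthology -> codon alignment -> NG86 -> contrasts.

The two entry points mirror the analysis design: :func:`run_species_pair`
takes the two CDS sets of a within-genus species pair through quality
control, reciprocal-best-hit orthology, codon alignment and NG86 estimation,
and bins the resulting omegas into the genome profile;
:func:`run_genus_contrast` compares two such within-genus results through the
matched-orthologue fold contrast, a genome-wide Mann-Whitney test, and the
90th-percentile dS sensitivity re-analysis.

Both functions are pure in (inputs, thresholds): re-running with identical
inputs produces identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from . import contrasts, expression as expr
from .codon_alignment import align_cds_pair
from .contrasts import ContrastSummary, GenusProfile
from .dnds_ng86 import FLAG_OK, DnDsRecord, compute_dnds
from .orthology import OrthologuePair, reciprocal_best_hits
from .sequence_qc import CodingSequence, QcReport, apply_cds_filters

__all__ = [
    "PairResult",
    "ContrastResult",
    "run_species_pair",
    "run_genus_contrast",
    "omega_map",
    "high_dnds_sets",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairResult:
    """Everything produced by a within-genus species-pair run."""

    genus: str
    pgc_mode: str
    qc_a: QcReport
    qc_b: QcReport
    ortho_pairs: tuple[OrthologuePair, ...]
    records: tuple[DnDsRecord, ...]
    profile: GenusProfile


@dataclass(frozen=True)
class ContrastResult:
    """A between-genus contrast plus its dS-filtered sensitivity re-run."""

    main: ContrastSummary
    sensitivity: ContrastSummary
    ds_quantile: float


def run_species_pair(
    seqs_a: Iterable[CodingSequence],
    seqs_b: Iterable[CodingSequence],
    genus: str = "",
    pgc_mode: str = "",
    min_score: float = 50.0,
    ortho_map: Sequence[tuple[str, str]] | None = None,
    prefilter_min_shared: int = 2,
) -> PairResult:
    """QC, orthology, codon alignment and NG86 for one species pair.

    ``ortho_map`` short-circuits the reciprocal-best-hit search with a known
    correspondence (e.g. a simulation truth map or a precomputed table);
    genes absent from the QC-retained sets are skipped.
    """
    kept_a, qc_a = apply_cds_filters(seqs_a)
    kept_b, qc_b = apply_cds_filters(seqs_b)
    logger.info(
        "%s QC: %d/%d and %d/%d CDS retained",
        genus or "pair", qc_a.retained, qc_a.n_input, qc_b.retained, qc_b.n_input,
    )
    by_id_a = {c.gene_id: c for c in kept_a}
    by_id_b = {c.gene_id: c for c in kept_b}

    if ortho_map is None:
        pairs = tuple(
            reciprocal_best_hits(
                kept_a, kept_b, min_score=min_score, prefilter_min_shared=prefilter_min_shared
            )
        )
    else:
        pairs = tuple(
            OrthologuePair(gene_a=a, gene_b=b, score=float("nan"))
            for a, b in ortho_map
            if a in by_id_a and b in by_id_b
        )
    logger.info("%s orthology: %d pairs", genus or "pair", len(pairs))

    records = []
    for p in pairs:
        alignment = align_cds_pair(
            by_id_a[p.gene_a].sequence, by_id_b[p.gene_b].sequence, p.gene_a, p.gene_b
        )
        records.append(compute_dnds(alignment, p.gene_a, p.gene_b))
    profile = contrasts.bin_omegas(records, genus=genus, pgc_mode=pgc_mode)
    return PairResult(
        genus=genus,
        pgc_mode=pgc_mode,
        qc_a=qc_a,
        qc_b=qc_b,
        ortho_pairs=pairs,
        records=tuple(records),
        profile=profile,
    )


def omega_map(records: Iterable[DnDsRecord], key: str = "gene_a") -> dict[str, float]:
    """gene id -> omega for records with a defined ratio."""
    return {
        getattr(r, key): r.omega
        for r in records
        if r.flag == FLAG_OK and r.omega is not None
    }


def run_genus_contrast(
    records_a: Sequence[DnDsRecord],
    records_b: Sequence[DnDsRecord],
    intergeneric_map: Sequence[tuple[str, str]],
    fold: float = 1.5,
    ds_quantile: float = 0.90,
    genus_a: str = "A",
    genus_b: str = "B",
    mode_a: str = "",
    mode_b: str = "",
) -> ContrastResult:
    """Fold contrast and MWU between two genera, with the dS sensitivity re-run.

    The sensitivity re-run repeats the identical contrast after dropping, in
    each genus separately, genes whose dS lies above the ``ds_quantile``
    percentile of that genus's dS distribution.
    """
    main = contrasts.fold_contrast(
        omega_map(records_a), omega_map(records_b), intergeneric_map,
        fold=fold, genus_a=genus_a, genus_b=genus_b, mode_a=mode_a, mode_b=mode_b,
    )
    filt_a = contrasts.ds_percentile_filter(records_a, q=ds_quantile)
    filt_b = contrasts.ds_percentile_filter(records_b, q=ds_quantile)
    sensitivity = contrasts.fold_contrast(
        omega_map(filt_a), omega_map(filt_b), intergeneric_map,
        fold=fold, genus_a=genus_a, genus_b=genus_b, mode_a=mode_a, mode_b=mode_b,
    )
    return ContrastResult(main=main, sensitivity=sensitivity, ds_quantile=ds_quantile)


def high_dnds_sets(
    omegas_a: Mapping[str, float],
    omegas_b: Mapping[str, float],
    intergeneric_map: Sequence[tuple[str, str]],
    fold: float = 1.5,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Split fold-divergent orthologues by which genus holds the larger omega.

    Returns two lists of (gene_a, gene_b) pairs: those with >= ``fold``-fold
    higher omega in the first genus, and those with the excess in the second.
    These are the gene sets whose developmental expression profiles the
    expression module compares.
    """
    higher_a: list[tuple[str, str]] = []
    higher_b: list[tuple[str, str]] = []
    for ga, gb in intergeneric_map:
        wa = omegas_a.get(ga)
        wb = omegas_b.get(gb)
        if wa is None or wb is None or (wa == 0.0 and wb == 0.0):
            continue
        threshold = fold * (1.0 - 1e-12)  # inclusive boundary despite rounding
        if wb == 0.0 or (wa > 0.0 and wa / wb >= threshold):
            higher_a.append((ga, gb))
        elif wa == 0.0 or wb / wa >= threshold:
            higher_b.append((ga, gb))
    return higher_a, higher_b
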
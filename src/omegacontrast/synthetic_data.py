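"""Seeded generators of synthetic inputs with the structure the pipeline assumes.

The generators emulate the study design the analysis targets: pairs of
closely related genomes (per-gene synonymous divergence well below
saturation, dS < 1), per-gene omega concentrated below 0.5, a known
orthologue correspondence, and stage-wise log-normal RPKM expression with
dropout. Every generator is driven by a NumPy ``Generator`` seeded by the
caller and is byte-reproducible for a fixed seed.

Sequence pairs are produced by proposal-acceptance (rejection) evolution:
single-base changes are proposed uniformly; synonymous proposals are always
accepted, nonsynonymous proposals with probability omega, and stop-creating
proposals never. Proposals continue until the accepted synonymous events per
ancestral synonymous site reach target_ds / 2 on each of the two lineages.
This controls the synonymous/nonsynonymous acceptance asymmetry exactly and
is adequate below saturation; it does not model codon-usage mutational bias
or indels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_core import BASES, STANDARD_CODE, synonymous_site_count
from .expression import DEFAULT_STAGES, ExpressionTable
from .sequence_qc import CodingSequence

__all__ = [
    "GenomePairSimulation",
    "ContrastSimulation",
    "simulate_ancestor",
    "evolve_pair",
    "simulate_genome_pair",
    "simulate_expression",
    "simulate_contrast_genera",
    "simulate_usage_biased_genes",
    "write_fasta",
    "default_omega_dist",
    "default_ds_dist",
    "default_length_dist",
]

_SENSE = STANDARD_CODE.sense_codons
_OTHER: dict[str, str] = {b: "".join(x for x in BASES if x != b) for b in BASES}
_TABLE = STANDARD_CODE.codon_to_aa

Dist = float | Sequence[float] | Callable[[np.random.Generator], float]


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw(dist: Dist, rng: np.random.Generator, i: int) -> float:
    if callable(dist):
        return float(dist(rng))
    if isinstance(dist, (int, float)):
        return float(dist)
    return float(dist[i % len(dist)])


def default_omega_dist(rng: np.random.Generator) -> float:
    """Per-gene omega: log-normal, median 0.15, most mass below 0.5.

    Mimics genome-wide omega profiles in which the large majority of genes
    sit in the strong-purifying-selection bin (omega < 0.5).
    """
    return float(min(np.exp(rng.normal(math.log(0.15), 0.8)), 2.0))


def default_ds_dist(rng: np.random.Generator) -> float:
    """Per-gene target dS: log-normal, median 0.25, kept below saturation."""
    return float(np.clip(np.exp(rng.normal(math.log(0.25), 0.3)), 0.05, 0.7))


def default_length_dist(rng: np.random.Generator) -> float:
    """Gene length in codons: log-normal, median 400, floor 50."""
    return float(max(np.exp(rng.normal(math.log(400.0), 0.4)), 50.0))


def simulate_ancestor(
    n_codons: int,
    codon_freqs: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> str:
    """A random sense-codon sequence starting with ATG.

    ``codon_freqs`` maps sense codons to sampling probabilities (uniform over
    the 61 sense codons when omitted) and must sum to 1.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = _as_rng(seed)
    if codon_freqs is None:
        codons = list(_SENSE)
        probs = np.full(len(codons), 1.0 / len(codons))
    else:
        codons = sorted(codon_freqs)
        for c in codons:
            if c not in _SENSE:
                raise ValueError(f"{c!r} is not a sense codon")
        probs = np.array([codon_freqs[c] for c in codons], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"codon frequencies sum to {probs.sum()}, not 1")
    draws = rng.choice(len(codons), size=n_codons - 1, p=probs)
    return "ATG" + "".join(codons[i] for i in draws)


def _synonymous_sites(codons: Sequence[str]) -> float:
    return float(sum(synonymous_site_count(c) for c in codons))


def _evolve_lineage(
    codons: list[str], omega: float, n_syn_events: int, rng: np.random.Generator
) -> list[str]:
    """Accumulate accepted changes until ``n_syn_events`` synonymous ones."""
    L = len(codons)
    syn = 0
    while syn < n_syn_events:
        ci = int(rng.integers(L))
        pos = int(rng.integers(3))
        codon = codons[ci]
        new_base = _OTHER[codon[pos]][int(rng.integers(3))]
        mutated = codon[:pos] + new_base + codon[pos + 1 :]
        if _TABLE[mutated] == "*":
            continue  # stop-creating proposals are rejected outright
        if _TABLE[mutated] == _TABLE[codon]:
            codons[ci] = mutated
            syn += 1
        elif rng.random() < omega:
            codons[ci] = mutated
    return codons


def evolve_pair(
    ancestor: str,
    omega: float,
    target_ds: float,
    seed: int | np.random.Generator = 0,
) -> tuple[str, str]:
    """Evolve two descendant sequences from a common ancestor.

    Divergence is split symmetrically: each lineage accumulates
    round(target_ds / 2 x S_ancestor) synonymous substitution events, with
    nonsynonymous events arising alongside at relative acceptance omega.
    """
    if omega <= 0:
        raise ValueError("omega must be positive (use a tiny value for the omega->0 limit)")
    if not 0 < target_ds < 0.75:
        raise ValueError(f"target_ds must lie in (0, 0.75), got {target_ds}")
    if len(ancestor) % 3:
        raise ValueError("ancestor length must be a multiple of 3")
    rng = _as_rng(seed)
    codons = [ancestor[i : i + 3] for i in range(0, len(ancestor), 3)]
    s_anc = _synonymous_sites(codons)
    n_events = int(round(target_ds / 2.0 * s_anc))
    if s_anc == 0 and target_ds > 0:
        raise ValueError("ancestor has no synonymous sites; target divergence unattainable")
    a = _evolve_lineage(list(codons), omega, n_events, rng)
    b = _evolve_lineage(list(codons), omega, n_events, rng)
    return "".join(a), "".join(b)


@dataclass(frozen=True)
class GenomePairSimulation:
    """A simulated within-genus species pair with its ground truth."""

    cds_a: tuple[CodingSequence, ...]
    cds_b: tuple[CodingSequence, ...]
    ortho_truth: tuple[tuple[str, str], ...]
    truth: pd.DataFrame = field(repr=False)  # gene_id, omega, target_ds, n_codons
    seed: int = 0


def simulate_genome_pair(
    n_genes: int,
    omega_dist: Dist | None = None,
    ds_dist: Dist | None = None,
    seed: int = 0,
    length_dist: Dist | None = None,
    genus: str = "SimGenus",
    species_a: str = "sim_sp1",
    species_b: str = "sim_sp2",
) -> GenomePairSimulation:
    """Simulate a within-genus species pair with known per-gene truth.

    Per-gene omega, target dS and length (codons) are drawn from the given
    distributions (scalars, cycled sequences, or callables taking the RNG);
    defaults are the package's standard study conditions.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    omega_dist = default_omega_dist if omega_dist is None else omega_dist
    ds_dist = default_ds_dist if ds_dist is None else ds_dist
    length_dist = default_length_dist if length_dist is None else length_dist

    cds_a: list[CodingSequence] = []
    cds_b: list[CodingSequence] = []
    ortho: list[tuple[str, str]] = []
    rows = []
    for i in range(n_genes):
        omega = _draw(omega_dist, rng, i)
        ds = _draw(ds_dist, rng, i)
        n_codons = int(round(_draw(length_dist, rng, i)))
        gene = f"g{i:05d}"
        ancestor = simulate_ancestor(n_codons, seed=rng)
        seq_a, seq_b = evolve_pair(ancestor, omega, ds, seed=rng)
        cds_a.append(CodingSequence(gene_id=gene, sequence=seq_a, species=species_a, genus=genus))
        cds_b.append(CodingSequence(gene_id=gene, sequence=seq_b, species=species_b, genus=genus))
        ortho.append((gene, gene))
        rows.append({"gene_id": gene, "omega": omega, "target_ds": ds, "n_codons": n_codons})
    truth = pd.DataFrame(rows)
    return GenomePairSimulation(
        cds_a=tuple(cds_a),
        cds_b=tuple(cds_b),
        ortho_truth=tuple(ortho),
        truth=truth,
        seed=seed,
    )


def simulate_expression(
    genes: Iterable[str],
    n_stages: int = 10,
    expressed_prob: float | Sequence[float] = 0.9,
    log_mean: float = math.log(12.0),
    log_sigma: float = 1.5,
    seed: int = 0,
    stages: Sequence[str] | None = None,
) -> ExpressionTable:
    """Stage-wise RPKM table: dropout-zero with probability 1 - expressed_prob,
    else log-normal RPKM.

    Defaults give per-stage expressed fractions around 90% and >50 RPKM
    fractions around 15%, in the range seen for real developmental
    transcriptomes.
    """
    genes = list(genes)
    rng = np.random.default_rng(seed)
    if stages is None:
        stages = DEFAULT_STAGES[:n_stages] if n_stages <= 10 else tuple(
            f"stage_{i}" for i in range(n_stages)
        )
    if np.isscalar(expressed_prob):
        probs = [float(expressed_prob)] * n_stages
    else:
        probs = [float(p) for p in expressed_prob]
        if len(probs) != n_stages:
            raise ValueError("expressed_prob must be scalar or one value per stage")
    for p in probs:
        if not 0 <= p <= 1:
            raise ValueError(f"expressed_prob {p} outside [0, 1]")
    values = np.zeros((len(genes), n_stages))
    for j, p in enumerate(probs):
        on = rng.random(len(genes)) < p
        rpkm = np.exp(rng.normal(log_mean, log_sigma, size=len(genes)))
        values[:, j] = np.where(on, rpkm, 0.0)
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=list(stages))
    return ExpressionTable(df)


@dataclass(frozen=True)
class ContrastSimulation:
    """Two simulated genera with a planted fold-divergence asymmetry."""

    genus_a: GenomePairSimulation
    genus_b: GenomePairSimulation
    intergeneric_map: tuple[tuple[str, str], ...]
    higher_in_a: frozenset[str]  # genes whose true omega is larger in genus A
    fold: float
    seed: int = 0


def simulate_contrast_genera(
    n_genes: int,
    frac_higher_in_first: float | None = 0.7,
    fold: float = 3.0,
    base_omega_dist: Dist | None = None,
    ds_dist: Dist | None = None,
    length_dist: Dist | None = None,
    seed: int = 0,
) -> ContrastSimulation:
    """Two genera of matched orthologues with a planted omega asymmetry.

    Every gene gets a base omega; a fixed fraction of genes (exactly
    round(n x frac)) has its omega multiplied by ``fold`` in genus A, the
    rest in genus B, so all orthologues are truly fold-divergent with a
    planted directional split. ``frac_higher_in_first=None`` plants no
    asymmetry at all (identical true omegas in both genera, evolved
    independently) for null contrasts.
    """
    rng = np.random.default_rng(seed)
    if base_omega_dist is None:
        base_omega_dist = lambda r: float(np.clip(np.exp(r.normal(math.log(0.12), 0.4)), 0.02, 0.45))
    if ds_dist is None:
        ds_dist = 0.3
    if length_dist is None:
        length_dist = default_length_dist

    base = [_draw(base_omega_dist, rng, i) for i in range(n_genes)]
    if frac_higher_in_first is None:
        omega_a = list(base)
        omega_b = list(base)
        higher_in_a: frozenset[str] = frozenset()
    else:
        n_a = int(round(n_genes * frac_higher_in_first))
        which_a = np.zeros(n_genes, dtype=bool)
        which_a[rng.permutation(n_genes)[:n_a]] = True
        omega_a = [w * fold if up else w for w, up in zip(base, which_a)]
        omega_b = [w if up else w * fold for w, up in zip(base, which_a)]
        higher_in_a = frozenset(f"g{i:05d}" for i in range(n_genes) if which_a[i])

    seed_a, seed_b = int(rng.integers(2**31)), int(rng.integers(2**31))
    genus_a = simulate_genome_pair(
        n_genes, omega_dist=omega_a, ds_dist=ds_dist, length_dist=length_dist,
        seed=seed_a, genus="GenusA", species_a="a_sp1", species_b="a_sp2",
    )
    genus_b = simulate_genome_pair(
        n_genes, omega_dist=omega_b, ds_dist=ds_dist, length_dist=length_dist,
        seed=seed_b, genus="GenusB", species_a="b_sp1", species_b="b_sp2",
    )
    intergeneric = tuple((f"g{i:05d}", f"g{i:05d}") for i in range(n_genes))
    return ContrastSimulation(
        genus_a=genus_a,
        genus_b=genus_b,
        intergeneric_map=intergeneric,
        higher_in_a=higher_in_a,
        fold=fold,
        seed=seed,
    )


def simulate_usage_biased_genes(
    n_genes: int,
    n_codons: int,
    preferred: Mapping[str, str],
    bias: float = 0.7,
    seed: int | np.random.Generator = 0,
    id_prefix: str = "hi",
) -> list[CodingSequence]:
    """Genes whose codon usage favours one planted codon per amino acid.

    Within each synonymous family the planted codon is drawn with probability
    ``bias`` and the family's other codons uniformly otherwise; families
    without a planted codon are uniform. ``bias`` equal to 1/family-size
    reproduces uniform usage.
    """
    rng = _as_rng(seed)
    from .codon_usage import DEGENERATE_FAMILIES

    for aa, codon in preferred.items():
        if aa not in DEGENERATE_FAMILIES or codon not in DEGENERATE_FAMILIES[aa]:
            raise ValueError(f"{codon!r} is not a degenerate-family codon for {aa!r}")
    families = sorted(DEGENERATE_FAMILIES)
    genes: list[CodingSequence] = []
    for g in range(n_genes):
        codons = ["ATG"]
        for _ in range(n_codons - 1):
            aa = families[int(rng.integers(len(families)))]
            fam = DEGENERATE_FAMILIES[aa]
            if aa in preferred and rng.random() < bias:
                codons.append(preferred[aa])
            else:
                others = [c for c in fam if c != preferred.get(aa)]
                codons.append(others[int(rng.integers(len(others)))])
        genes.append(CodingSequence(gene_id=f"{id_prefix}{g:04d}", sequence="".join(codons)))
    return genes


def write_fasta(records: Iterable[CodingSequence], path: str | Path, width: int = 70) -> None:
    """Write CDS records as wrapped plain-text FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
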
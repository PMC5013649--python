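"""Comparative statistics over per-genus dN/dS tables.

Implements the genome-profile and between-genus machinery: the four-bin
omega profile (omega < 0.5, 0.5 <= omega < 0.75, 0.75 <= omega < 1,
omega >= 1), the matched-orthologue fold contrast (a pair enters the fold
set when the larger omega is at least ``fold`` times the smaller; default
1.5, boundary inclusive), Mann-Whitney U comparisons of genome-wide omega
distributions, the 90th-percentile dS sensitivity filter, and box-plot-style
dS distribution summaries used to verify divergences sit below saturation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .dnds_ng86 import FLAG_OK, DnDsRecord

__all__ = [
    "BIN_EDGES",
    "BIN_LABELS",
    "GenusProfile",
    "ContrastSummary",
    "DsSummary",
    "ok_omegas",
    "bin_omegas",
    "fold_contrast",
    "mann_whitney_u",
    "ds_percentile_filter",
    "ds_distribution_summary",
]

BIN_EDGES = (0.5, 0.75, 1.0)
BIN_LABELS = ("omega<0.5", "0.5<=omega<0.75", "0.75<=omega<1", "omega>=1")


@dataclass(frozen=True)
class GenusProfile:
    """Counts and proportions of genes in the four omega magnitude bins."""

    genus: str
    pgc_mode: str  # "preformation" | "induction" | ""
    counts: tuple[int, int, int, int]
    total: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "total", sum(self.counts))

    @property
    def proportions(self) -> tuple[float, ...]:
        return tuple(c / self.total for c in self.counts)

    def to_dict(self) -> dict:
        return {
            "genus": self.genus,
            "pgc_mode": self.pgc_mode,
            "bins": dict(zip(BIN_LABELS, self.counts)),
            "proportions": dict(zip(BIN_LABELS, self.proportions)),
            "total": self.total,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass(frozen=True)
class ContrastSummary:
    """Matched-orthologue fold contrast between two genera."""

    genus_a: str
    genus_b: str
    mode_a: str
    mode_b: str
    n_matched: int
    n_fold_genes: int
    pct_higher_in_first: float
    pct_higher_in_second: float
    mwu_u: float
    mwu_p: float
    fold: float = 1.5

    def to_dict(self) -> dict:
        return {
            "genus_a": self.genus_a,
            "genus_b": self.genus_b,
            "mode_a": self.mode_a,
            "mode_b": self.mode_b,
            "fold": self.fold,
            "n_matched": self.n_matched,
            "n_fold_genes": self.n_fold_genes,
            "pct_higher_in_first": self.pct_higher_in_first,
            "pct_higher_in_second": self.pct_higher_in_second,
            "mwu_u": self.mwu_u,
            "mwu_p": self.mwu_p,
        }


@dataclass(frozen=True)
class DsSummary:
    q25: float
    median: float
    q75: float
    whisker_low: float
    whisker_high: float
    n_outliers: int
    maximum: float


def ok_omegas(records: Iterable[DnDsRecord]) -> list[float]:
    """Omega values of records with a defined ratio (flag ok)."""
    return [r.omega for r in records if r.flag == FLAG_OK and r.omega is not None]


def bin_omegas(
    records: Iterable[DnDsRecord], genus: str = "", pgc_mode: str = ""
) -> GenusProfile:
    """Place each defined omega into one of the four magnitude bins."""
    omegas = ok_omegas(records)
    if not omegas:
        raise ValueError("no records with defined omega to bin")
    counts = [0, 0, 0, 0]
    for w in omegas:
        if w < BIN_EDGES[0]:
            counts[0] += 1
        elif w < BIN_EDGES[1]:
            counts[1] += 1
        elif w < BIN_EDGES[2]:
            counts[2] += 1
        else:
            counts[3] += 1
    return GenusProfile(genus=genus, pgc_mode=pgc_mode, counts=tuple(counts))


def fold_contrast(
    omegas_a: Mapping[str, float],
    omegas_b: Mapping[str, float],
    ortho_map: Iterable[tuple[str, str]],
    fold: float = 1.5,
    genus_a: str = "A",
    genus_b: str = "B",
    mode_a: str = "",
    mode_b: str = "",
) -> ContrastSummary:
    """Fold contrast of matched orthologue omegas between two genera.

    A matched pair enters the fold set iff max(wa, wb) / min(wa, wb) >= fold,
    attributed to the genus with the larger omega. If exactly one omega is
    zero the pair is attributed to the nonzero genus; pairs with both omegas
    zero are excluded. Genes lacking a defined omega in either genus are
    skipped. The Mann-Whitney test compares all matched omegas.
    """
    matched_a: list[float] = []
    matched_b: list[float] = []
    higher_a = higher_b = 0
    for gene_a, gene_b in ortho_map:
        wa = omegas_a.get(gene_a)
        wb = omegas_b.get(gene_b)
        if wa is None or wb is None:
            continue
        matched_a.append(wa)
        matched_b.append(wb)
        if wa == 0.0 and wb == 0.0:
            continue
        if wa == 0.0:
            higher_b += 1
            continue
        if wb == 0.0:
            higher_a += 1
            continue
        hi, lo = (wa, wb) if wa >= wb else (wb, wa)
        # tiny relative slack keeps the printed boundary (e.g. exactly
        # 1.5-fold) inclusive despite binary rounding of the ratio
        if hi / lo >= fold * (1.0 - 1e-12):
            if wa > wb:
                higher_a += 1
            else:
                higher_b += 1
    if not matched_a:
        raise ValueError("no matched orthologues with defined omega in both genera")
    n_fold = higher_a + higher_b
    if n_fold:
        pct_a = 100.0 * higher_a / n_fold
        pct_b = 100.0 * higher_b / n_fold
    else:
        pct_a = pct_b = float("nan")
    u, p = mann_whitney_u(matched_a, matched_b)
    return ContrastSummary(
        genus_a=genus_a,
        genus_b=genus_b,
        mode_a=mode_a,
        mode_b=mode_b,
        n_matched=len(matched_a),
        n_fold_genes=n_fold,
        pct_higher_in_first=pct_a,
        pct_higher_in_second=pct_b,
        mwu_u=u,
        mwu_p=p,
        fold=fold,
    )


def mann_whitney_u(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses exact null enumeration when the smaller sample has at most 8
    observations and there are no ties across the pooled sample; otherwise
    the normal approximation with tie and continuity corrections. Returns
    (U of the first sample, two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("Mann-Whitney requires two non-empty samples")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both samples; p = 1", stacklevel=2)
        return float(a.size * b.size / 2.0), 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def ds_percentile_filter(records: Sequence[DnDsRecord], q: float = 0.90) -> list[DnDsRecord]:
    """Sensitivity filter: drop records with dS strictly above the q-quantile.

    The quantile is taken over records with a defined dS, using the
    linear-interpolation percentile convention. This is a re-analysis filter,
    never applied by default.
    """
    if not 0 < q <= 1:
        raise ValueError(f"quantile must lie in (0, 1], got {q}")
    ds_values = [r.dS for r in records if r.dS is not None]
    if not ds_values:
        return list(records)
    cut = float(np.percentile(ds_values, 100.0 * q))
    return [r for r in records if r.dS is None or r.dS <= cut]


def ds_distribution_summary(records: Sequence[DnDsRecord]) -> DsSummary:
    """Quartiles, 1.5 x IQR whiskers and outlier count of the dS distribution."""
    ds = np.asarray([r.dS for r in records if r.dS is not None], dtype=float)
    if ds.size == 0:
        raise ValueError("no defined dS values to summarize")
    q25, med, q75 = (float(np.percentile(ds, p)) for p in (25, 50, 75))
    iqr = q75 - q25
    lo_fence = q25 - 1.5 * iqr
    hi_fence = q75 + 1.5 * iqr
    inside = ds[(ds >= lo_fence) & (ds <= hi_fence)]
    n_outliers = int(ds.size - inside.size)
    return DsSummary(
        q25=q25,
        median=med,
        q75=q75,
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        n_outliers=n_outliers,
        maximum=float(ds.max()),
    )
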
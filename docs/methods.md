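# Methods

## Study design the pipeline implements

The question is whether taxa that specify their germ line by maternal germ
plasm (preformation) show faster protein evolution than taxa using
inductive signalling. Because PGC-specification mode rarely varies within a
genus, the unit of measurement is a **within-genus species pair**: per-gene
dN/dS between two congeneric genomes gives one independent, saturation-free
estimate of current evolutionary rates per genus. Genera with opposite
modes from the same phylum are then compared two ways: genome-wide ω
profiles and Mann–Whitney tests, and matched-orthologue fold contrasts in
which each intergeneric orthologue pair asks which genus holds the larger ω.

## Pipeline stages and conventions

**CDS quality control.** A CDS is retained iff its alphabet is strictly
A/C/G/T, its length is a multiple of three, and no stop codon occurs before
the final codon. A terminal stop is permitted and stripped so that database
CDS deposited with and without stops are comparable; length violations are
rejected because no reading frame can be established without annotation.
Sequences are canonicalized (uppercase, U→T) on input. Filtering is
idempotent and the QC report partitions the input exactly.

**Orthology.** Reciprocal best hits on translated CDS, scored by local
Smith–Waterman alignment under BLOSUM62 with affine gaps costing
11 + L for a gap of length L (BLAST's open-11/extend-1 convention; the
Biopython aligner's `open_gap_score` is set to −12 because it charges the
first gap position separately). An e-value cutoff would depend on database
size, so acceptance uses a raw score threshold (default 50; unrelated
random 20-mers score far below it, near-identical genes far above). Ties
for best hit exclude the gene — conservative, deterministic. When several
records share a gene-id prefix (text before the first `.`), only the
longest isoform is searched. A shared-4-mer prefilter (≥2 shared 4-mers)
prunes candidate pairs for speed; every surviving candidate is judged by
the full alignment score, and the prefilter can be disabled.

**Codon alignment.** The two proteins are aligned globally
(Needleman–Wunsch, BLOSUM62, gap cost 10 + L), the alignment is projected
onto the underlying codons, and every column with a gap in either sequence
is deleted (complete-deletion). Aligning proteins and back-translating is
what codon-level alignment tools do internally; for a pair of sequences a
progressive multiple aligner adds nothing. The dynamic program's first
optimal traceback is used, which is deterministic for a fixed scoring
scheme and aligner version.

**NG86 estimation.** Potential sites are exact rationals
(s(c) = synonymous single-base changes / 3 per position, nonsense changes
counted nonsynonymous so s + n = 3 exactly); S and N are averaged over the
two sequences, so N + S = 3L to within 1e-9 (asserted). Observed
differences average synonymous/nonsynonymous step counts over all k!
orderings of the k differing positions, discarding orderings through stop
codons; if every ordering is blocked (possible for some three-difference
pairs) the average falls back to all orderings with stop-touching steps
counted nonsynonymous, and the fallback is logged. Pathways are equally
weighted (classic NG86, no transition/transversion weighting). Jukes–
Cantor corrects each proportion; p ≥ 3/4 flags the gene `saturated`, dS = 0
flags it `ds_zero`; both are excluded from ω summaries but kept in audit
tables.

**Contrast statistics.** ω bins are half-open with the printed boundaries
(ω<0.5, 0.5≤ω<0.75, 0.75≤ω<1, ω≥1). A matched orthologue pair enters the
fold set iff max(ωa,ωb)/min(ωa,ωb) ≥ fold (default 1.5, boundary inclusive
— a 1e-12 relative epsilon keeps e.g. 0.3/0.2 inclusive despite binary
rounding); if exactly one ω is zero the pair is attributed to the nonzero
genus, and both-zero pairs are excluded (our convention; orientation is by
the larger ω). Mann–Whitney U is two-sided, exact when the smaller sample
has ≤8 observations and the pooled sample is tie-free, otherwise the
normal approximation with tie and continuity corrections (the two branches
agree to ~0.01 in p at n=8). The dS sensitivity filter removes genes with
dS strictly above the 90th percentile (linear-interpolation convention,
which matters at the margin by one gene) of each genus's dS distribution;
it is a re-analysis, never the default. Box summaries use 1.5×IQR
whiskers.

**Expression profiling.** A gene × 10-stage RPKM table (the fly scheme
0–6 h embryo … adult male/female by default; any ordered 10-stage scheme is
accepted). "Expressed" means RPKM > 0 (no positive floor — the smallest
defensible convention), "high" means RPKM > 50. The five categories are
none (0), low (>0–10], moderate (>10–50], high (>50–1000], extremely high
(>1000). Per-stage comparisons use 2×2 chi-squared without Yates
correction (fixed for reproducibility; immaterial at the set sizes
involved), degenerate tables return p = 1 with a warning; cross-stage
agreement uses Spearman with average ranks. Gene sets from a non-reference
genus are transferred into the reference gene space through the orthologue
map, with unmapped genes counted and reported.

**Optimal codons and Fop.** The optimal codon of an amino acid is the
codon with the largest positive gain in within-family relative usage in
highly versus lowly expressed genes, accepted when the 2×2 chi-squared
(candidate vs rest of family, high vs low class) has p < 0.05; ties or
absent families yield no call, and at most one optimal codon per amino
acid is allowed. Fop counts only codons whose amino acid has an optimal
codon, so Met, Trp and stops never contribute; distribution summaries
report moments, a 20-bin histogram and a Shapiro–Wilk normality p-value
(first 5000 genes), with constant distributions flagged degenerate.

## Synthetic data generator

The generator emulates the study conditions: closely related genome pairs
with dS below saturation, ω concentrated below 0.5, known orthologue
truth, and dropout + log-normal stage expression.

* Ancestors are i.i.d. sense codons (uniform by default) behind a forced
  ATG start.
* Evolution is proposal–acceptance: uniform single-base proposals;
  synonymous accepted always, nonsynonymous with probability ω,
  stop-creating never. Each lineage runs until its accepted synonymous
  events per ancestral synonymous site reach target_ds/2 (divergence split
  symmetrically). This controls the acceptance asymmetry exactly and is
  adequate below saturation; it does not model rate-matrix dynamics,
  codon-usage mutational bias, or indels (the alignment stage is exercised
  by constructed gap fixtures instead).
* Defaults: per-gene ω log-normal with median 0.15, σ = 0.8 (≈93% of mass
  below 0.5, matching the shape of genome-wide profiles); target dS
  log-normal median 0.25, σ = 0.3, clipped to [0.05, 0.7]; gene length
  log-normal median 400 codons, σ = 0.4, floor 50.
* Expression: each gene × stage is zero with probability 1 − 0.9, else
  log-normal with median 12 RPKM, σ = 1.5 — giving ≈90% expressed and
  ≈15% above 50 RPKM per stage, in the range of real developmental
  transcriptomes.
* Contrast simulations plant the asymmetry in *every* gene (base ω times a
  3-fold factor in genus A for exactly round(n·frac) genes, in genus B for
  the rest) so that the fold set is essentially the whole orthologue set
  and the planted percentage is estimable to within sampling error; the
  null configuration shares identical true ω per gene across genera with
  independent sequence evolution.

**Known estimator bias worth stating.** NG86 counts stop-ward changes as
nonsynonymous *sites*, but neither the generator nor real coding evolution
realizes them; realized dN is therefore deflated by the blocked mutational
flux, ≈5–8% at ω = 1 and proportionally less at low ω. Validation
experiments recover planted ω = {0.1, 0.5, 1.0} class means and dS = 0.3
within 10%, which brackets this bias; claims of exact unbiasedness at high
ω should not be made.

## Problem sizes used in the validation experiments

Chosen as the package's standard experiment sizes: parameter recovery runs
10 replicate genomes of 500 genes (default length distribution, dS 0.3,
planted ω classes cycled); the planted 70/30 contrast uses 500 genes at
default lengths; the null contrast uses 5 replicates of 1500 genes at 200
codons — shorter genes raise per-gene estimation noise so the noise-entrant
fold set is large enough for a ±3-point check of the 50/50 split, while the
broad between-gene ω dispersion keeps the genome-wide Mann–Whitney p
concentrated near 1 (asserted via the replicate median, since a single
null p-value is uniform-ish by construction).

## Limitations

* Pairwise pipeline only: no many-to-many orthology, synteny, or
  frameshift-aware alignment; no ML codon models (GY94/PAML-style) or
  site-specific ω.
* Standard nuclear genetic code only; other codes are rejected, not
  translated.
* Passing tests on the generator show estimator correctness under its
  assumptions (uniform mutation, no indels, no usage bias), not robustness
  to misalignment, annotation error, or compositional heterogeneity in
  real genomes — the dS-percentile sensitivity re-run exists precisely to
  probe such artefacts in real data.
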
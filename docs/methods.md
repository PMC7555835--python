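# Methods

This note documents the models, conventions and numerical choices behind
`amoascan`, and what the synthetic benchmarks do and do not demonstrate.

## Primer model and coordinates

A degenerate oligonucleotide over the 15 IUPAC symbols is treated as the
equimolar pool of its fully specified expansions; degeneracy is the product of
per-position allowed-base-set sizes, and expansions are enumerated in
lexicographic order so variant indices are stable.  Reverse primers are stored
in their own 5'→3' orientation (matching the reverse complement of the
template's plus strand).

Coordinates are 1-based inclusive on the comammox *amoA* reference numbering.
The published binding intervals for these primers are internally inconsistent
with the oligo lengths (a 21-position interval for a 20-mer, a 17-position
interval for a 16-mer), so the packaged table re-anchors them: **forward
primers keep the published start** (end = start + length − 1) and **reverse
primers keep the published end** (start = end − length + 1).  This preserves
the two anchors that define product geometry, so the forward-start /
reverse-end spans reproduce the published product sizes (162→359 = 198 bp;
244→659 = 416 bp, printed as "approximately 415").  Published positions are
treated as approximate anchors only; templates without reference coordinates
are always located by scanning, never by fixed offsets.

## In-silico PCR

Mismatch counting is IUPAC-aware Hamming distance: a primer position
mismatches a template position iff their allowed-base sets are disjoint.
Because per-position choices of a degenerate oligo are independent, the
minimum mismatch count over all expansions equals the count of disjoint
positions — the scanner exploits this instead of enumerating expansions, and
the test suite checks it against a full-enumeration brute-force oracle.
Indels are not modelled (primer-length indels are not a feature of this
marker), and mismatches are unweighted by position by default.  Mixtures are
matched as "best over all member oligos and all expansions" with no
inter-oligo weighting (the wet-lab pools are equimolar); ties break to the
lowest mismatch count, then packaged oligo order, then lexicographic variant
order, making every scan deterministic.

Both template strands are scanned: strand `+` means the oligo matches the
window as read, strand `-` means it matches the window's reverse complement.
Amplicon extraction pairs each forward site with the nearest compatible
downstream reverse site (optionally length-bounded) and returns products in
forward→reverse orientation regardless of template orientation.

Cross-primer coverage locates the best-matching window for a probe pool by
scanning the whole amplicon rather than using a fixed reference offset —
reference-anchored amplicons are a special case of the scan, and diverged
templates need not preserve exact spacing.  Coverage is bucketed by minimum
mismatch (0 / 1 / ≥2) and reported both abundance-weighted (per read, the
headline figure) and per unique sequence, since published coverage figures do
not always state their weighting basis.  An optional 3'-terminal window mode
(default width 3) reports mismatches in the primer's last bases separately,
as 3' mismatches dominate PCR failure.

The amplicon-vs-metagenome comparison reports the plain per-clade ratio of
relative abundances; a clade with zero metagenome RA is flagged rather than
divided.  (Published fold-change summaries of such comparisons are not always
recoverable from the printed RAs; the plain ratio is the reproducible
quantity.)

## Short-read screening

Reads are translated in all six frames (standard code, partial codons
dropped, stops as `*`, N-codons as X) and aligned locally (Smith–Waterman)
against the clade-labelled protein panel under BLOSUM62 with BLAST-convention
affine gaps: a gap of length k costs 11 + k (open_gap_score −12,
extend_gap_score −1 in `Bio.Align` terms).  The best hit over frames ×
references is chosen by score, then identity, then lexicographic reference
id.  A read is annotated only if the best hit reaches ≥80 % amino-acid
identity over ≥25 aligned amino acids; identity's denominator includes gap
columns (the conservative choice, stated explicitly because published filters
rarely define it).  The E-value pre-filter used by BLASTX-based pipelines is
replaced by a raw-score floor (default 50; an exact 25-aa match scores ≥100
since the smallest BLOSUM62 diagonal entry is 4) — E-values need a
database-size calibration that is no part of the identity/length filter
itself.  Clade RA is the annotated-read proportion, reported at 2 decimals
with full precision retained.

## OTU clustering

Clustering is greedy and centroid-based (UCLUST-style): sequences are
processed in decreasing abundance (ties by id) and join the first existing
centroid at ≥ threshold identity (default 95 %), else found a new OTU.  With
abundance-sorted input the founder is the highest-abundance member of its
OTU.  Pairwise identity comes from a global alignment with free end gaps
(match 2 / mismatch −3 / gap open 5 / extend 2, blastn-like); terminal
overhang columns are excluded from the denominator so nested fragments of one
gene score 100 % — necessary when regions of different lengths are compared —
while internal gap columns count.  Identity is symmetrised by canonicalising
the argument order before alignment, since optimal-alignment tie-breaking
could otherwise differ between orderings.

The region comparison excises the 198-bp (Ntsp), 415-bp (comaA+comaB pooled)
and combined-span regions from full-length genes by in-silico PCR, restricts
to the genes covered by every region (so all regions cluster an identical
membership), and reports per-region OTU counts.

## Alpha diversity

Rarefaction is a multivariate-hypergeometric draw (uniform subsampling
without replacement) under an explicit seed; the repeated-draw mean is tested
against the closed-form hypergeometric expectation.  Richness-at-threshold
counts OTUs whose RA meets each of {0, 0.01, 0.1, 0.5, 1} % (configurable);
at 0 % this is the positive-count OTU number.  Shannon is −Σ pᵢ log pᵢ in
natural log by default with an explicit base switch, because QIIME
generations disagree on the base.  Faith's PD is the rooted form — the sum of
branch lengths of edges whose subtree contains an observed tip — computed by
one post-order pass and cross-checked against an independent union-of-paths
oracle; whether a published PD used the rooted or unrooted variant is often
unstated, and the rooted choice is flagged here deliberately.  Tree inference
is out of scope: PD consumes a user-supplied Newick tree, and the synthetic
generator emits a matching truth tree so PD is testable without inference.

## Synthetic communities

The generator emulates the structure of a two-clade comammox *amoA* system at
desk scale.  Per clade it builds a random 702-bp ancestral open reading frame
(ATG start, no internal stop in frame +1) and plants, at the reference
coordinates, a clade-diagnostic comaA or comaB forward and reverse site plus
the shared Ntsp sites (site variants are drawn only from expansions that keep
the frame stop-free; any stop codon straddling a site boundary is repaired in
the flanks).  Descendants carry third-codon-position substitutions
(synonymous-biased) outside the primer sites at the stated divergence.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| gene length | 702 bp | accommodates the 162–659 primer geometry with flanks; codon-multiple |
| `n_per_clade` | 4 | smallest panel giving within-clade structure per clade |
| `within_clade_divergence` | 0.02 | keeps within-clade identity above the 95 % OTU threshold, between-clade far below |
| abundance model | lognormal, μ = 0, σ = 1.5 | typical amplicon rank-abundance skew; no published abundance model exists for this system |
| `total_abundance` | 1000 | resolves spectrum fractions of 0.1 % exactly |
| mismatch spectrum | {0: 0.7, 1: 0.3} at the coma forward site | mirrors the observed 0-vs-1-mismatch coverage splits |
| read length | 150 bp | short-read platform fragment length; single-end fragments stand in for paired ends, which add no information for per-read screening |

Clade splits and mismatch-spectrum fractions are honoured **exactly by
abundance mass**: the integer total abundance is allocated to clades, then to
spectrum groups within clades (each fraction × mass must be integral, else
the call fails loudly), and lognormal weights shape the within-group curve
via largest-remainder rounding with a floor of one read per template.  Exact
allocation is what makes coverage fractions like 70.0 / 100.0 deterministic
rather than approximate.  Planted mismatches are placed at positions where
the substituted base is outside the union of allowed bases of every pool
member, so the pool-minimum mismatch count rises by exactly one per planted
position; the generator audits each template with the scanner before
recording it.

Amplicon simulation gates each template on both primer sites binding within
`max_mismatch` (dropout below the gate) and attenuates abundance by
`per_mismatch_efficiency` per mismatch.  Metagenome simulation draws
fragments proportional to abundance × template length with uniform start and
random strand; background reads are uniform random nucleotides — real
off-target genomes are not bundled, and at the 80 %/25-aa screening gate the
distinction is immaterial (random 50-aa translations essentially never reach
it, which the suite verifies).

**What passing the synthetic benchmarks shows** — that the scanner, gates,
clustering and diversity arithmetic are correct and self-consistent, and that
parameter recovery works at the planted effect sizes.  **What it does not
show** — performance on real amplicon data with sequencing error, chimeras,
length variation, codon-usage structure, or genuinely novel clades: the
generator has no error model, its background is random rather than
homologous, and its within-clade divergence is uniform along the gene (except
where a test plants otherwise).

## Problem sizes used in the shipped benchmarks

The test-suite benchmarks run at desk scale, chosen as the smallest sizes at
which the statistical checks are meaningful: 100 random templates ≤1 kb for
the scanner/oracle equivalence, 200 random pairs ≤60 aa for the aligner
oracle, 2000 shotgun reads for clade-split recovery (binomial 95 % CI around
the planted 0.885/0.115 split), panels of 2–4 genes per clade, and
1000 rarefaction replicates for the hypergeometric expectation check.

## Known limitations

* Hamming-only primer matching; no thermodynamics (melting temperature,
  dimers) and no quantitative amplification-bias model beyond the mismatch
  gate and per-mismatch efficiency.
* No chimera or sequencing-error simulation; ASV-style denoising is out of
  scope.
* Greedy clustering approximates, not reimplements, UCLUST (no k-mer
  acceleration; deterministic abundance ordering).
* Faith's PD is rooted-only; beta diversity and group statistics (ANOVA) are
  not provided.
* The screening score floor is a fixed raw-score proxy, not a calibrated
  E-value.
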
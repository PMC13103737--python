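# Methods

This note documents the models, algorithms and design choices behind
`canisv`: what each stage computes, the parameters that matter, what the
synthetic cohort does and does not emulate, and the numerical decisions
taken where the design was genuinely open.

## Coordinates and formats

All internal coordinates are 0-based, half-open. VCF `POS` (1-based) and
RepeatMasker `.out` begin/end (1-based inclusive) are converted at the
parse/write boundary in both directions, so writing and re-reading is an
involution. Sequences are uppercased on read; masking state is carried
as annotations, never as case. Unphased `a/b` genotypes are accepted and
treated as ordered (haplotype 1 = a) with a logged warning — the
intended inputs are haplotype-resolved assemblies, which are inherently
phased. Multiallelic VCF records are kept unsplit; each record is
treated independently (no bubble deduplication is attempted).

## Symmetric DUST masking

`sdust_mask(seq, window=64, threshold=20)` scores an interval by its
triplet composition: with c_t the count of each of the 64 overlapping
3-mers in the interval and l the number of triplets, the score is
`sum(c_t·(c_t−1)/2) / (l−1)`. An interval of 4..window bases is
reported when its score exceeds `threshold/10` = 2.0 and it is
*perfect*: no proper subinterval scores strictly higher. The mask is the
union of all perfect intervals. This makes masking symmetric — an
interval's masked status depends only on its own content, never on
flanking context — which matters because the same allele sequence must
mask identically wherever it occurs.

Numerical notes: scores are exact rationals (numerator ≤ ~1900,
denominator ≤ 61), and with float64 division two distinct scores in
this range can never collide, so the production kernel can compare
floats while the test oracle compares `Fraction`s; the two provably
agree. The divisor `l−1` (not `l` or `l−2`) follows the canonical DUST
normalization; W=64/T=20 are the canonical published defaults. Non-ACGT
characters break triplets: the scan runs per ACGT segment and no masked
interval spans an `N`. The kernel is an O(n·W) dynamic scan (numba);
the test suite checks exact equivalence against a brute-force
enumeration oracle on >1,000 randomized sequences.

## Exact tandem repeats

`find_exact_tandem_repeats` reports, per period p, maximal runs where
`seq[i] == seq[i−p]` throughout, keeping runs with ≥ 2 whole copies and
span ≥ 4 bp (`min_span`; partial trailing copies count toward span but
not toward copies). Only primitive motifs are reported — a homopolymer
is a unit-1 run, never also a unit-2 run — and the reported `unit` is
phase-aligned (`seq[start:start+p]`) so every run reconstructs its span
exactly, while `canonical_unit` gives the lexicographically smallest
rotation for phase-independent matching. The unit-length cap is 6 for
genome STR scans and uncapped for allele annotation. Minimum span and
copy count are exposed as configuration; the chosen defaults (4 bp, 2
copies) are the weakest thresholds consistent with "a motif occurring
two or more times", which makes the genome-wide STR scan deliberately
permissive (about a quarter of a uniform-random genome carries some
exact repeat at these thresholds — see Enrichment below).

## Annotation merging

`merge_repeat_annotations` joins fragments that share a RepeatMasker
element ID when only Simple_repeat/Low_complexity annotations (or
nothing) lie between them, spanning the gap and keeping the element's
name and class; a (CT)n/(AG)n/(TC)n/(GA)n annotation between two SINEC
fragments or inside a SINEC interval is absorbed into the SINEC — these
microsatellite calls are the element's own internal CT run, not
independent repeats. A different element between fragments blocks the
merge (so a nested insertion keeps host fragments separate). Conflicting
classes under one ID resolve to the majority-length class with a
warning. The operation is idempotent. Merged consensus coordinates take
the fragment minimum/maximum, which is what the LINE-1 3'-intactness
filter consumes.

## Library annotator and alignment backend

Where RepeatMasker output is not supplied (the synthetic path), alleles
are annotated by `LibraryAnnotator`: exact 16-mers shared with either
strand of any consensus are clustered by diagonal (±32) and proximity
(≤250 bp), extended exactly at both ends, and refined by edit-distance
(edlib) alignment; hits with identity ≥ 0.8 survive, resolved
best-score-first with a 50% overlap cap. K-mers occurring more than 16
times across the library are ignored as anchors (poly-A, CT runs).
This is a deliberately lightweight annotator — no substitution
matrices, no cross-locus defragmentation — sufficient for the ~1–5%
divergent copies the simulator plants, not a RepeatMasker replacement.

The transduction analysis needs "align a short query to the genome".
`GenomeAligner` seeds with three exact 20 bp probes (both orientations),
refines candidates with infix edit-distance alignment, and scores
matches − mismatches − gap-opens. This scoring approximates the
published tool's default; only the threshold (25) is taken from the
method description.

## Extraction and classification

Extraction applies the three locus filters in order (missing genotype;
not variable among analyzed samples; max allele-size difference < 50
bp), attributing each removed site to the first failing filter so the
counts partition the input exactly. "Variable" is evaluated on the
analyzed haplotypes only: a site where all ten haplotypes share one
non-reference allele is invariant and removed. The VCF anchor base is
kept for size arithmetic (the empty site is exactly 1 bp) and stripped
before composition analysis. Reference-only alleles are dropped from
the locus allele list. Longest-allele ties break to the lower allele
index.

Classification is the five-step decision procedure in
`sv_classification` (70% coverage criterion; 5% for Partial). Two open
points were resolved as follows: when a repeat type and low-complexity
both reach 70%, the repeat type wins (the low-complexity clause applies
to loci not already classified); the STR/VNTR 70% thresholds use the
full allele length as denominator, consistent with every other clause.
When two repeat types both reach 70% via nesting, the larger covered
length wins, ties in the frequency order SINEC > LINE/L1 > LTR/ERV >
OtherRepeat.

Because the internal annotator does not emit Simple_repeat annotations
the way RepeatMasker does, the pipeline's annotation stage adds
Simple_repeat intervals for exact tandem runs with unit ≤ 13 bp and
span ≥ 20 bp before merging. Without this, a clean VNTR allele with a
10–12 bp unit would have nothing to satisfy the Low-Complexity gate
(DUST only marginally masks such units), which would misroute the
STR/VNTR relabeling; the emission mirrors what RepeatMasker's own
simple-repeat step provides in the real path.

## MEI genetics

A locus is a clean SINEC (or LINE-1) locus when every observed allele is
the 1 bp empty site or classifies to the element type; every distinct
allele is classified, not just the longest. The empty site is the
ancestral state. Heterogeneity is the count of distinct derived allele
sequences. Sharing is tabulated per individual (presence on either
haplotype); loci with no ancestral allele observed count as present in
all samples. The report includes singleton counts, all presence
patterns, per-sample het/hom derived counts (het + 2·hom equals derived
haplotypes — asserted in tests), and conditional sharing given presence
in a focal sample. Autosome restriction is configuration-driven (the
synthetic genome is all-autosomal).

## LINE-1 analyses

ORF scanning runs only when the allele's LINE-1 annotation span is ≥ 4
kb. ORFs of ≥ 300 codons on the element strand are translated and
matched to the consensus ORF1p/ORF2p by infix edit distance; a call is
intact when distance ≤ 10% of the consensus length (which also bounds
missing consensus coverage at 10%). A protein longer than its matched
consensus reports the excess in codons — this is how the nested
frame-preserving SINEC-in-ORF2 allele surfaces (~60–75 codons at the
simulated insert size). An upstream in-frame ATG can also lengthen a
protein by a few codons; the nested detection threshold in the tests
(≥ 60) sits well above that.

Transduction extraction takes the allele segment strictly 3' (element
orientation) of the longest LINE-1 annotation and trims the terminal
poly(A) run (≥ 5 A's, one non-A tolerated only when followed by at
least two more A's); segments < 25 bp are discarded. Filters follow the
stated order — unplaced target, match score < 25, fewer than 25
unmasked query positions (annotator ∪ SDUST), within 7 kb of the locus
(nearest edge), more than 5 retained alignments ("excess", a documented
choice), genomic span > query + 100 bp — with per-filter counts and the
first failing reason recorded; the chain is idempotent. Source
resolution labels a PASS call REFERENCE_SOURCE when its best alignment
lies within 1 kb of a reference LINE-1 3' end, SEGREGATING_SOURCE when
within 1 kb of a dimorphic LINE-1 locus, else PARENTLESS; calls sharing
a source form families.

## Rates and enrichment

Divergence time uses T = D/(2·μ·L): both lineages accumulate mutations,
so pairwise differences ≈ 2μTL. D counts biallelic SNP sites (all
alleles 1 bp) outside the duplication mask; L is the genome minus the
mask. The element rate per comparison is r = N/T with N the clean
element loci derived in one haplotype and ancestral in the outgroup
haplotype; the estimate is the mean over ten comparisons (nine
haplotypes vs the outgroup, plus outgroup vs one dog haplotype to avoid
double-counting outgroup-lineage insertions). For LINE-1, loci whose
annotation ends more than 100 bp short of the consensus 3' end are
removed first; these are dominated by intra-LINE-1 deletion variants,
which did not arise as new insertions, and the removal report carries
the 2×2 split by reference-LINE-1 membership with Fisher's exact test.

Sampling behavior at desk scale: with a 2 Mb genome and μ = 4.5×10⁻⁹,
a 10,000-generation comparison yields only D ≈ 170–210 SNPs, and most
of that divergence accrues on the two deep shared branches, so the
Poisson noise in D (and in the shared-branch insertion counts) is
common to all ten comparisons and does not average out. The recovered
rate therefore carries a sampling standard deviation of roughly 10% of
its value; the fixed-seed acceptance test sits well inside the 20%
recovery band, but individual seeds can approach or exceed it. This is
a property of the problem size, not of the estimator; at realistic
genome sizes (D in the tens of thousands) the same estimator is
sub-percent.

STR enrichment re-places every STR interval uniformly at random per
permutation — chromosome drawn proportional to length, start uniform,
overlaps permitted (genome-wide placement, the shuffle tool's default
dialect; a per-chromosome flag is not provided at this scale). Fold is
observed/mean(permuted) over 100 permutations, deterministic under the
seed. Because the STR scan is permissive (min span 4 bp), background
exact-repeat coverage is high and the SINEC fold on the synthetic
genome is modest (~1.4–1.5): the planted SINEC CT runs and A tails
enrich, but the effect is diluted relative to a scan with a stricter
span threshold. The qualitative ordering (SINEC most enriched) is the
tested property.

## Duplication summaries and identity

Pair tables pass a base filter (≥ 1 kb, ≤ 10% divergence; mitochondrial
pairs removable) and a strict subset (≥ 10 kb, ≤ 5%), then classify
INTRA vs INTER; INTRA pairs are TANDEM when the gap between the nearer
ends of the paralogs (0 if overlapping) is under 200 kb; INTER pairs are
CENTROMERIC when both paralog start positions fall in the first 5 Mb
(start-position test; exposed as configuration). Percentages round
half-up to one decimal (the centromeric share also at integer
precision). Within the pipeline the thresholds are scaled to the
megabase synthetic genome (strict ≥ 2 kb, tandem < 100 kb, window 100
kb) — configuration values, not new defaults for the functions.

Gap-excluded identity is matches/(matches+mismatches); gap-compressed
divides additionally by the number of maximal indel runs (each run of
I/D operations is one difference). `M`-only CIGARs are resolved with
the edit-distance tag.

## The synthetic cohort

The generator is the package's study design, not a test fixture. A
fixed labeled genealogy relates five diploid samples — wolf-like
outgroup (GW-like) splitting 10,000 generations from four dog-like
samples, within-dog splits at 3,000/2,000 generations, haplotype
coalescences at 800 generations except the NGSD-like sample at 50
(emulating captive inbreeding; its insertions are overwhelmingly
homozygous, and the sharing report shows the expected heterozygote
deficit). Every haplotype is 10,000 generations from the root.

Defaults (2 chromosomes × 1 Mb; rates per lineage per generation):
SINEC insertions at 0.02 (~600 events), LINE-1 at 0.002 (~60), SNPs at
μ = 4.5×10⁻⁹, LINE-1 full-length probability 0.5, TSD length uniform
5–20 bp (duplicated on both flanks by construction), post-insertion
heterogeneity probability 0.25 per descendant branch (substitutions,
CT-run and A-tail drift), plus fixed-count accessory classes (STR,
VNTR, LTR, satellite, mixed, partial, unclassified insertions; plain
deletions; intra-LINE-1 deletions carved out of reference-fixed LINE-1
copies). The reference carries 200 fixed SINECs, 8 fixed LINE-1s (two
of them transduction sources), one satellite array and 20 physically
copied duplication pairs. Twenty-four transductions carry 90 bp
downstream tags from three sources, one of which is itself a planted
dimorphic LINE-1 absent from the outgroup (the resolved-"parentless"
scenario); two additional transductions carry satellite-derived tags
and are planted to fail the repetitive-alignment filters. One nested
allele inserts a reverse-complement SINEC (with its own TSD,
frame-padded and stop-scrubbed in the host frame) into ORF2 of an
otherwise intact LINE-1 on an internal branch, with the nesting on a
descendant branch, giving the three-allele empty/LINE-1/LINE-1+SINEC
configuration.

What the simulation does not emulate: recombination, demography or
coalescent variance (the genealogy is fixed), assembly or genotyping
error, reference bias, 5'-inversion structures, endonuclease site
preference, and RepeatMasker's full annotation behavior (the truth
`.out` files carry one clean annotation per element copy). Passing
end-to-end tests therefore demonstrates correctness of the pipeline's
logic under clean calls at megabase scale, not robustness to real-data
artifacts.

Determinism: a single seeded generator drives the whole simulation in a
fixed order, and identical parameters + seed produce byte-identical
emitted files and pipeline reports (timings are excluded from the
persisted report). Problem sizes throughout the test suite — the
default cohort for acceptance-grade checks, reduced cohorts for
unit-level checks — were chosen so the full suite completes in a few
minutes on one CPU.
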
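# canisv

Structural-variant extraction, repeat-composition classification and
mobile-element analysis for canine pangenome VCFs.

Canine genomes are unusual among mammals: the dominant source of
structural variation is retrotransposition of the carnivore-specific
SINEC family (a ~200 bp tRNA-Lys-derived SINE with an internal (CT)N
microsatellite and an A-rich tail) and of LINE-1 (~6 kb, encoding ORF1p
and ORF2p). `canisv` is for researchers who have a multi-sample pangenome
VCF projected from haplotype-resolved assemblies (e.g. Minigraph-Cactus
output) plus RepeatMasker annotations and a segmental-duplication pair
table, and want the standard battery of analyses over that variation:

* **SV locus extraction** — insertion/deletion loci from the VCF under
  three filters: no missing genotype among analyzed haplotypes, variable
  among the analyzed samples, and max allele-size difference ≥ 50 bp.
* **Ten-way classification** of each locus's longest allele (SINEC,
  LINE/L1, LTR/ERV, OtherRepeat, LowComplexity, STR, VNTR, Mixed,
  Partial, Unclassified) from merged repeat annotations, symmetric-DUST
  masking and exact tandem-repeat runs, with a 70% coverage criterion.
* **Dimorphic MEI genetics** — "clean" SINEC/LINE-1 loci (every allele is
  the element or the 1 bp empty site), allelic heterogeneity, and
  ancestral/derived allele sharing and zygosity across samples.
* **LINE-1 biology** — ORF1p/ORF2p intactness, 3' transduction
  extraction and filtering, and resolution of "parentless" transductions
  to segregating (non-reference) source elements.
* **Insertion rates** — SNP-calibrated: pairwise divergence time
  T = D/(2·μ·L) with μ = 4.5×10⁻⁹/bp/generation, element rate r = N/T,
  averaged over ten comparisons against an outgroup (wolf-like)
  haplotype.
* **STR enrichment** (shuffle permutations) and **segmental-duplication
  pair summaries** (intra/inter, tandem/dispersed, centromeric-end
  concentration) with gap-excluded/gap-compressed alignment identity.

Because the full-genome inputs are large and external, the package ships
a first-class synthetic cohort generator: a megabase-scale reference, a
repeat library with designed ORFs and CT runs, and five diploid samples
on a fixed genealogy with a known insertion/SNP history — emitted as
FASTA + VCF + RepeatMasker-format truth so the entire pipeline is
testable end to end, including nested (Matryoshka) alleles and
transduction source tracing.

## Worked example

Run the full pipeline on a simulated cohort:

```bash
canisv run-all --outdir run1 --seed 1
```

This simulates the cohort, writes `run1/sim/` (reference, haplotypes,
VCF, truth annotations), then extracts, classifies and analyzes it,
printing:

```
{
 "n_loci": 826,
 "category_counts": {
  "SINEC": {"biallelic": 391, "triallelic": 133, "multiallelic": 112},
  "LINE/L1": {"biallelic": 55, "triallelic": 22, "multiallelic": 16},
  ...
 }
}
```

826 loci survive the three filters (the other 280 VCF records are SNPs,
removed by the 50 bp size criterion). 636 loci classify as SINEC and 93
as LINE/L1 — the two expected peaks of the canine SV spectrum — and 245
of the 636 clean SINEC loci carry more than one distinct insertion
allele, the allelic heterogeneity that post-insertion CT-run and A-tail
drift creates. `run1/report.json` holds the full machine-readable
report; highlights from seed 1:

* `insertion_rates.SINEC.mean_rate` = 0.0200 per generation ("1 in 50
  births" at this simulation's rate; the estimator recovers the
  generating rate of 0.02 to 0.1%).
* `transductions`: 24/24 planted 3' transductions PASS all filters and
  resolve to their true source — two reference LINE-1s and one
  segregating dimorphic LINE-1 (three families of 8).
* `elongated_orf2` flags the planted nested SINEC-in-ORF2 allele with a
  64-codon in-frame insertion.
* `line1_3prime_filter` removes exactly the planted intra-LINE-1
  deletion variants (annotation ends > 100 bp from the consensus 3'
  end), all of which sit inside reference LINE-1 copies.

Individual stages are exposed as subcommands over the same files:
`canisv extract`, `classify`, `mei-share`, `transduce`, `rates`,
`str-enrich`, `dup-summary`, `identity`, `mask`, `etrf`, `simulate`,
`init-config`. For example:

```bash
canisv rates --vcf run1/sim/cohort.vcf --seed 1 --mask run1/sim/dup_pairs.tsv
canisv dup-summary --pairs run1/sim/dup_pairs.tsv
```

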
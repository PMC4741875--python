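# cpgvar

Classification and enrichment analysis of **CpG-site-related SNPs (cgSNPs)**
— genetic variants that create or abolish a CpG dinucleotide, the substrate
of DNA methylation.

## The scientific problem

A single-base substitution can change whether a CpG dinucleotide overlaps
the variant position: a C→T transition on the C of a CpG abolishes the
site, and the reverse transition creates one. Because CpG methylation
regulates transcription, such variants are natural candidates for
regulatory and disease associations. `cpgvar` provides, as a tested and
reusable pipeline:

1. **Sequence-rule classification.** From the trinucleotide context
   (5′ base, the two alleles, 3′ base), each biallelic substitution is
   classed as CpG-polymorphic, CpG-shift, or neutral; with an ancestral
   allele, CpG-polymorphic variants are oriented as **cg-gain** (derived
   allele creates the CpG) or **cg-loss** (ancestral CpG abolished).
   Substitutions where *both* alleles carry a CpG at adjacent dinucleotides
   (e.g. C[C/G]G) merely shift the site and are excluded. Exhaustive
   enumeration over all 192 ordered substitutions-in-context yields 22 gain
   and 22 loss scenarios plus 2 shift scenarios; the full table is emitted
   by `enumerate_scenarios()`.
2. **Genomic-context annotation.** CpG island / shore (±2 kb) / open sea
   and genebody / promoter (2 kb upstream of the strand-aware 5′ end) /
   intergenic labels from BED tracks.
3. **LD tagging and pruning.** Pairwise r² (D²/(p_A p_a p_B p_b)) from a
   PLINK-style pair table; a proxy SNP is a **cgSNPt** if it is a cgSNP or
   tags one at r² > 0.8; greedy genome-order LD pruning at r² = 0.8 / 0.5 /
   0.3 defines the proxy panel.
4. **Enrichment testing.** Whether cgSNPts are over-represented among
   outcome-positive SNPs (eQTLs, trait-associated loci), via the logistic
   model

   ln(P/(1−P)) = β₀ + β_cgSNPt·X_cgSNPt + β_MAF·X_MAF + β_tags·X_tags

   (OR = exp(β_cgSNPt) with 95% Wald CI), and via a matched-resampling
   test: null 500-SNP sets drawn 300 times that exactly reproduce the index
   set's composition over (MAF bin × tag-count bin) strata, giving an
   empirical p = fraction of draws whose cgSNPt count ≥ the observed count.
   Significance bins on reported p and per-trait-category fits are included.
5. **Methylation differences at CpG-destroying mutations.** For paired
   normal/tumor methylation tracks and somatic cg-loss mutations (cgMuts),
   the normal-minus-tumor difference at the lost CpG cytosines versus
   intact CpGs in distance annuli (±10 bp … ±2 kb), summarised as
   percentiles per bin.
6. **A synthetic-data generator** that emits every input format with known
   ground truth (planted region bias, realizable haplotype-pool r², planted
   logistic coefficients and category contrasts, planted methylation
   drops), so the whole pipeline is testable without external downloads.

## Worked example

Generate a synthetic study (20,000 SNPs) and run the full pipeline:

```bash
cpgvar synth --seed 42 --n-snps 20000 --out demo/data
cpgvar run --snps demo/data/snps.tsv --islands demo/data/islands.bed \
    --ld demo/data/ld.tsv --outcomes demo/data/outcomes.tsv \
    --top 300 --draws 300 --seed 42 --out demo/results
```

prints

```
prune_r2_0.8 eqtl: OR=1.431 [1.222, 1.676], simulation p < 0.003333
prune_r2_0.8 trait: OR=1.345 [1.150, 1.573], simulation p 0.01667
```

The generator planted a cgSNPt log-odds of ln(1.5) for eQTL outcomes: the
fitted OR of 1.431 with CI [1.222, 1.676] recovers it, and none of the 300
matched null draws reached the observed cgSNPt count in the top-300 index
set (empirical p below the 1/300 resolution). The trait outcome mixes
planted category ORs of 1.5 (cancer) and 1.1 (others), so its pooled OR
falls between them; per-category fits are in
`demo/results/results.json`.

The methylation analysis on the paired synthetic tracks:

```bash
cpgvar methdiff --normal demo/data/normal.tsv --tumor demo/data/tumor.tsv \
    --muts demo/data/mutations.tsv --out demo/methdiff.tsv
```

```
53 cg-loss mutations; site-bin median difference 0.219 over 53 sites -> demo/methdiff.tsv
```

The planted drop at mutated CpGs was 0.20; the annulus bins in
`demo/methdiff.tsv` have medians near zero, showing the drop is
site-specific rather than a global tumor/normal difference.

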
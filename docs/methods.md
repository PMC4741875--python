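# Methods

This note documents the models and procedures implemented in `cpgvar`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Variant classification

A CpG dinucleotide can overlap a variant base in exactly two ways: the
variant is the C (followed by G) or the G (preceded by C). Classification
therefore needs only the trinucleotide context — the immediately adjacent
5′ and 3′ bases plus the two alleles. Longer flanking sequences are
accepted but only the adjacent bases are consulted.

* `cpg_present(left, center, right)` is true iff `left-center` = CG or
  `center-right` = CG.
* A substitution is **CpG-polymorphic** iff exactly one allele yields a
  CpG, a **CpG shift** iff both do (necessarily at different adjacent
  dinucleotides, as in C[C/G]G where CCG and CGG each contain one CpG),
  and neutral otherwise. Shift variants leave local CpG density unchanged
  — methylation at immediately adjacent CpGs is highly correlated — and
  are excluded from cgSNPs. Implementing the shift rule as "both alleles
  yield CpG presence" avoids positional bookkeeping and reproduces the
  CCG worked case exactly.
* Orientation takes the ancestral trinucleotide as the initial state:
  **cg-loss** if the ancestral allele carries the CpG, **cg-gain**
  otherwise; with no ancestral information the variant remains an
  unoriented cgSNP (it still counts as a cgSNP downstream).

Classification is strand-invariant (CpG is its own reverse complement), a
property the tests verify on all 192 ordered context cases against an
independent oracle that literally builds both trinucleotide strings and
searches them for "CG".

**Scenario count.** Exhaustive enumeration over the 4×4×3×4 = 192 ordered
(5′ base, ancestral, derived, 3′ base) cases gives 22 gain scenarios, 22
loss scenarios (mirror images under ancestral/derived swap, hence always
equinumerous) and 2 shift scenarios. Published figures for this count vary
with the enumeration convention (ordered vs unordered allele pairs, strand
collapsing); `enumerate_scenarios()` therefore emits the full per-scenario
table alongside the counts so any external figure can be compared row by
row rather than trusted as a bare number.

Ambiguous context bases (N or other IUPAC codes) classify as non-CpG with
a machine-readable warning instead of raising, so genome-scale runs do not
abort on unclassifiable sites. Indels and multiallelic records are
rejected at parse time with a counted skip. Coordinates are 0-based
half-open internally; SNP/methylation/mutation TSVs carry 1-based
positions, BED is 0-based, both converted only at the I/O boundary.

## Genomic-context annotation

CpG islands are merged before use. Shores are the ±2 kb flanks of merged
islands minus any island overlap; open sea is everything farther than 2 kb
from an island. Precedence is island > shore > open sea, so shore zones of
nearby islands merge and never shadow island labels; the three labels
partition each chromosome. Shores and promoters truncate at position 0 and
(when chromosome lengths are known) at chromosome ends.

Gene context: genebody if inside any gene interval; else promoter if
within 2 kb upstream of a gene's strand-aware 5′ end (left of the start
for + genes, right of the end for − genes); else intergenic. Genebody wins
over a neighbouring gene's promoter, since a position inside any gene is a
genebody position. Promoters are defined from the gene interval's 5′ end;
transcript-level isoform starts are out of scope.

Interval lookups use binary search over merged sorted arrays; a per-base
distance-scan oracle on randomized toy genomes is the correctness check in
the test suite.

## LD, tagging, and the proxy panel

r² between two loci is D²/(p_A p_a p_B p_b) computed from haplotype
counts; monomorphic loci raise an explicit undefined-LD error. Absent
pairs mean r² = 0 (sparse symmetric index); no LD crosses chromosomes.

Thresholding is **strictly greater than** r² = 0.8 everywhere — tag
counts, cgSNPt status, and pruning conflicts — one convention fixed and
documented. `n_tagged` counts only *other* SNPs, not the proxy itself.
Tag counts and cgSNPt status are computed on the full panel; pruning then
selects the proxy set. Pruning is a greedy scan in genome order (chrom,
pos, id) retaining a SNP iff its r² to every already-retained SNP is at or
below the threshold; the result is deterministic, contains no internal
pair above the threshold, and is maximal (every dropped SNP conflicts with
a retained one). PLINK's windowed pruning heuristic is deliberately not
reproduced: determinism and testability over replication of an unspecified
algorithm. Thresholds 0.8 / 0.5 / 0.3 are supported as a sensitivity
analysis.

## Enrichment testing

**Logistic model.** For each proxy SNP, the outcome y (eQTL membership or
trait association) is regressed on the binary cgSNPt indicator with MAF
and tag count as confounder covariates (both correlate with cgSNPt status
and with ascertainment into outcome catalogs):

ln(P/(1−P)) = β₀ + β_cgSNPt·X_cgSNPt + β_MAF·X_MAF + β_tags·X_tags

The fit is maximum likelihood (statsmodels `Logit`); the reported effect
is OR = exp(β_cgSNPt) with a 95% Wald interval exp(β ± 1.96·SE) — matching
the usual OR/CI reporting style; profile likelihood is not required at
these sample sizes. Single-state outcomes or indicators raise explicit
collinearity errors; separation and non-convergence raise a separation
error rather than returning garbage coefficients. The test suite verifies
the MLE against an independent generic-optimizer maximization of the
hand-written log-likelihood to 4 decimals.

**Matched-resampling test.** Proxies are stratified on MAF bins of width
0.05 over [0, 0.5] (upper edge inclusive) × tag-count bins {0}, {1–2},
{3–5}, {6–10}, {>10}; the edges are configurable, the defaults give ~50
strata with adequate occupancy at panel sizes of 10⁴–10⁵. Each of the
(default 300) null draws reproduces the index set's per-stratum
composition exactly, sampling without replacement from the non-index SNPs
of each stratum (index SNPs are excluded from the pool so the null is a
true background). Draws are vectorised per stratum by ranking uniform
random keys. The empirical p is the proportion of draws whose cgSNPt count
is ≥ the observed count — ties count toward p, which is conservative —
reported as "< 1/n_draws" when no draw reaches it; a (+1)/(n+1) estimator
is available by flag.

**Index feasibility.** Matching requires every stratum's pool to be at
least as large as its index count. Index selection (`feasible_index`)
walks the signal-ranked candidates and caps each stratum's index count at
half the stratum size, passing over SNPs in strata too small to match;
a genuinely infeasible stratum still raises an error naming it. This makes
top-signal index sets always matchable without silently merging strata.

**Significance bins and categories.** Trait SNPs are binned on −log₁₀ of
their reported p with default edges 5, 6, 7, 8, 11, 14, 17, 20 (eight
bins, the last open-ended); the first edge doubles as the catalog filter
(p < 10⁻⁵). Only the extreme anchors of such binnings are ever printed in
catalogs, so the edges are configurable. Per-bin and per-category fits use
the bin's/category's SNPs as positives against all never-associated
proxies as shared negatives — a design choice documented here because
per-bin subsets with disjoint negatives are equally defensible.

## Methylation differences at cgMuts

Somatic mutations are classified with the reference allele as the initial
state; CG_LOSS calls are cgMuts, and the abolished CpG's cytosine is the
mutated base itself (C>N on the C) or one base left (G>N on the G). The
per-site statistic is methylation in normal minus tumor at that cytosine;
tumor methylation at a lost CpG is taken as reported in the tumor track
(residual signal from heterozygosity and tumor purity), not forced to
zero. Sites absent from either track are dropped with a count.

Intact CpG sites present in both tracks are assigned to half-open distance
annuli (0,10], (10,50], (50,100], (100,500], (500,1000], (1000,2000] bp by
their minimum distance to any cgMut cytosine; the mutated sites themselves
form a separate SITE bin, and sites beyond 2 kb are excluded. Nested ±
radii are rendered as disjoint annuli so each site lands in exactly one
bin. Summaries are the 10th/25th/50th/75th/90th percentiles
(linear-interpolation convention, `numpy.percentile` default) plus the
fraction of sites with normal > tumor. A site-specific drop with flat
annuli attributes the change to the mutation rather than to global
tumor/normal differences.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated. All generators are pure functions of a `SynthConfig` whose seed
is mandatory; each derives a fixed independent random stream, so outputs
are byte-reproducible.

* **SNP panel** (default 50,000 SNPs on two 5-Mb toy chromosomes, ~1% of
  the genome in 1-kb islands): flanking bases are drawn with region-
  dependent G+C content (0.60 island / 0.50 shore / 0.40 open sea), and
  with probability 0.45 / 0.25 / 0.10 respectively the ancestral context
  carries a pre-existing CpG overlapping the variant — so cg-loss
  dominates inside islands, reproducing the direction (not the magnitude)
  of the real genome's pattern, where hypomethylated island CpGs persist
  and methylated CpGs decay. Derived alleles are transitions with
  probability 2/3. MAF is 0.5·Beta(0.8, 1.4) with a mild upward shape
  shift for cgSNPs so MAF genuinely confounds enrichment; the ancestral
  state is masked at rate 0.02.
* **LD blocks**: SNPs are grouped in genome order into 10-SNP blocks; 120
  haplotypes are drawn from 3 founder haplotypes with 2% per-site flip
  noise (monomorphic sites re-draw their founder pattern, preserving block
  structure). Emitted r² values are computed from the realized pool with
  the package's own haplotype-count formula, so they are realizable and
  self-consistent by construction; this yields a mean of ~1 tagged SNP per
  proxy and a cgSNPt fraction of ~0.45 against a cgSNP fraction of ~0.26.
  Cross-block r² is zero.
* **Outcomes** are Bernoulli draws from the logistic model with planted
  coefficients (defaults β₀ = −3, β_cgSNPt = ln 1.5, β_MAF = 0.5,
  β_tags = 0.02); trait outcomes override β_cgSNPt per category (cancer
  OR 1.5 vs 1.1 elsewhere, the contrast the category analysis is designed
  to detect). Reported p-values for positives are spread uniformly over
  the significance bins **by design, not from a test statistic** — they
  exist only to exercise bin logic and index ranking.
* **Methylation pair** (default 20,000 CpGs on a 2-Mb toy chromosome):
  normal levels ~ Beta(6, 2) (somatic-tissue-like hypermethylation,
  mean 0.75); tumor adds symmetric Normal(0, 0.02) measurement noise,
  except at 53 randomly chosen CpGs where a C→T mutation abolishes the
  site and the tumor level drops by Normal(0.20, 0.07), clipped to [0, 1].
  Twenty decoy substitutions touching no CpG exercise mutation filtering.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: coalescent population structure and
recombination-driven LD decay, ascertainment of genotyping arrays,
correlated methylation along the genome, read-level bisulfite noise,
tumor subclonality, and any dependence of outcome status on genomic
position. The pipeline's statistical behaviour (parameter recovery,
calibration, power) is validated under these idealized conditions; its
correctness on real inputs rests on the format contracts and the
deterministic sequence rules, which do not depend on the generator.

## Problem sizes and numerical choices

Replicate studies run at the scales the analyses are designed around:
parameter recovery and type-I calibration on 50,000-SNP panels (100 and
200 replicates), matched-test calibration and power on 20,000-SNP panels
with 500-SNP index sets and 300 draws (200 and 50 replicates), and the
end-to-end determinism check on a 20,000-SNP run — sizes chosen so the
whole validation completes in minutes on one CPU while keeping the test
dimensions (500 × 300) at full scale. Logistic fits use Newton iterations
with a 100-iteration cap; percentiles use linear interpolation; empirical
p-values count ties as exceedances; LD r² values are emitted at 6
decimals; all randomness flows from explicit seeds (numpy `default_rng`),
and derived seeds stay below 2³¹.

## Known limitations

* The classifier assumes correctly oriented, single-base flanks; records
  whose flanks disagree with the stated strand will classify consistently
  but on the wrong strand's context (strand-invariance makes this moot for
  CpG status, but not for the emitted context columns).
* Greedy genome-order pruning is one deterministic choice among several
  defensible proxy definitions; retained sets differ from PLINK's windowed
  output.
* Wald CIs can be anticonservative at very low positive counts (per-bin
  fits with few positives); the separation error guards the worst cases
  but per-bin results with n_positive below a few dozen deserve caution.
* The matched test conditions on the realized stratum scheme; strata
  coarser or finer than the defaults change the null and therefore the
  empirical p.
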
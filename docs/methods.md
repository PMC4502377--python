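# Methods

## Scope and data model

`palmpop` analyses diploid, biallelic single-nucleotide variants from a
multi-sample VCF. The in-memory unit is a samples × loci `GenotypeMatrix`
holding, per cell, the alternative-allele dosage (0/1/2 or missing), the
read depth, and the SAMtools-convention PL triple (phred-scaled genotype
likelihoods ordered hom-ref, het, hom-alt, minimum rescaled to 0). Indels
and multi-allelic records are dropped at import and counted. The pipeline
deliberately starts at the VCF: read alignment and variant calling are
upstream tools' territory, as are tree search and figure rendering
downstream.

## Filtering

Filters run in a fixed order — PL mask, site coverage, alternative-allele
support, missingness cap — and each stage logs inputs/removals in a
`FilterReport`, so the composition is auditable and idempotent.

* **PL mask** (`pl_min`, default 35 phred): a call is kept only when the
  *second-smallest* PL value is at least the threshold. The second-smallest
  PL is the margin by which the best genotype beats the runner-up, so this
  is a direct confidence cut on the call. Cells without PL data are set
  missing and counted.
* **Site coverage** (default ≥10 reads in ≥80% of samples): the required
  sample count is `ceil(0.8·N)`; a site at exactly 80% passes. The rule is
  evaluated on the samples actually in the matrix passed in — when a
  sample subset is analysed, coverage is judged on that subset.
* **Alternative-allele support** (default ≥4 observations): counted over
  called genotypes (het = 1, hom-alt = 2). Raw read counts are no longer
  available after the VCF, so called genotypes are the closest available
  evidence.
* **Missingness cap**: per-analysis maximum number of missing genotypes at
  a locus (tree/structure/differentiation sets conventionally use
  different caps, e.g. 10/8/15; the cap is a parameter).

**Duplicate concordance.** For technical-replicate pairs, concordance is
measured over co-called loci. Under the model that an error is equally
likely in either member of the pair, observed discordance *d* implies a
per-sample accuracy of 1 − *d*/2, reported as `predicted_accuracy`.

## Admixture model

The model is the standard admixture model with independent allele
frequencies: individual *i* draws each of its two allele copies at locus
*l* from ancestral population *k* with probability Q[i,k], and population
*k* carries the alternative allele at frequency P[k,l]. Inference is Gibbs
sampling over the latent origin indicators:

* P[k,l] | Z ~ Beta(1 + alt copies assigned to k, 1 + ref copies) —
  uniform prior;
* Q[i,·] | Z ~ Dirichlet(α + per-population copy counts), symmetric
  α = 1;
* indicators are resampled per allele copy with probability ∝
  Q[i,k]·P or Q[i,k]·(1−P).

Point estimates are posterior means over post-burn-in sweeps (matching the
proportions replicate-alignment tools consume, rather than a MAP state).
Missing dosages contribute no copies anywhere. The log-likelihood of the
data under the current (Q, P) is recorded every sweep; the per-run scalar
used for model choice is its post-burn-in mean. The uniform-prior,
independent-frequency variant was chosen as the simplest published model
adequate for two well-separated populations; correlated-frequency priors,
LOCPRIOR and linkage models are out of scope.

Implementation notes: copies are assigned by stick-breaking binomials
(exact for ≤2 copies per cell and fully vectorised); since rows of Q sum
to 1, the reference-allele weight matrix is computed as Q − Q·P and its
row-sum as 1 − Σ; P is clipped to [1e-12, 1−1e-12] after each Beta draw
for numerical safety. Chain defaults are 5,000 burn-in / 25,000 retained
sweeps; recovery tests and the acceptance script use a reduced chain
(1,000 / 5,000), which mixes well at the simulated divergences.

**Replicate alignment.** Replicate runs are label-switched. Each run's Q
columns are permuted to maximise similarity with the first run, searching
all K! permutations (exact; practical for K ≤ 8, vs. heuristic search in
CLUMPP). Similarity is G(Qa, Qb) = 1 − ‖Qa − Qb‖_F / √(2N); the
concordance summary H′ is the mean pairwise G after alignment (1.0 and
flagged for a single run), and the consensus Q is the cell-wise mean.

**Model choice (Evanno ΔK).** With L(K) the replicate mean log-likelihood
and s(K) the replicate standard deviation (ddof = 1), L′(K) = L(K) −
L(K−1), L″(K) = |L′(K+1) − L′(K)| and ΔK = L″(K)/s(K), defined for
interior K with at least two replicates; s = 0 yields +inf with a warning.
`best_k` is the argmax of ΔK.

**Assignment.** A sample is assigned to population *k* when Q[i,k] ≥ the
purity threshold (default 0.75, inclusive — "at least 75%"); otherwise it
is labelled `Mixed`. The threshold must exceed 0.5 so at most one
population qualifies.

## PCA

Genotypes are coded hom-ref = 1, het = 2, hom-alt = 3. Missing calls are
imputed with the column mean of observed codes (keeping all samples
without external imputation); all-missing columns are dropped with a
warning. The coded matrix is column-centred but *not* scaled to unit
variance (`pca.scale = false` is the recorded choice), then decomposed by
SVD; the variance fraction of a component is its squared singular value
over the total.

## Differentiation

All two-group statistics take an explicit grouping of assignment labels.
The default sides `Mixed` samples with the Western group (geographically
intermediate cultivars cluster with North Africa); the strict West-vs-East
comparison is available by overriding the grouping.

* **Allele counts**: heterozygotes contribute one copy to each allele,
  homozygotes two to one; missing genotypes contribute nothing.
* **Private alleles**: a position is *nonreference-private* when the
  alternative allele occurs (count ≥ 1) in exactly one group and not at
  all in the other; *reference-private* symmetric for the reference
  allele. The headline count is nonreference-private — when the reference
  genome derives from one of the two populations (here an Eastern
  cultivar), the nonreference category is the interpretable one, and the
  two sides' counts sum to the headline total. No call-rate or frequency
  filters are applied.
* **Weir–Cockerham Fst**: per-locus variance components a (among
  populations), b (among individuals within populations), c (within
  individuals) from genotype counts — sample sizes, allele frequencies
  and observed heterozygosity per group. Loci where a group has no called
  genotype, the average sample size is ≤1, or a+b+c = 0 (monomorphic) are
  excluded and counted. Two summaries are reported: *mean* Fst (average of
  per-locus a/(a+b+c); negative per-locus estimates retained, preserving
  the estimator's unbiasedness) and *weighted* Fst (ratio of sums
  Σa/Σ(a+b+c)), the pair conventionally reported together.
* **Fisher scan**: two-sided Fisher exact test on the 2×2 table of
  (ref, alt) allele counts × group, per locus. Allele (not genotype)
  counts are used, consistent with counting both alleles of a
  heterozygote. A locus is tested when both groups have ≥1 called allele;
  Bonferroni uses m = number of *tested* loci (untestable loci carry no
  p-value); significance is adjusted p < 0.01.
* **Fixed differences**: both groups monomorphic, for different alleles,
  among called alleles, each group with ≥1 called allele. A fixed locus is
  necessarily nonreference-private on one side.
* **Artificial chromosomes**: contigs are concatenated in genetic-map
  order per linkage group; a SNP's artificial position is its contig's
  cumulative offset plus its position. Contigs absent from the map route
  to an `unmapped` bucket. Per-LG enrichment is
  (flagged/total on LG)/(flagged/total genome-wide); window densities use
  half-open windows on artificial coordinates. `exclude_lg` drops one
  LG's loci to support re-running structure without a suspect linkage
  group (e.g. a sex-determination region).

## Polarization

A SNP is *region-segregating* when every called Western genotype is
homozygous for one allele and every called Eastern genotype homozygous for
the other (any heterozygote disqualifies; each group needs ≥1 call —
missing calls are tolerated, which is a stated choice, not the only
possible reading). Against a precomputed outgroup-allele table the SNP is
classed: `east_deviated` when the Western allele equals the outgroup
allele (the East changed), `west_deviated` symmetric, `both_deviated` when
the outgroup carries a third base, `unaligned` when no outgroup allele is
available. The four classes partition the segregating set per scaffold;
per-scaffold percentages round half-away-from-zero to integers. Producing
the outgroup table (whole-genome alignment) is out of scope.

## Alignment export

Concatenated-SNP sequences, one character per locus: in `homozygous` mode
dosage 0 → ref base, 2 → alt base, heterozygous and missing → N (topology
from homozygous calls only); `iupac` mode encodes heterozygotes as
two-base ambiguity codes. Both FASTA and relaxed PHYLIP are written and
round-trip losslessly. Pairwise p-distances ignore positions where either
sequence is N/ambiguous; pairs with no comparable sites are flagged NaN.
Seeded column bootstrap is provided for feeding external tree tools; tree
inference itself is out of scope.

## Synthetic data generator

The generator emulates the survey design: two source populations (defaults
11 West + 52 East), admixed individuals (7, expected Western ancestry 0.5,
drawing a source population per locus), outgroup trees (4, split between
two species), and duplicated samples (4).

* **Divergence**: Balding–Nichols — ancestral frequency p ~ U(0.05, 0.95)
  per locus, population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F). F is
  the expected Weir–Cockerham Fst between the populations, giving the
  estimators a known recovery target. F = 0 and F = 1 are rejected
  (degenerate Beta). The default F (0.267) and duplicate error rate
  (0.006 per call, i.e. 99.4% predicted accuracy under the equal-error
  model) are the survey's stated conditions. The outgroup draws from the
  same ancestral frequency at a larger divergence (default 0.6) — a
  stand-in for species-level divergence, not calibrated to any measured
  value.
* **Genotype layer**: true genotypes are Hardy–Weinberg draws from the
  population frequency; depth ~ Poisson(mean 20); alternative reads ~
  Binomial(depth, [0.01, 0.5, 0.99][genotype]); PLs are the phred-scaled
  binomial read-split likelihoods normalised to min 0; the emitted call is
  the PL argmin, so realistic call errors and PL-filterable low-confidence
  cells arise naturally. Zero-depth cells and a `missing_rate` fraction of
  cells are missing.
* **Private loci**: a `private_rate` fraction of loci is forced to
  alternative-allele frequency 1 in one population and 0 in the other —
  guaranteed nonreference-private fixed differences for downstream tests.
* **Duplicates**: a duplicated sample and its original are two
  independently perturbed copies of one source call vector (per-call flip
  probability `genotype_error`), so expected pair discordance is
  ≈ 2e(1−e).
* **Map and ancestral table**: contigs (default 40) with lengths uniform
  in [50 kb, 500 kb] are assigned round-robin to linkage groups (default
  18); loci fall uniformly on contigs (only the ordering matters
  downstream). The ancestral allele is drawn from the outgroup frequency;
  an `unaligned_rate` fraction (default 0.13) has no ancestral call.

What the generator does **not** model: linkage disequilibrium between loci
(sites are independent), restriction-site biases of GBS library
construction, read-level artefacts (FASTQ), batch effects, or related
individuals beyond the duplicate pairs. Passing recovery tests therefore
demonstrates estimator correctness under the assumed independent-loci,
two-population model — not robustness to LD, kinship or calling artefacts
in real data.

## Determinism and numerics

Every random stage derives from one seed: the generator uses a single
`numpy` Generator; replicate run r at K uses
`SeedSequence(master, spawn_key=(K, r))`. Identical configurations produce
byte-identical VCFs and pipeline summaries (timings are excluded from the
canonical summary payload). Ties in PL argmin calls resolve to the lowest
genotype index. Percentages round half-away-from-zero, with one decimal
below 10% and integers otherwise, matching the reporting convention the
package targets.

## Problem sizes

Recovery checks run at sizes chosen so the whole suite stays comfortable
on a laptop-class single core while keeping sampling error well inside the
asserted tolerances: Fst recovery at 50+50 diploids × 2,000 loci
(binomial error on weighted Fst ≈ 0.005, asserted at ±0.02); the
admixture battery at 40+40 (+6 admixed) × 500 loci with the reduced chain,
K ∈ 1..4 × 3 replicates; the Fisher cross-check enumerates every 2×2
table with total ≤ 24 (20,475 tables).

## Known limitations

* The Gibbs sampler assumes unlinked loci; dense data in strong LD will
  overstate confidence in Q.
* Exhaustive permutation alignment is exact but factorial in K; above
  K = 8 a heuristic matcher would be needed.
* Evanno ΔK cannot evaluate the boundary K values and is undefined when
  replicate variance is zero (reported as +inf with a warning).
* Mean-of-ratios Fst is sensitive to low-information loci and typically
  sits below the ratio-of-sums summary; both are reported and neither is
  truncated at zero.
* The Fisher scan treats the two alleles of a heterozygote as independent
  observations, as the counting convention dictates; allele counts are
  not corrected for within-individual dependence.
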
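# Methods

This note documents the models and procedures implemented in
`methcode`, the assumptions behind them, the defaults that matter, and
what the synthetic-data tests do and do not demonstrate about real
data.

## Reference-free consensus construction

RRBS reads from one locus share a common backbone once every C is
collapsed to T, because bisulfite conversion makes the C/T distinction
reflect methylation state rather than genotype. `build_consensus`
therefore groups reads by their full-length C→T-collapsed key, merges
keys within Hamming distance 1 (single pass in descending stack size;
the larger stack absorbs the smaller; implemented with masked-key
hashing so the merge is linear in reads × read length), and drops
stacks below `min_stack_depth = 5` members to suppress singleton noise.

Cytosines of the consensus are recovered by two rules, in order of
authority: a position is called C if unconverted-library members show C
at frequency ≥ `tau_unconv = 0.5` (the unconverted library reveals the
true genomic base), or if converted members show C at frequency ≥
`tau_meth = 0.1` (a cytosine that survives conversion in ≥10% of reads
is genuinely methylatable rather than a sequencing error). A genomic
cytosine that is unmethylated and not covered by the unconverted
library is unrecoverable and remains T; this is an inherent limitation
of the reference-free setting, and the k-mer feature extractors
restrict to fragments covered by the unconverted library for exactly
this reason. Ties in the non-cytosine majority vote break by the fixed
base order A<C<G<T, which makes consensus construction independent of
read input order.

Fragments are single-stranded references: reads from the opposite
strand form their own stacks, and CpG calls are not strand-merged,
because strand pairing is unknown without a reference. Alignment is
substitution-only; at 50 bp read length indel handling buys little and
costs determinism.

## Read simulation

The generator emulates the structure of a multi-species RRBS study.
Its defaults are the study conditions, not tuning knobs: read length
50 bp, conversion rate 0.99 (typical RRBS conversion efficiency),
over-conversion 0.005, spike-in fraction 0.001 (0.1%, matching the
standard spike-in concentration), and Poisson read counts at
`mean_coverage` per fragment end. Reads are single-end and directional,
taken from both fragment ends and both strands. Methylation is planted
at fragment level — all CpGs of a fragment share one base probability,
optionally jittered per CpG — which mirrors the fragment-level
discretization the genomic-code analysis targets. CpG-context
cytosines follow the planted probability; all other cytosines use a
background non-CpG level (default 0.01, elevated for brain samples
when the brain contrast is being simulated). Spike-in controls are two
fixed CpG-rich 200 bp sequences (generated once from fixed seeds, one
treated as fully methylated and one as fully unmethylated).

What the simulation does *not* model: realistic quality scores, PCR
duplicates, paired-end reads, indels, CNVs, or sequence-dependent
conversion bias. Passing tests therefore demonstrate correctness of
the algorithms under the stated noise model, not robustness to every
artefact of real libraries.

## Erosion (PDR)

A read with at least 4 valid CpG measurements is concordant if all its
CpGs share one state and discordant otherwise; the first and last CpG
on each read are discarded as unreliable before counting. The PDR of a
CpG is the discordant fraction of valid reads covering it; sample PDR
is the unweighted mean over CpGs with ≥1 valid read (read-depth
weighting is a documented alternative we do not use), species PDR the
mean over samples. Under the null of independent per-CpG methylation
at level m with n CpGs per read, E[PDR](m) = 1 − mⁿ − (1−m)ⁿ: zero at
m ∈ {0, 1}, symmetric about 0.5, maximal there (0.875 for n = 4). The
curve is evaluated on a 0.001-step grid; n = 4 is the default, an
empirical read-CpG-count mixture can be substituted.

## Aggregation conventions

Methylation aggregates unweighted up the hierarchy cytosine → fragment
→ sample → species. Fragment bins use fragments with ≥ 10 total reads;
boundaries are low [0, 0.2), mid [0.2, 0.8], high (0.8, 1] — the
boundary values belong to the middle bin since the published bin
definitions are strict (">80%", "<20%").

## Coverage QC

Per sample, "average coverage" is the mean read count over fragments
with nonzero coverage (zero-coverage fragments excluded; including
them would let covered-fragment count differences masquerade as
coverage differences). A fragment is reliably covered above 0.5× and
highly covered above 4× that average, both strict. Highly covered in
>80% of samples ⇒ repeat (a collapsed genomic repeat); in <20% with at
least one such sample ⇒ amplified; reliably covered in >80% of one
individual's samples and <20% of every other individual's ⇒ private
(requires ≥4 samples and ≥2 individuals). When rules collide the
precedence is repeat > amplified > private, strongest evidence first.
CpG overlap between samples is |A∩B| / mean(|A|, |B|) (min and Jaccard
denominators available); species drop below 50% mean overlap. The QC
acceptance simulations use a base coverage of 50 reads per fragment —
a typical RRBS fragment depth — with planted 5× repeat and amplified
fragments.

## Sequence features and islands

k-mer spectra pool overlapping windows across fragments (positions
weigh equally, so longer fragments contribute more; per-fragment
averaging is available in principle but pooling is the default).
Windows containing non-ACGT characters are skipped; counting is on the
given strand only. The observed/expected CpG ratio is
(#CpG × N) / (#C × #G). CpG-island calls slide a 50 bp window at step
1 and require GC ≥ 0.50 and obs/exp ≥ 0.6 (Gardiner-Garden) or ≥ 0.55
and ≥ 0.65 (Takai-Jones), both thresholds inclusive ("at least").
Species clustering uses Euclidean distance between spectra and
complete-linkage agglomeration.

## Global models and phylogenetic correction

Species-level models are OLS with R² adjusted by the Wherry formula
1 − (1 − R²)(n − 1)/(n − p − 1) (the n − p − 1 denominator variant)
and Gaussian maximum-likelihood AIC that counts the intercept, the p
slopes, and the residual variance: AIC = 2(p + 2) − 2 log L.

Phylogenetic correction is generalized least squares with Brownian
residual covariance Σᵢⱼ = shared root-to-MRCA path length from the
species tree (unit branch lengths substituted when a taxonomy carries
none). On a star phylogeny Σ ∝ I and the estimator reduces exactly to
OLS — this equivalence and 95% CI coverage of a planted slope under
Brownian noise on a 64-leaf tree are both asserted in the tests. A GEE
formulation is a published alternative; the GLS form satisfies the
same contract (coefficients and tests corrected for tree-induced
covariance) with simpler, fully specified numerics.

Stepwise selection is bidirectional greedy AIC search from the
intercept-only model, with per-feature stability = percentage of
bootstrap resamples (species drawn with replacement, default 100)
whose final model contains the feature. A caveat any user of stepwise
AIC should know: greedy selection over ~64 candidates takes the best
of ~64 χ²₁-distributed likelihood gains at each step (≈ 2·ln 64 ≈ 8,
against an AIC penalty of 2), so pure-noise features are routinely
admitted and null models are far from intercept-only — R's `step()`
behaves identically. Stability scores are therefore meaningful as a
*ranking* (a planted feature reaches ~100% and tops the list) rather
than as calibrated selection probabilities.

## Genomic-code classifiers

Fragments become training instances under the strict rule (low:
methylation <20% in all samples; high: >80% in all samples; mean
coverage strictly >10 reads; a lenient any-sample rule for "low" is
available). Balanced train/test sets of 2000 sequences each (1000 per
class; both classes shrink together when the limiting class is small)
feed a linear SVM with hinge loss on overlapping k-mer frequency
vectors — the primal form of a spectrum kernel. Frequencies are not
further standardized so weights read directly as per-k-mer effects
(logo-ready). The grid C ∈ {0.01, 0.1, 1, 10} × k ∈ 1..10 is scored
by mean cross-validated AUC (AUC rather than accuracy: threshold-free
and insensitive to residual class imbalance); ties prefer smaller k
then smaller C. AUC is the Mann-Whitney rank statistic with midrank
ties, which guarantees AUC(w) + AUC(−w) = 1 exactly.

Cross-species transfer applies a trained model to another species'
test set, recomputing features at the model's k. A species is
"inverted" when the mean off-diagonal AUC of its test column falls
strictly below 0.45 (the column mean — what happens when *others'*
codes are applied to this species; the row mean is a documented
alternative). The acceptance simulation (8 species, one sign-flipped,
100 replicates at 120 fragments per class and fixed k = 3) flags the
flipped species uniquely in ≥95 replicates. Grid-search behaviour is
checked at 300 sequences per class with 5 folds across 10 seeds; the
held-out recovery check uses the full 2000-sequence sets.

## Tissue differential methylation

Variance decomposition: per species with ≥2 individuals, ≥2 tissues,
and a shared tissue, r²_tissue is the mean squared Pearson correlation
of fragment-mean profiles over same-tissue/different-individual sample
pairs, r²_individual over same-individual/different-tissue pairs;
pairs require ≥100 shared fragments. The group-level test is a paired
two-sided Wilcoxon across species.

Per-CpG tests are moderated two-group t-tests: pooled per-CpG
variances are shrunk toward a prior fitted across CpGs by the
log-variance moment method (an F-distribution prior; the posterior
variance is (d₀s₀² + ds²)/(d₀ + d) and the statistic has d₀ + d
degrees of freedom). BH correction runs within species.

Per-fragment combination defaults to a correlation-corrected Fisher
statistic: X = −2Σ ln pᵢ is referred to a scaled χ² whose first two
moments absorb the empirical inter-CpG correlations within the
fragment (Brown's polynomial approximation for the covariance of
−2 ln p terms). Plain Fisher is available and, as the tests show,
anticonservative when CpGs within a fragment are correlated — which
they are by construction.

DMR selection is a combined-rank rule per direction: ascending ranks
by p-value, by −|relative difference| (denominator: mean of the two
tissue means), and by −|absolute difference|; the combined rank is the
maximum of the three (sum available); fragments need combined p < 0.05
and mean coverage ≥ 2 reads in both tissues; the top 500 per direction
are selected, ties broken by fragment id. Swapping tissue labels flips
directions and leaves combined ranks invariant.

Motif enrichment scans log₂-odds PWM scores (0-order background
estimated from all input sequences, both strands). The hit threshold
is the smallest score whose exact null exceedance probability is ≤
1e-4, computed by dynamic programming over a discretized score
histogram (granularity 0.01; half a bin per column is subtracted from
the returned threshold so continuous window scores never miss by
rounding). Sequence-level hits feed a one-sided Fisher exact test of
each direction against the others, BH-corrected across motifs ×
directions. TF activity calls combine significant enrichments with a
binding-preference table (unmethylated-preferring TF enriched among
fragments hypomethylated in a tissue ⇒ active there;
methylated-preferring TF enriched among hypermethylated ⇒ active
there) and an expression filter (normalized expression > 1 in at least
one of the two tissues).

## Gene-centric analysis

Cross-mapping is ungapped seed-and-extend (11-mer seeds, both strands)
with a mismatch-rate bound of 0.2; ties between equally good distinct
locations make a fragment ambiguous and it stays unmapped rather than
being placed arbitrarily. The genome with the highest mapped fraction
becomes the species' reference for gene-space analyses.

Meta-gene profiles bin methylation in 100 bp bins over ±5 kb flanks
and 200 bp bins within the gene body; for the meta-gene average the
variable-length body-bin vectors are linearly rescaled to a fixed
20-bin grid. Minus-strand genes are flipped so bin 0 is always 5'
upstream. The promoter dip statistic — mean over all bins minus the
minimum over the promoter bins (−1000..+500 bp around the TSS) — is
exposed for validation. Promoter methylation for the ortholog matrix
is the mean over 50 × 50 bp bins spanning 2500 bp upstream of the
TSS, strand-aware; bins without data are skipped, not imputed. Genes
map to human orthologs through two two-column dictionaries; source
genes sharing one ortholog are averaged.

Embedding uses pairwise-complete Pearson correlation (rows with
undefined pairs dropped iteratively), 1 − r distances, UMAP, and
Leiden communities on the k-nearest-neighbour graph (resolution 0.06
by default). One numerical note: the published sample-wise parameters
(min_dist = 2, spread = 1) originate from an embedding library that
permits min_dist > spread; the library used here does not, so spread
is raised to max(spread, min_dist). Scrambled controls permute
non-missing values over non-missing positions, preserving the
missingness mask exactly (asserted).

Species-held-out classification filters genes to ≥60% sample coverage
and samples to ≥12% gene coverage, draws the configured number of
training species per repetition (no species straddles a split — hard
assertion), and fits a random forest whose trees route missing values
natively, so no global imputation distorts the missingness structure.
Repetitions whose test draw contains one class are discarded and
redrawn. Acceptance-scale runs use 80 samples × 60 genes, 10
repetitions and 80 trees.

## Problem sizes and determinism

All fixtures are generated programmatically. The round-trip check runs
a 1 Mb genome at coverage 20 (≈3000 digest fragments, ≈360k reads);
the digest oracle covers 1000 random 10 kb sequences; model-calibration
checks use 100 replicates each. Every stochastic component takes an
explicit seed and is byte-reproducible; FASTQ output is asserted
byte-identical across runs with the same seed.

## Known limitations

- Consensus construction cannot recover unmethylated cytosines absent
  from the unconverted library; fragment sequences are biased toward
  T at such positions, which is why sequence-feature analyses filter
  to unconverted-covered fragments.
- The Hamming-1 merge can fuse genuinely distinct loci differing at a
  single base (e.g. SNVs between individuals); at 50 bp this is rare
  but not impossible.
- The moderated test assumes approximately Gaussian per-CpG ratios;
  at very low coverage a beta-binomial model would be preferable.
- Stepwise-AIC stability scores rank features; they are not calibrated
  selection probabilities (see above).
- The PWM scanner assumes a 0-order background; no higher-order or
  position-specific background models.
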
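# methcode

Reference-free, cross-species analysis of RRBS DNA methylation data.

Comparative epigenomics across many animal species runs into a basic
obstacle: most species have no (usable) reference genome. `methcode`
implements a complete desk-scale workflow that sidesteps the reference:
reduced representation bisulfite sequencing (RRBS) reads are clustered
into *consensus reference fragments* — locus-level references
reconstructed directly from the reads, with genomic cytosines recovered
from an unconverted companion library — and all downstream analysis is
performed against those fragments. On top of this the package provides:

- **In silico digest** (`insilico_rrbs`): MspI (C^CGG) + TaqI (T^CGA)
  digestion, 50–1000 bp size selection, fragment-end read registration,
  expected CpG coverage of genomic elements, scaffold concatenation
  into pseudo-chromosomes with a reversible coordinate map.
- **Synthetic study generator** (`synthetic_data`): species trees
  (pure-birth, ultrametric), genomes with CpG islands and planted
  repeats, a planted logistic "genomic code" mapping 3-mer content to
  methylation, tissue/individual effects, bisulfite conversion noise,
  spike-in controls, and deterministic FASTQ output.
- **Reference-free core** (`reffree_core`): read-stack clustering by
  C→T-collapsed keys, consensus inference, decoy-based contamination
  filtering, per-sample methylation calling, conversion-rate estimation
  from unmethylated spike-ins.
- **Coverage QC** (`fragment_qc`): repeat / amplified / private
  fragment flags from coverage anomalies; inter-sample CpG overlap.
- **Methylome metrics** (`methylome_metrics`): genome-wide methylation
  aggregation and low/mid/high fragment bins; non-CpG methylation and
  brain-vs-other-tissue contrasts; epiallele erosion via the
  **proportion of discordant reads** (PDR), with its closed-form null
  curve E[PDR](m) = 1 − mⁿ − (1−m)ⁿ.
- **Sequence features** (`seqfeatures`): k-mer spectra, CG composition
  with observed/expected CpG ratio, CpG-island calls (Gardiner-Garden,
  Takai-Jones), and 3-mer-based species clustering.
- **Global models** (`global_models`): OLS with Wherry-adjusted R²,
  phylogenetic GLS under Brownian covariance (exactly OLS on a star
  tree), stepwise AIC selection with bootstrap stability, per-feature
  tests with and without phylogeny, covariate association.
- **Genomic code** (`genomic_code`): discretization of fragments into
  high (>80% in all samples) and low (<20%) methylation classes,
  balanced train/test sets, grid-searched linear spectrum-kernel
  classifiers (C ∈ {0.01, 0.1, 1, 10}, k ∈ 1..10), rank-statistic
  ROC-AUC, cross-species transfer matrices, detection of "inverted"
  species (mean transfer AUC < 0.45), differential feature weights,
  9-mer repeat analysis.
- **Tissue DMRs** (`tissue_dmr`): tissue-vs-individual variance
  decomposition, moderated per-CpG tests with empirical-Bayes variance
  shrinkage, correlation-corrected (Brown-style) Fisher combination
  per fragment, combined-rank top-500 selection, PWM motif enrichment
  with exact score thresholds, TF activity calls and regulator
  networks.
- **Gene-centric analysis** (`genecentric`): cross-mapping of
  fragments to annotated genomes, meta-gene and promoter methylation
  profiles, sample × human-ortholog promoter matrices, embedding and
  Leiden clustering with scrambled controls, species-held-out
  classification with missing-value-native tree ensembles.

## Worked example

Simulate one species end to end and recover its genomic code:

```python
from methcode import synthetic_data as sd
from methcode import reffree_core as rf
from methcode import methylome_metrics as mm
from methcode import genomic_code as gc

genome = sd.simulate_genome(300_000, 0.45, 8, None, seed=1)
cfg = sd.ReadSimConfig(mean_coverage=20, conversion_rate=0.99, seed=2)
fragments = sd.digest_genome(genome.sequence, cfg)             # 1449 fragments
code = sd.random_planted_code(3, scale=5.0)
design = [sd.SampleDesign("heart_1", "sp01", "heart", "i1"),
          sd.SampleDesign("liver_1", "sp01", "liver", "i1")]
methylome = sd.assign_methylome(fragments, code, design, seed=4)
reads = sd.simulate_rrbs_reads(fragments, methylome, design, cfg)
unconv = sd.simulate_unconverted_reads(fragments, cfg)

consensus = rf.build_consensus(
    [r for rs in reads.values() for r in rs], unconv)          # 5780 fragments
calls = rf.call_methylation(reads, consensus)

profile = mm.aggregate_species(calls, species_id="sp01")
print(profile.mean_cpg_methylation)        # 0.392
print(profile.fragment_bin_fractions)      # (0.59, 0.05, 0.36)
_, _, pdr = mm.compute_pdr(calls)
print(pdr)                                 # 0.106
print(mm.expected_pdr(n=4).argmax_m)       # 0.5

seqs = {c.fragment_id: c.sequence for c in consensus}
labeled = gc.discretize_fragments(calls, seqs)                 # 1432 low / 871 high
train, test = gc.make_balanced_sets(labeled, set_size=1200, seed=5)
model = gc.train_code_model(train, k_grid=range(1, 6), folds=5, seed=6)
auc = gc.evaluate_auc(model.score(list(test.frame.sequence)),
                      list(test.frame.label))
print(model.k, model.C, auc)               # 3 10.0 0.705
```

The grid search lands on k = 3 — 3-mer composition carries most of the
predictive signal — and a 50 bp consensus sequence predicts the
fragment's methylation class with AUC ≈ 0.7, squarely in the range seen
when short sequence tiles predict locus-level methylation state. The
genome-wide mean (0.39), the bimodal low/high fragment bins, and a PDR
well below the theoretical maximum of 0.875 at 50% methylation are the
expected signatures of a vertebrate-style methylome.

A thin CLI wraps the entry points a user runs from a shell:

```bash
methcode simulate --config cfg.yaml --out simdir/   # synthetic study
methcode digest --genome genome.fa --out frags.tsv  # in silico RRBS digest
methcode expected-pdr --n 4                         # erosion null curve
```

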
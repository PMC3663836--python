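# Methods

## Ct preprocessing

Raw TaqMan-array Ct values pass through four fixed, stage-checked steps.

1. **Censoring.** Ct strictly above the threshold (default 35 cycles) is
   treated as amplification noise and set to missing. The boundary is
   strict: Ct = 35.0 is retained. Censoring is idempotent.
2. **Detection filter.** A miRNA detected in fewer than `min_fraction`
   (default 0.20) of samples is removed; the boundary is again strict, so
   detection in exactly 20% of samples retains the feature. The card's
   internal-control assays (MammU6, RNU24/43/44/48/6B) are removed
   unconditionally: the pipeline mean-normalizes rather than
   control-normalizes, so controls would otherwise enter the analysis
   matrix as ordinary features. A flag to keep them in the sample mean is
   deliberately *not* offered at the matrix level — exclusion happens
   before normalization, which keeps the sample mean a function of the
   analysis features only.
3. **Mean normalization.** Each sample's mean Ct over its present values is
   subtracted from that sample's Cts. A sample with no present values is an
   error naming the sample. After this step every sample's mean is 0 within
   1e-9 (the package-wide absolute float tolerance).
4. **Relative expression.** `2^(ct_max − ct)` with `ct_max` the *global*
   maximum of the mean-normalized matrix, computed after normalization
   (the formula is applied to normalized values, so its reference point
   lives on the same scale). The global convention gives a single reference
   well: every expression value is ≥ 1 and the minimum is exactly 1.
   `scope="feature"` re-references each miRNA to its own maximum instead;
   both conventions yield identical downstream results for everything
   rank-based (clustering, heatmap ranks, rank-sum tests), which the tests
   assert.

Pools A and B are concatenated into one matrix per sample before
normalization; the two cards form one 667-miRNA profile.

## Clustering

Sample dissimilarity is `1 − ρ_Spearman` over the features present in both
samples (average ranks for ties), so `d ∈ [0, 2]`. Pairs sharing fewer than
`min_overlap` (default 10) features are an error naming the pair rather
than a silently propagated NaN.

Agglomeration follows Ward's minimum-variance criterion through the
Lance–Williams recurrence applied to the dissimilarities **as given** — the
classic "ward.D" dialect of older statistical environments. `squared=True`
updates squared dissimilarities and square-roots the merge heights back
("ward.D2"); the tests verify the exact algebraic correspondence between
the two dialects via scipy's Ward implementation on square-rooted inputs.
Equal-cost merges pick the pair whose clusters contain the
lexicographically smallest leaf ids, making the tree deterministic under
input reordering.

Cutting removes the k−1 highest merges; clusters are named A, B, C, … by
decreasing size (ties by smallest member id). The nested presentation
labels (A / B1 / B2a / B2b) used by the pipeline are a thin layer: the
top-level pediatric-rich cluster is named B, its pediatric-rich child B2,
and B2 is split once more. Heatmap output is the rank-of-sample-per-miRNA
matrix; image rendering is out of scope.

`identify_split_drivers` runs the rank-sum/Bonferroni machinery between the
two clusters of a split and returns the significant miRNAs. Dropping a
feature block re-checks the matrix invariants and records the removal (the
minimum may then exceed 1).

## Differential expression

Per comparison, each miRNA with at least two present values in both groups
is tested with a two-sided Wilcoxon rank-sum. In `auto` mode the exact null
distribution is used when the smaller group has ≤ 8 observations and the
pooled values are tie-free; otherwise the normal approximation with
average-rank tie correction and continuity correction. Features failing the
presence rule are dropped from the family and logged.

Bonferroni control uses the family of miRNAs actually tested **within**
each comparison, not across all ten comparisons — the comparisons have
different eligible feature sets, and the published per-comparison lists are
organized the same way. Direction (`higher_in_a` / `higher_in_b`) comes
from the comparison of group mean ranks and is reported separately from the
two-sided p. Significance means adjusted p < α (default 0.05); an
uncorrected mode is intentionally not the default.

The ten comparisons are: (1) adult mutant vs pediatric, (2) adult WT vs
pediatric WT, (3) all adult vs pediatric, (4) adult WT vs adult mutant,
(5) all WT vs all mutant, (6) cluster B2a vs B2b (requires cluster labels),
(7) SDHB-immunopositive vs -immunonegative, (8) 14q32 FISH loss vs no loss,
(9) adult high vs low risk, (10) adult DOD/AWD vs no evidence of disease.
A comparison whose groups are empty on a given table is skipped with a
logged reason, never an error.

## Target integration

A diametric set pairs the miRNAs significantly *lower* in a class with the
genes significantly *higher* in that class, over the same contrast. Five
distinct pairing schemes are encoded (the published list of six repeats its
first entry verbatim; it is encoded once). The statistic is the count of
predicted miRNA→gene pairs linking the two sets.

Because the original over-representation software never specified its
chance model, two nulls bracket it:

- **Permutation (default, degree-aware on the miRNA side).** Gene sets of
  equal size are resampled uniformly without replacement from the gene
  universe; p = (1 + #{count ≥ observed}) / (1 + B). `permute="mirnas"`
  resamples the miRNA side instead. Fixed seed ⇒ bit-identical results.
- **Hypergeometric (degree-blind).** In the flattened pair space of the
  fixed miRNA set (population |M|·|G|, of which K pairs are predicted
  interactions, with |M|·|genes_up| drawn), the upper-tail probability of
  the observed count. Its expectation, Σ_m deg(m)·|genes_up|/|G|, is the
  reported `expected` under both nulls.

Universes are the measured-and-expressed miRNAs/genes (post detection
filter), not the genome — standard enrichment practice that prevents
detection-bias inflation. Target pairs are taken at face value per miRNA
id; no family collapsing is applied by default.

## Imprinting analysis

The 14q32 miRNA mega-cluster is transcribed only from the maternal allele;
methylation-specific PCR of the MEG3-promoter DMR with maternal/paternal
primers reads out which alleles remain. Classification is total on the
2×2×2 band/control space: both bands ⇒ normal pattern; maternal only ⇒
paternal (silent) allele lost; paternal only ⇒ maternal (expressed) allele
lost; no bands or failed bisulfite control ⇒ uninterpretable. A
normal-pattern call in a FISH-loss case is flagged as a discordance
(admixed stromal DNA), never reclassified. Concordance fractions are kept
at full precision; display rounding is to the nearest integer percent.
Band intensity thresholding is upstream of this package: inputs are
boolean calls, not gel images.

## Synthetic cohort generator

The generator emulates the study conditions: 30 adult mutant, 25 adult WT
(11 SDHB-negative) and 18 pediatric WT samples over 667 miRNAs plus 6
controls on two card pools. Structure planted (all shifts on the Ct scale,
where measurement and dropout live):

- per-feature baselines ~ N(28, 2) cycles, per-well technical noise
  sd 1.0 cycles (a typical replicate scatter for FFPE-derived TLDA data;
  the baseline parameters are conventional for such arrays, not estimates
  from the profiled cohort);
- a 47-member imprinted block shifted +4 cycles (16-fold down) in cases
  that lost the expressed maternal allele, and in pediatric-type cases,
  where normal methylation coexists with block silencing by some other
  mechanism;
- adult-type allelic states drawn 9 : 5 : 4 (paternal loss : maternal
  loss : normal), the proportions observed among tested cases;
- a 16-miRNA SDHB signature in SDHB-negative cases, half up and half down
  by 3 cycles;
- optional planted DE per named comparison (default: 20 miRNAs, +3 cycles
  in WT, in the all-WT-vs-all-mutant contrast), matched by a gene DE table
  and a target-pair matrix with 2% background density and 10% density
  inside the designated diametric sets;
- logistic dropout P(missing) = expit(slope·(Ct − 34)) with slope 1.0, so
  half of the wells at Ct 34 drop out and the emitted matrix still
  contains values above the censoring threshold;
- methylation calls consistent with the allelic states except for a 20%
  stromal-contamination rate on loss cases (mirroring the imperfect
  published concordances).

One seed drives independent child streams per table (cases, Ct, dropout,
methylation, gene DE, targets), so adding a table never perturbs earlier
draws; identical configs are bit-identical.

What the generator does *not* emulate: genomic coordinates or sequence
content, amplification-efficiency differences, batch structure, sample
degradation gradients, or correlated (co-regulated) noise between miRNAs
outside the planted blocks. Passing tests therefore demonstrate that the
statistical machinery behaves correctly under the planted model, not that
the biological conclusions would survive such artefacts in real data.

## Problem sizes used by the test and acceptance runs

Property suites run at deliberately small sizes chosen to keep the full
suite fast while leaving the checks sharp: exact-test oracles enumerate all
group assignments up to 12 pooled observations; Ward agglomeration is
cross-checked against a from-scratch Lance–Williams recomputation on up to
7 points; family-wise error is estimated from 500 null replicates of a
20-feature, 15-vs-15 design; enrichment calibration uses 100 replicates at
background density and 40 at planted density; the imprinted-block recovery
experiment uses 50 replicates of the full 667 × 73 cohort.

## Known limitations and deliberate choices

- The imprinted-block recovery experiment recovers a median of ~42 of the
  47 planted block members (with essentially no false drivers): a 4-cycle
  silencing shift pushes block members whose baseline lies above ~Ct 30.5
  beyond the censoring threshold and the dropout midpoint, so in the
  ~12-sample silenced group they lose the two-present-values-per-group
  testability rule or the power to clear Bonferroni. This is a property of
  the measurement process being simulated — silenced low-abundance miRNAs
  genuinely leave the detectable range — not of the clustering, which
  separates the silenced from the expressing samples essentially always.
- Exact Wilcoxon p-values with ties present fall back to the normal
  approximation in `auto` mode; forcing `exact` with ties uses the
  tie-blind exact distribution.
- The ward.D/ward.D2 choice matters for merge heights but rarely for
  small-k partitions; both are exposed.
- Bonferroni (not FDR) is used throughout by design; with ~660-member
  families it is conservative, which the null simulations confirm.
- No cluster-stability (bootstrap/consensus) assessment is implemented.
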
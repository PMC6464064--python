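# Methods

## Scope and model

`regcl` models promoter-proximal transcriptional regulation as the spatial
organization of information-dense TFBS clusters. The pipeline has five
stages — scanning, clustering, featurization, labeling, learning — plus an
in-silico mutagenesis loop that re-runs the first four on a variant allele.

### Scanning

A site's strength is its individual information R_i, the sum of the iPWM's
bit weights along the k-mer; R_sequence (the matrix's average information
content / area under the sequence logo) is taken from file metadata when
present and otherwise recomputed from the weights under the importer
convention `w = 2 + log2 f` (columns renormalized to absorb the floor applied
to vanishing frequencies). Both strands of every accessible promoter
subinterval are scanned; windows containing non-ACGT characters are skipped
rather than scored with fabricated weights, and windows with
R_i ≥ 0.1 · R_sequence are kept. Overlapping hits and palindromic
both-strand hits are all retained: cluster information totals are sums over
every reported site, so de-overlapping would change downstream quantities.
Promoters are strictly upstream of the TSS (10 kb by default, clamped at
contig edges); accessibility masking intersects the promoter with DNase
intervals and merges the pieces.

### Clustering (IDBC)

Information density-based clustering is implemented as a deterministic
seed–merge–filter procedure: each site seeds the interval
`[center − d, center + d)` with `center = start + ⌊L/2⌋` (symmetric under
strand); transitively overlapping seeds merge into one group; a group is
emitted when its summed R_i reaches the threshold I (inclusive). Defaults:
d = 25 bp; I = R_sequence for a single-TF (homotypic) panel and the sum of
R_sequence values for a multi-TF (heterotypic) panel, both overridable. The
procedure is isolated in one function (`clustering.idbc`) so an alternative
grouping rule can be swapped in; its partition provably equals the
transitive closure of the "centers within 2d" relation, which the test suite
checks against a brute-force union-find oracle. Cluster-to-TSS distance uses
the nearest span edge, 0 when the TSS falls inside the span.

### Featurization

Per cluster: f1 distance to TSS (bp), f2 length (bp), f3 information content
(bits), and per TF f4 site count, f5 strong-site count, f6 summed R_i,
f7 summed strong-site R_i, with *strong* meaning R_i > R_sequence — strictly:
a site exactly at R_sequence counts in f4/f6 but not f5/f7. Homotypic panels
drop f6 (it duplicates f3), giving 6-value blocks. Clusters are ordered
5'→3' along the promoter strand; genes are padded to a common slot count
M_max with all-zero null-cluster blocks at the distal (5') end, so the most
TSS-proximal cluster always occupies the last slot. The null block zeroes
every field including distance; a zero distance is therefore ambiguous
between "no cluster" and "cluster at the TSS", which the count features
disambiguate — a documented modeling caveat. At prediction time a matrix is
assembled under the training M_max, truncating the most distal clusters of
genes that exceed it (training data itself never does).

### Labeling

CRISPR guide-coefficient matrices hold log10 fold changes. A gene is a
positive target when (1) all its per-guide fold changes lie on the same side
of 1 — a zero coefficient breaks consistency, being neither above nor
below — (2) the *arithmetic mean of the per-guide fold changes*
(mean of 10^c, the literal reading of "average fold change", not
10^mean-coefficient; the alternative is a one-line change) exceeds ε or
falls below 1/ε in the shared direction, and (3) the 10 kb promoter of any
of its TSSs overlaps a merged ChIP-seq peak by ≥ 1 bp. All-zero rows are
negatives. Balancing keeps the |positives| negatives with the *smallest*
Bray-Curtis similarity to the positive with the largest mean coefficient;
ties break lexicographically, making the selection input-order invariant.
siRNA labels use p ≤ 0.01 plus peak overlap for positives and p > 0.01 for
negatives; siRNA sets are not balanced (balancing is a CRISPR-route step),
though the same function can be applied to them.

### Learning

The primary learner is an unpruned CART decision tree with Gini impurity and
axis-aligned binary splits, grown until leaves are pure or unsplittable —
spelled out concretely rather than inherited from any library's drifting
defaults, and realized by scikit-learn's `DecisionTreeClassifier`. Naive
Bayes, random forest and SVMs (linear/RBF/poly/sigmoid kernels) are available
for comparison only. Evaluation: 10 rounds of stratified 10-fold
cross-validation with folds re-drawn each round from a seeded stream
(stratification avoids empty-class folds at small n); per round the confusion
counts accumulate over test folds; sensitivity = TP/(TP+FN) on the positive
class. ROC scores from a hard tree are the positive-class fraction at the
leaf; margin classifiers without probabilities use the min-max-scaled
decision function (rank-preserving, hence AUC-neutral). Gini importances are
scikit-learn's normalized impurity-decrease totals.

### Mutagenesis

Variants are single-nucleotide only, entered 1-based (VCF convention) and
converted in exactly one audited function (`formats.to_zero_based`). The
stated reference base is checked against the genome before any edit. After
mutation the pipeline re-runs; wild and variant sites pair by
(TF, strand, span overlap) — a mutation can shift the best-scoring window, so
pairing is positional overlap, not coordinate identity. A wild cluster is
*retained* when any variant cluster passing I overlaps its span, else
*abolished*; span overlap is the only coordinate-stable wild→variant mapping.
`design_cluster_knockouts` abolishes a chosen cluster by sequentially
mutating the strongest remaining site of whatever overlapping cluster
survives, re-scanning after each substitution — one substitution usually
suffices, but overlapping windows that keep the total above I trigger further
rounds. Indels are out of scope.

## Synthetic data: what it emulates, what it does not

The generators produce every input the pipeline consumes, with planted truth:

- **iPWMs** (`gen_ipwm`): per-position frequencies from a Dirichlet sharpened
  by a bisected temperature until the matrix information content hits the
  target ± 0.5 bits (temperature 0 = uniform = 0 bits; → ∞ = one-hot =
  2 bits/position, so the bisection is monotone). Weights are 2 + log2 f,
  floored at −10 bits; the realized content is stored as metadata.
- **Promoters** (`gen_promoters`): one contig per gene, i.i.d. background
  bases (GC configurable, uniform by default), TSS at the contig end.
  Positive genes receive 1..`clusters_per_positive` homotypic clusters of
  `sites_per_cluster` consensus-derived sites spaced within 2d so they merge;
  DNase intervals cover every plant (plus random background accessibility in
  all genes) and ChIP-like peaks cover plants only. Cluster counts vary per
  gene so a classifier must use the TSS-proximal slots rather than memorize a
  fixed layout.
- **Planted strength**: each cluster's total-information target is
  I · (1 + 5(ε − 1)) · LogNormal(0, 0.25), coupling knockdown effect size to
  promoter signal: ε = 1.01 plants sit marginally at the clustering
  threshold, ε = 1.1 plants clear it, which is what makes classifier accuracy
  rise with ε. Site k-mers are designed greedily from the consensus by
  applying the largest weight reductions that do not overshoot, so realized
  R_i brackets the target from above.
- **Expression** (`gen_expression`): one log-normal tissue archetype per gene
  group, members = archetype × gene scale × multiplicative noise, giving
  within-group Bray-Curtis similarity above between-group.
- **Knockdown** (`gen_knockdown`): target rows get same-sign coefficients
  with every per-guide fold change beyond ε^1.2 (so the labeling criteria
  hold by construction); non-targets are exact zeros; optional mixed-sign
  decoys stay unlabeled.

Defaults are the study conditions: 200 genes, 100 positives, 53 tissues,
10 kb promoters, d = 25, ε ∈ {1.01, 1.05, 1.1}, 12-bp matrices at 15 bits.
The matrix information content was calibrated once, by Monte-Carlo, against
the generator's stated contract that background accessibility alone forms a
passing cluster in < 5% of negative promoters (at 13 bits the rate is ~20%,
at 15 bits ~2.5%).

Not emulated: nucleosome positioning and chromatin domain structure, read- or
peak-level ChIP noise, multiple TSSs per gene, correlated guide failures,
isoform-resolved expression, and heterotypic cofactor co-occurrence
structure. Passing tests therefore demonstrate that the machinery recovers
planted organization under the stated noise model — not that real promoters
are this clean; on real data the accessible-interval boundaries and peak
quality dominate performance.

## Numerical and design choices

- Thresholds are inclusive (`>=`) at the scan cutoff and at I; the strong-site
  rule is strict (`>`). Ranking and balancing ties break lexicographically by
  gene id, so every reported list is deterministic.
- Bray-Curtis is computed on raw (untransformed) expression vectors; the
  all-zero/all-zero case returns 1 by definition. The metric's known weakness
  — an all-zero profile is equally dissimilar to every expressed gene — is
  left uncorrected; callers can drop never-expressed genes.
- Genes with missing tissue values are excluded at expression load time, not
  imputed; knockdown matrices reject missing cells outright.
- Raising ε can only shrink the positive set; raising I can only reduce
  cluster counts; raising d can only reduce merged-group counts — all three
  monotonicities are property-tested.
- Randomness flows from `numpy.random.SeedSequence` spawns, so every
  generator and the cross-validation fold stream are reproducible per seed.
- `matrix_r_sequence` raises on weights above 2 bits (frequencies
  unrecoverable) unless metadata is present; recovered frequency columns must
  sum to 1 within 5%.

## Known limitations

- Only SNVs in mutagenesis; the CLI does not persist trained models
  (classifier re-prediction after mutation is an API-level operation).
- Null-cluster padding zeroes the distance feature (see caveat above).
- The heterotypic route is fully implemented but the planted benchmark
  exercises the homotypic (single-TF) configuration, matching the TF-target
  prediction task; heterotypic behavior is covered by unit tests only.
- Feature matrices are dense; with very large panels (hundreds of TFs) and
  many cluster slots the per-TF blocks grow as 4·K per slot.
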
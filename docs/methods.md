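# Methods

This note documents the models, parameter choices and numerical
conventions behind `utrdecay`, and what the synthetic study conditions
do and do not establish about real data.

## The synthetic study conditions

The generator (`utrdecay.simulate`) emulates a two-condition experiment:
a "naive" state and a "primed" state reached after a signaling cue. Each
gene is a single-isoform 3'UTR with:

- **Regulation class** — down / up / control in configurable proportions
  (default 1/3 each, largest-remainder apportionment so divisible gene
  counts give exact class sizes).
- **One terminal canonical PAS** (AATAAA) whose 3' end lies 20–40 nt
  from the UTR terminus. Spurious AATAAA occurrences elsewhere are
  mutated away (middle base → C, which cannot recreate the hexamer), so
  `locate_terminal_pas` has exactly one valid answer per gene.
- **Planted AUU trimers** within the 100-nt terminal window upstream of
  the PAS, Poisson-distributed with class-specific rates — default 8 for
  the down class and 3 for up/control, matching the observed median
  valency of destabilized 3'UTR termini against background. Planted
  positions are non-overlapping and recorded in the truth table.
- **Background sequence** i.i.d. with configurable GC content (default
  0.40, a typical mammalian 3'UTR composition; the real background
  composition is not specified anywhere, so this is exposed as a knob).
- **True half-lives** drawn uniformly from 2–10 h, the bulk of the
  mammalian mRNA range (mES medians sit near 4–6 h). Down-class genes
  are destabilized by a factor of 2 in the primed condition. The range
  matters: the delta-half-life ranking must separate true destabilization
  (minimum delta = 1 h at t½ = 2 h) from the fit noise of long-lived
  controls, and the recovery requirement on the generator's defaults
  fixes how wide a range the default conditions can use.

Cross-link tracks are drawn per gene from a mixture of uniform
background (weight 0.3) and hotspot components (±5 nt around hotspot
centers). In the naive condition hotspots sit at two interior positions;
in the primed condition the down-class hotspots are the planted terminal
AUU positions, so the regulator's signal relocates to 3'UTR termini.
Down-class genes additionally receive 2× expected depth in the primed
condition (`primed_binding_boost`), reflecting enhanced terminal
binding of the activated regulator; without it the per-UTR mean track
features would carry no class signal and the feature-based classifier
would have nothing to detect.

Conversion time courses are v(t) = exp(−λt) + ε, ε ~ N(0, 0.02²)
truncated at 0, at chase timepoints {0, 3, 6, 12, 24, 48} h. The noise
model is a deliberate simplification (no coverage-dependent variance, no
T-content normalization artifacts); background subtraction and
normalization are assumed done upstream, so the module consumes clean
normalized fractions.

**What passing tests show** — that the estimators and summaries recover
planted signal under exponential kinetics, i.i.d. background sequence
and position-independent noise. They do not establish robustness to
multi-isoform genes, alignment artifacts, UMI saturation,
non-exponential decay, or correlated biological replicates, none of
which the generator emulates.

## Half-life estimation

`fit_halflife` runs Levenberg–Marquardt least squares
(`scipy.optimize.curve_fit`) on v(t) = v0·exp(−λt) with v0 free
(initialized at the first observation) and λ ∈ (1e−6, 100) h⁻¹
initialized at ln2 / median(t). A fit is non-converged when the
optimizer fails, all values are zero, or λ collapses onto its lower
bound (a flat series). R² = 1 − SS_res/SS_tot against the mean of the
observed values. The R² > 0.6 gate applies per gene across **all**
conditions. Delta-half-life ranking breaks ties lexicographically by
gene id so results are deterministic; requesting more labels than genes
labels everything with a warning.

At the default study conditions (1,000 genes, 6 timepoints, noise 0.02)
the median relative half-life error is ~2.8% and the down regulon is
recovered at ~98%.

## Stability classification

The boosted-tree harness follows a fixed protocol: stratified 75/25
train/hold-out split; grid search over interaction depth {1, 3, 6},
shrinkage {0.01, 0.1} and tree counts {50, 100, 200} (the full published
grid — trees 1..500, shrinkage 0.001..0.1 — is available via
`grid="full"`), minimum terminal-node size 10; model selection by mean
AUROC over 5-fold CV repeated 5 times; final metrics (AUROC, accuracy,
MCC) from the hold-out only. The tree-count axis is scored from
`staged_decision_function` of a single maximal fit per (depth,
shrinkage) pair, which is mathematically identical to fitting each tree
count separately but threefold cheaper. Ties in CV AUROC resolve to the
smallest parameter triple. Gradient boosting is scikit-learn's
`GradientBoostingClassifier`; the harness contract (grid, CV scheme, two
importance outputs) is independent of the backing implementation.

Permutation importance shuffles one column at a time (10 seeded
shuffles) and reports the mean hold-out AUROC drop; relative influence
is the ensemble's impurity-based importance.

## Motif analysis

*Enrichment.* For each 5-mer, occurrences within ±20 nt of cross-link
sites are compared against 100 seeded draws of equally many uniform
positions from the same UTRs (matched per gene, so sequence composition
is controlled). The score is the z-statistic against the background
draws; the p-value is the empirical permutation tail with a +1
pseudocount — floor 1/(n_shuffle+1) ≈ 0.0099 — because a continuous
normal tail over 1,024 k-mers cannot keep the family-wise minimum p
calibrated at desk-scale shuffle counts. "Relevant positions" are
offsets where the observed per-offset count exceeds background mean +
2 sd; with fewer than 50 cross-links the background draw is widened
tenfold (with a warning).

*Clustering distance.* Substring sets contain all substrings of length
< k (so "UGA" → {U, G, A, UG, GA}); the Jaccard distance is 1 − |∩|/|∪|.
Rank distance is |rankᵢ − rankⱼ|. Both matrices are standard-scaled and
min–max-scaled **globally over all entries** (per-column scaling would
break symmetry and the zero diagonal), then combined as √(a² + b²).
UPGMA operates on correlation distances between the rows of the
combined matrix — the matrix is treated as a feature embedding, which is
the literal pipeline order of the original description. Constant rows
(correlation undefined) become singleton groups with a warning. Group
names come from diagnostic-trimer voting (AUU / WGG / GAU families,
alphabetical tie-break); the WGG merge of the two G-rich clusters is
opt-in (`merge_g_rich=True`) since it is a post-hoc judgment.

*Coverage and sites.* cDNA weights in cross-link-anchored coverage are
capped at 20 so a few very deep sites cannot dominate; positions outside
the sequence count toward the denominator but can never be covered.
Binding sites require a group k-mer starting at one of its relevant
offsets within ±20 nt of a cross-link; overlapping same-group sites
merge, and support sums each contributing cross-link once. Peak merging
joins book-ended or overlapping intervals within a set; across sets,
overlap classification requires ≥ 1 nt of true intersection (book-ended
pairs do not overlap).

## Cross-link normalization and metaprofiles

value(pos) = count(pos) · 1e6 / library_size / TPM(gene), i.e. CPM per
TPM; genes with zero or missing TPM are dropped with a warning.
Gene-level TPM sums transcript TPM within a gene per replicate, then
averages across replicates.

Smoothing is a centered triangular rolling mean (default 20 nt, scipy
`triang` weights, normalized to unit mass so constants are preserved);
edge positions take the nearest valid smoothed value. The order of
operations is normalize → extract anchored window → smooth within the
window → average across regions. Bootstrap CIs resample regions (not
positions), percentile method, n = 1000, seeded; a single region yields
a zero-width CI by construction.

Whole-transcript binning uses 100 equal-width bins with the remainder
spread over the leading bins (length mod 100 leading bins get one extra
nucleotide); regions shorter than the bin count fall back to
repeated-boundary binning and are flagged. Per-UTR heat-map rows are
moving-average smoothed (window 10) and min–max normalized; constant
rows — including all-zero — map to all-zero (resolving the 0/0
convention downward). Binned log2 fold changes convert 20-nt-binned
counts to within-region percentages and add 1 to each percentage before
the ratio. The terminal-abundance comparison applies, in order, the
length (≥ 800 nt), expression (≥ 1 TPM) and per-sample cDNA (≥ 5 in both
300-nt windows) filters and reports a per-filter exclusion tally.

## Sequence classifier

Architecture (scaled-down default / published-scale preset): conv stem
and 3 conv blocks of 16 / 5 filters, kernel 5, each convolution followed
by layer normalization and ReLU, dropout 0.25 / 0.34 and max-pool 2 per
block; GRU of 24 / 64 units consuming the sequence reversed; dense
24 / 64 with batch normalization and ReLU; softmax output. Inputs
shorter than pool^n_blocks = 8 nt are rejected with that formula. The
network and its gradients run on a small reverse-mode autodiff engine
(`utrdecay.seqmodel.autodiff`) written for this package; gradient
correctness is checked against central differences in the test suite.

Training: Adam (default lr 3e-3; preset lr 5e-5, β₂ 0.98, clipnorm 0.5),
categorical cross-entropy, L1/L2 penalties on convolution weights,
batches of 64, early stopping on validation loss with best-weight
restore. The default schedule arms early stopping only after epoch 20
(patience 10, max 40): on small planted-signal tasks the validation loss
plateaus near ln 2 for 10–15 epochs before the signal is found, and
un-warmed patience reliably stops inside that plateau. The published
regularization preset treats its reported L1 of ~7.53e4 as a typo for
7.53e-4 — at 7.53e4 every weight is driven to zero and the model cannot
train; both values are selectable.

Attribution is integrated gradients with the all-N (all-zero) baseline,
default 24 path steps, batch-norm in inference mode. Attributions are
exactly zero off the one-hot support and for all-N inputs, and their
per-sequence sums track the model's logit difference from baseline
(Spearman ρ > 0.9 on the planted task). Trimer summaries assign each
3-nt window's mean score to the trimer at its start position, bin window
starts into 100 relative bins (same remainder rule as above), sum within
bins, normalize by bin width and average across sequences — so an
all-ones attribution reproduces the binned trimer occupancy map, which
the test suite checks against a direct count.

On the 2,000-sequence planted terminal-AUU task (3'UTRs of 150–300 nt,
kept short to bound training cost) the scaled-down model reaches test
AUROC ≈ 0.85–0.89 across seeds, collapses to chance under label
shuffling, and attributes 2–6× more absolute importance to planted
motif positions than to background.

## Pipeline

`run_pipeline` executes enabled stages in dependency order from a
validated YAML config (unknown keys anywhere are errors; nothing runs on
an invalid config). One global seed fans out through a fixed affine map
to per-stage seeds, so toggling one stage does not shift another's
randomness. Each stage writes a manifest (parameters, seed, SHA-256 of
inputs and outputs); reruns from the same config produce identical
manifests, and every number in the report traces to a manifest.

## Problem sizes

Benchmarks run at the package's desk-scale study conditions: 1,000 genes
for half-life recovery, the default 300-gene transcriptome for
metaprofiles and the GBM drivers, 20 seeds for clustering recovery,
1,000 rows for the label-permutation null, and 2,000 sequences for the
sequence model. These sizes were chosen to make the statistical claims
meaningful (binomial noise on recovery rates well below the margins
being asserted) while remaining runnable on a single CPU.

## Known limitations

- Single-isoform genes, plus strand only in the simulator (readers are
  strand-aware); no antisense or overlapping-gene structure.
- The k-mer enrichment is a deliberately simple permutation surrogate
  for positional k-mer enrichment analysis; ranks and relevant-position
  sets are compatible with downstream use, but scores are not
  comparable to the original tool's.
- The exponential model is single-rate; biphasic decay will fail the R²
  gate rather than be modeled.
- The sequence model's published-scale preset is provided for
  completeness but is not exercised at full input length (3,425 nt) in
  the test suite; desk-scale tasks use shorter UTRs.
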
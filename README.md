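# utrdecay

Analyses of signal-induced, selective mRNA decay at 3'UTR termini — the
computational half of a study design in which a signaling cue (MEK/ERK
activation during the naive-to-primed pluripotency transition)
repositions an RNA-binding regulator onto AU-rich 3'UTR terminal regions
and thereby destabilizes a co-regulated set of transcripts. The package
is aimed at computational RNA biologists who want a tested, end-to-end
reimplementation of the analysis stack: metabolic-labeling half-life
estimation, feature-based stability classification, k-mer motif-group
discovery from cross-link (iCLIP-style) data, positional cross-link and
motif metaprofiling around poly(A) signals, and a sequence-only neural
classifier with per-nucleotide attribution.

Because the original sequencing depositions are not required, the
package ships a first-class synthetic-data module that generates a
ground-truthed transcriptome emulating the study conditions; every
downstream stage is validated by recovering what was planted.

## What it computes

**Half-lives from conversion time courses.** Background-subtracted,
chase-normalized T>C conversion fractions v(t) are fit per transcript
and condition to

    v(t) = v0 · exp(−λt),    t½ = ln 2 / λ

by nonlinear least squares; transcripts are kept when the fit converges
with R² > 0.6 in every condition, then ranked by Δt½ between conditions
to define "decreased" / "increased" stability classes (top n each way).

**Stability classification.** A feature matrix over 3'UTRs (G+C content,
the 16 overlapping dinucleotide frequencies, UTR width, optional
conservation, plus the per-UTR mean signal of each cross-link track)
feeds gradient-boosted trees with a stratified 75/25 train/hold-out
split and a grid search (interaction depth × tree count × shrinkage)
scored by 5-fold cross-validation repeated 5 times, maximizing AUROC.
Feature importance is reported both as the ensemble's relative influence
and as permutation importance (hold-out AUROC drop over 10 shuffles).

**Motif groups from cross-link data.** 5-mers enriched within ±20 nt of
cross-link sites (permutation z-score against uniform background draws
from the same UTRs) are clustered with a combined distance: substring-set
Jaccard distance between k-mer sequences and Euclidean distance between
enrichment ranks, each standard-scaled then min–max-scaled, joined by
Pythagorean addition (√(a² + b²)), re-compared by correlation distance
and linked by UPGMA; the tree is cut into four groups (with an optional
merge of the two G-rich groups into WGG).

**Positional summaries.** Cross-link counts are normalized to CPM
(per-library) and then per gene to its expression (CPM per TPM), smoothed
with a 20-nt triangular window, and averaged across regions anchored on
the terminal canonical PAS (AAUAAA) or the 3'UTR terminus, with
bootstrap 95% CIs (regions resampled). Also: 100-bin whole-transcript
profiles, per-UTR min–max heat-map rows, 20-nt-binned log2 fold changes
with a +1 pseudocount, terminal-vs-start abundance with explicit filter
tallies, trimer valency upstream of the PAS, and nucleotide composition
around the PAS.

**Sequence-only classification.** A 1-D CNN (stem + three conv blocks
with dropout and max-pooling, layer normalization + ReLU after each
convolution) feeds a GRU that reads the sequence in reverse (real
nucleotides last, N-padding first), then two dense layers with softmax.
Implemented on a small numpy reverse-mode autodiff engine included in
the package; the same engine supplies integrated-gradients attribution
against the all-N baseline, summarized into per-trimer and positional
importance profiles over 100 relative bins.

## Worked example

The numbered drivers under `analysis/` run the full story on synthetic
data (defaults: 300 genes, one third destabilized 2× in the primed
condition, AUU trimers planted at rate 8 vs 3 in the 100 nt upstream of
the PAS):

```sh
python analysis/01_simulate.py
python analysis/02_fit_halflives.py
python analysis/03_stability_features.py
python analysis/04_motif_groups.py
python analysis/05_clip_profiles.py
python analysis/06_sequence_model.py   # ~4 min on one CPU
```

Output from a run with the default seed:

```
fit 600 series; 300 genes pass R^2 > 0.6 in all conditions
delta-half-life ranking recovers 99/100 (99.0%) of the down regulon

regulation groups: {'up': 100, 'down': 100, 'control': 100}
hold-out AUROC=0.998 accuracy=0.960 MCC=0.923
top feature by relative influence: clip_regulator_primed

180 5-mers enriched at p < 0.05; top ranked: UUAUU, AUUAU, UAUUA, CAUUA, AUUAA
median AUU valency in the 100 nt upstream of the PAS:
  {'control': 5.0, 'down': 9.0, 'up': 5.0}
down/control valency factor: 1.80

down:    mean terminal coverage 2.222 CPM/TPM (n=100)
control: mean terminal coverage 0.128 CPM/TPM (n=100)
up:      mean terminal coverage 0.112 CPM/TPM (n=100)
```

Read: half-lives and the destabilized regulon are recovered almost
perfectly from the conversion kinetics; the regulator's cross-link track
is the top-ranked stability predictor; the enriched k-mers around its
primed-condition cross-links are AUU-family 5-mers; destabilized 3'UTRs
carry ~1.8× the AUU valency of controls upstream of the PAS; and the
regulator's normalized terminal coverage is an order of magnitude higher
on down-class UTRs in the primed condition.

The whole pipeline can also be run from one YAML config via
`utrdecay.pipeline.run_pipeline` (`validate_config` checks it first);
each stage writes a manifest with parameters, seed and output hashes.

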
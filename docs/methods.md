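# Methods

## Problem and model

Small RNAs (18–50 nt) are exported from cells into extracellular space —
vesicle-packaged (EV) or free in conditioned medium (CM) — at rates that do
not track their intracellular abundance, which implies a *cis*-regulatory
sequence grammar read by the sorting machinery (RNA-binding proteins such as
YBX1, whose CCUGGC site is the canonical example). `secgram` treats secretion
as a binary classification problem over curated extracellular (EC) vs
intracellular (IC) sequence sets and then interrogates the fitted classifier
to recover that grammar.

The flagship classifier is a stacked, unidirectional GRU over the one-hot
primary sequence:

    z_t = σ(W_z x_t + U_z h_{t-1} + b_z)
    r_t = σ(W_r x_t + U_r h_{t-1} + b_r)
    h'_t = tanh(W_h x_t + U_h (r_t ∘ h_{t-1}) + b_h)
    h_t = (1 − z_t) ∘ h_{t-1} + z_t ∘ h'_t

with the final hidden state mapped through a linear layer and a sigmoid; the
output is read as a secretion probability. LSTM and VGG-style CNN variants
(conv blocks with width-2 max pooling, dense head 1024→128) are provided for
comparison, along with linear/RBF SVMs and random forests (50 or 200 trees,
depth 20) over tabular sequence+structure features. Because no deep-learning
framework is assumed, the deep families run on a small tape-based numpy
autodiff engine (`secgram/_autodiff.py`); recurrent layers are fused
(hand-derived backprop-through-time) so desk-scale corpora train on one CPU
in minutes. Gradients were verified against central finite differences to
~1e-5 relative error, and the cell semantics against independent scalar
transcriptions of the recurrences to 1e-12.

## Curation

Four ordered steps, each audited in an attrition report:

1. **Shared labels** — a sequence observed in both compartments keeps a
   single EC copy (exported RNAs also exist intracellularly, so an EC
   observation dominates).
2. **Length / ambiguity** — keep 18 ≤ len ≤ 50 (inclusive), drop sequences
   containing N.
3. **Duplicates and substrings** — exact duplicates collapse (ties keep the
   lexicographically smaller id); any sequence contained in a longer retained
   sequence is dropped. Implemented as a length-bucketed scan against a
   joined haystack, so it is near-linear in practice.
4. **Low complexity** — a DUST-style score: for a window w = min(len, 64),
   score = Σ c_t(c_t−1)/2 over triplet counts, normalized by (w−2). The
   default threshold 2.0 flags perfect dinucleotide repeats of length ≥ 12
   (an 18-nt AC-repeat scores 3.5) while passing random 18-mers; the
   threshold is a package default, not a claim about the original DUST tool.

The pipeline is idempotent, and the step order matters: the length filter
runs before substring collapse, so an 18-mer contained in a 51-mer survives
(its container is removed first).

## Features

Each sequence gets four representations: primary sequence, dot-bracket
secondary structure, per-position structural elements (f five-prime, t
three-prime, s stem, i interior loop, m multiloop, h hairpin), and the
8-term notation (sequence letters upper-cased at paired positions). K-mer
frequencies (k ∈ {1,2,3,4,5,7}) are counted per representation and divided
by the token count L−k+1, so each (representation, k) block lies on a
simplex — the divisor interprets "length normalization" in its testable
form. Free energy is emitted both raw and per nucleotide (per-nt used by
default), and sequence length is a feature.

Folding backends: `vienna` delegates to the ViennaRNA bindings when
installed; the default `nussinov` backend maximizes Watson–Crick+GU pairs
(minimum hairpin loop 3, energy −1 per pair) and is exact against exhaustive
enumeration for short sequences. The element annotator classifies an
unpaired position by its closest enclosing pair: zero enclosed helices →
hairpin, one → interior/bulge, two or more → multiloop; unpaired positions
outside all pairs are f before the first paired base, t after the last, m
between top-level helices. The six element letters are all supported even
though the originating description counts "five types" — the letter list
itself names six.

One-hot encoding fixes length at 50: longer sequences keep their 5′ end
(small-RNA identity is 5′-anchored for most biotypes), shorter ones are
right-padded with zero columns; N encodes as a zero column and doubles as
the masking symbol for ablation.

## Training regime

Adam (lr 0.001), batch 128, weighted binary cross-entropy with class weights
w_c = N/(2·N_c), L1+L2 penalties (λ = 1e−6) on weight matrices (not biases),
Xavier-uniform init, up to 100 epochs with early stopping (patience 10 on
validation loss) and learning-rate decay (×0.5 after 5 stagnant epochs).
The IC majority is downsampled to 4.33× the EC count before a stratified
0.8/0.1/0.1 split — that ratio reproduces the retained imbalance of the
motivating study's data inventory even after its stated downsampling; the
tension between "downsampled" and a still-imbalanced table is resolved by
making the ratio a config knob. Reported metrics: rank-statistic AUROC (ties
half-credit), step-interpolated AUPRC, and confusion metrics at 0.5 or at a
target specificity (smallest threshold achieving it on the negatives), with
an optional percentile bootstrap ROC band.

SVM probabilities are the sigmoid of the margin (uncalibrated), consistent
with the sigmoid-output convention of the deep families.

## Interpretation

* **Confidence tiers**: ECX = true EC with probability > 0.95; ICX = true IC
  with probability < 0.05. Mispredicted sequences never enter a tier.
* **Redundancy purge**: greedy scan dropping any sequence whose best local
  alignment against a retained one scores ≥ 50 (match +5, mismatch −4, gaps
  −10 first base / −1 extension via Biopython's aligner). The threshold is
  fixed by the protocol being reproduced; the scorer approximates that
  BLAST-like scale and is configurable.
* **Binned enrichment**: items sorted by a continuous profile are cut into
  equally populated bins (ties by stable input order, sizes differ ≤ 1);
  each bin's motif count is scored by exact hypergeometric tails, reported
  as signed log10 p (positive = over-represented); the global association is
  the mutual information (bits) between motif flag and bin index, calibrated
  as a z-score over profile permutations; per-bin significance is Bonferroni
  across bins at 0.05 (the correction is a package choice — the source
  heatmaps mark significance without naming one).
* **Ablation**: mask (N columns) or remove (delete and re-pad) every motif
  match; report mean probability before/after and the fraction of
  previously-ECX sequences demoted, under both the strict (≤ 0.95) and
  decision-boundary (< 0.5) readings, since either could be meant by "no
  longer classified as ECX".
* **Saliency**: gradient × input on the pre-sigmoid output, summed over
  channels. This substitutes for reference-based attribution tools; on the
  planted fixtures motif positions out-attribute background in aggregate,
  which is the only property asserted.

## Design

A first-order Markov model (add-one smoothing) over dinucleotides drives
generation. Lengths follow a discretized normal (sd 4) on [18, 50]; because
truncation inflates the realized mean (naively ~20.8 for a target of 20),
the location parameter is solved by bisection so the realized mean equals
the target (20 nt by default, or the data mean when fitting). REX/RIX
selection takes the top/bottom n by probability around the 0.5 decision
boundary. Guided mutagenesis scores all 3L single substitutions first and
falls back to two-position changes (exhaustive when 9·C(L,2) fits the
budget, else a seeded subsample), returning the minimal-probability
qualifying mutant or an explicit failure result. Count enrichment is a
simplified normalized log2 fold change (total-count size factors by default,
median-of-ratios or none optionally) standing in for a negative-binomial GLM
fit, and the ECX-vs-MUT comparison uses the one-sided exact Wilcoxon
signed-rank test (enumeration for n ≤ 25, normal approximation with
continuity correction above, zeros dropped).

## RBP signal enrichment

Replicate tracks merge by per-base maximum. Signal is extracted either over
peak∩region bases (optionally zero-filled — the zero-inflated variant) or
over the union of EC-extreme and IC-extreme regions, the default, which
avoids the zero inflation that makes the rank-sum test mean-sensitive. The
test is one-sided Mann-Whitney (EV greater), exact for tie-free samples with
min(n,m) ≤ 8, BH-corrected across the protein panel at 0.05. Intra-protein
features (region counts, overlap lengths, signal sums, means) get outlier
calls by robust z (0.6745·|x−median|/MAD > 3.5), parametric z (>3), and
percentile rank (>0.99) — cut-offs are package defaults. Tracks are dense
per-chromosome arrays: appropriate for the desk-scale fixtures the package
tests on, not whole genomes (bigWig ingestion is out of scope; bedGraph and
wiggle are the interchange formats).

## Synthetic benchmark (what a green test establishes)

The generator states one world: 5,000 EC / 20,000 IC sequences (the ~1:4
retained imbalance at desk scale), uniform dinucleotide background, lengths
mean 20 in [18, 50], and three planted motifs — CCUGGC at 0.60 EC / 0.05 IC
(fixed by the acceptance protocol), GAGUC at 0.40/0.05 and [ACU]AG[GU][GU]
at 0.30/0.05 (secondary signals, set once to mirror a motif hierarchy).
Motifs overwrite background letters at a uniform offset so length carries no
label information; the truth table records every insertion that survives
overwriting. Counts are negative-binomial (variance μ + αμ²; α → 0 recovers
Poisson, checked) with a 2^effect EV/CM boost for EC records and extra CM
dispersion; signal fixtures plant one EC-boosted protein among nulls on a
toy chromosome.

The benchmark emulates class imbalance, motif enrichment, count
overdispersion and signal bias — it does **not** emulate biotype structure
(miRNA hairpins, tRNA fragments), positional motif preferences, shared
genomic origins between near-duplicate reads, or technical artifacts of
library preparation. A green planted-grammar test therefore establishes
that the pipeline recovers a grammar of this statistical shape, not that
any particular biological motif is real.

## Numerical choices and limitations

* Nussinov ties resolve toward the unpaired branch and the smallest split
  point, making folds deterministic; minimum hairpin length is 3 for both
  backends.
* The exact/asymptotic switch points (Wilcoxon n ≤ 25; Mann-Whitney
  min(n,m) ≤ 8 without ties) follow the conventional exact-computability
  limits and are verified against full enumeration in the tests.
* All stochastic stages draw from generators derived from one global seed
  plus a stage name; identical config+seed reproduces identical outputs,
  including training (the autodiff engine is deterministic on CPU).
* Model checkpoints are self-describing `.npz` containers (architecture
  JSON + flat float64 arrays), reloadable without the training code path.
* The deep models are CPU-bound numpy: adequate for the bundled benchmark
  scale (minutes), not for corpus-scale retraining (millions of reads).
* Classical SVM training is O(n²)–O(n³) in sample count; it is intended for
  the tabular-feature comparison at desk scale.
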
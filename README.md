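# secgram

**secgram** is a toolkit for learning and dissecting the *cis*-regulatory
grammar that routes small RNAs (18–50 nt) out of cells. Extracellular RNA
content is poorly predicted by intracellular abundance, which points to
sequence signals — RNA-binding-protein sites such as YBX1's CCUGGC — that
mark transcripts for sorting into extracellular vesicles (EV) or conditioned
medium (CM). The package is written for computational biologists who want to
train secretion classifiers on extracellular (EC) vs intracellular (IC)
small-RNA sets, interrogate what the models learned, design synthetic
secreted/retained sequences, and test RNA-binding proteins for EC-biased
binding signal.

## What it does

| stage | module | summary |
|---|---|---|
| curate | `secgram.curation` | shared-label resolution (EC wins), 18–50 nt / no-N filter, duplicate+substring collapse, DUST low-complexity removal, attrition report |
| featurize | `secgram.features` | dot-bracket folding (ViennaRNA or built-in Nussinov), structural elements f/t/s/i/m/h, 8-term notation, k-mer frequencies (k = 1–5, 7) over four representations, energy/length features, one-hot encoding |
| model | `secgram.models` | sklearn-style estimators: `GRUSecretionClassifier`, `LSTMSecretionClassifier`, `CNNSecretionClassifier` (numpy autodiff, Adam, weighted cross-entropy, L1+L2, early stopping) plus SVM and random-forest wrappers; IC downsampling, stratified 0.8/0.1/0.1 splits, AUROC/AUPRC/threshold-at-specificity evaluation with bootstrap ROC bands |
| interpret | `secgram.interpret` | ECX/ICX confidence tiers (p > 0.95 / p < 0.05), redundancy purge (local-alignment score ≥ 50), equally-populated-bin hypergeometric/MI motif enrichment with shuffle z-scores, motif mask/remove ablation, gradient×input saliency |
| design | `secgram.design` | dinucleotide-matched sequence generation (mean 20 nt), REX/RIX selection, guided 1–2 position mutagenesis, normalized log2 EV/IC + CM/IC enrichment, exact Wilcoxon signed-rank testing |
| RBP | `secgram.rbp` | replicate-max signal tracks, peak/union region extraction, one-sided Mann-Whitney (EV > IC) with BH correction, intra-protein features and MAD/z/percentile outlier calls |
| benchmark | `secgram.synthbench` | planted-grammar generator (motifs CCUGGC, GAGUC, [ACU]AG[GU][GU]; 1:4 class imbalance; NB counts; EC-boosted signal tracks) so the whole pipeline is testable offline |

A `secgram` CLI wraps each stage (`simulate`, `curate`, `featurize`,
`train`, `predict`, `evaluate`, `interpret`, `ablate`, `design`, `mutate`,
`enrich-counts`, `enrich-rbp`); every run writes a seed-stamped JSON log.

## Worked example

```python
import numpy as np
from secgram import curation, models, synthbench
from secgram.interpret import bin_enrichment_profile, motif_ablation

# a planted-grammar benchmark: 5,000 EC / 20,000 IC, CCUGGC at 60% vs 5%
spec = synthbench.BenchmarkSpec(seed=1)
records, truth = synthbench.make_sequence_dataset(spec)
kept, report = curation.curate(records)

clf = models.GRUSecretionClassifier(hidden_size=64, n_layers=2, random_state=1)
model, hist = models.train(clf, [r.sequence for r in kept],
                           [r.label for r in kept],
                           models.TrainConfig(seed=1, max_epochs=30))

test = [kept[hist["kept_indices"][i]] for i in hist["test_idx"]]
probs = model.secretion_probability([r.sequence for r in test])
labels = [r.label for r in test]
print(models.evaluate(probs, labels).as_dict())

flags = ["CCTGGC" in r.sequence for r in test]
prof = bin_enrichment_profile(probs, flags, n_bins=9, n_shuffles=500, seed=1)
print(f"MI = {prof.mi_bits:.3f} bits, shuffle z = {prof.z_score:.1f}")
```

Output from this exact run:

```
{'auroc': 0.873274, 'auprc': 0.7072658422452446, 'sensitivity': 0.81,
 'specificity': 0.82, 'accuracy': 0.818, 'tp': 405, 'fp': 360,
 'tn': 1640, 'fn': 95, 'threshold': 0.5}
MI = 0.348 bits, shuffle z = 319.9
```

Held-out AUROC 0.87 against a Bayes ceiling of roughly 0.9 for this world
(motifs are planted in only ~83% of EC and ~14% of IC sequences), and the
planted motif's association with the model's probabilities sits hundreds of
standard deviations above the permutation null — the model recovered the
planted grammar. Masking CCUGGC in confidently-predicted carriers collapses their
secretion probabilities (see `motif_ablation`), mirroring how motif ablation
is used to attribute model behavior to specific sites.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline end to end at a reduced scale — simulate → curate →
train the GRU → evaluate → motif-enrichment profile → ablation → REX/RIX
design → RBP enrichment panel — printing each stage's summary numbers and
writing the results JSON. The property-level guarantees (oracle equivalence
of the recurrences, k-mer counting and folding; exact small-sample test
branches; planted-grammar recovery; null-grammar calibration) live in
`tests/test_acceptance.py`.

## Documentation

`docs/methods.md` describes the model, the curation and enrichment
statistics, the synthetic benchmark's stated world and its limits, and the
numerical choices (tolerances, tie-breaks, exact/asymptotic switch points).
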
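# ppibench

Bias-aware benchmarking of protein–protein interaction (PPI) predictors.

## The problem

Known PPIs come from a hub-heavy, scale-free network: a few proteins appear
in thousands of curated interactions while most appear in a handful.
Negative examples, by contrast, have to be random protein pairs (failed
experiments do not prove non-interaction), and random pairs use every
protein at nearly the same rate.  A classifier can therefore reach high
accuracy on the usual 50 %-positive benchmark simply by learning *which
proteins* are over-represented in the positive class — a membership bias
that is worthless for proteome-wide prediction, where interacting pairs are
rare (roughly 0.3–1.5 % of all pairs) and every protein meets every other.

`ppibench` builds evaluation datasets that expose this failure mode and
provides the machinery to score any pair predictor against it:

* **Dataset construction** at realistic class ratios (1:1, 1:4, 1:9, 1:332)
  under two regimes: *Full* (pairs sampled from all proteins, only pair-level
  train/test disjointness — the literature default) and *Held-Out*
  (proteins split into 6 bins, 1–2 bins reserved for testing so no test
  protein is ever seen in training; the protein-disjoint "C3" regime).
* **Sequence descriptors** behind one encoder registry: amino-acid /
  dipeptide composition, conjoint triad, auto covariance,
  composition–transition–distribution (CTD), Moran / Geary / Moreau–Broto
  autocorrelation, pseudo amino acid composition, quasi-sequence-order,
  grouped-weight encoding (EBGW), local descriptors (LD10 / MLD / MCD),
  multivariate mutual information, chaos-game representation, wavelet
  summaries of property signals, one-hot, BLOSUM62, PSSM readers with
  BLOSUM62 fallback, and residue-level skip-gram embeddings.
* **Annotation features**: Gene Ontology information content and semantic
  similarity (Resnik, Lin, Jiang–Conrath and others), grid aggregations
  (average / max / sum / product / best-matching-average), domain-pair and
  GO-pair interaction frequencies with noisy-OR combination, binary
  domain-sum and up-to-LCA ontology vectors — plus the three *source modes*
  (all / non-test / held-out interactions) that audit and remove test-set
  leakage from interaction-derived features.
* **Control models** built from deliberately *illogical* features: Count
  Bias (positive-minus-negative training appearances of each protein),
  sequence-similarity-weighted bias, and 500-dimensional random vectors fed
  to a random forest or a shared-layer feedforward net.  Accurate methods
  should beat these; on held-out data the controls collapse to chance by
  construction.
* **Rare-class metrics** with exact tie handling: accuracy
  (ties predict negative), AUC (half credit for ties), average precision and
  precision at 3 % recall (tied blocks treated atomically), proteome-wide
  hub cumulative-TP curves, and a missing-annotation audit.
* **Synthetic fixtures**: seeded generators for random proteomes,
  preferential-attachment interactomes, toy ontologies and domain
  assignments with a planted interacting-domain-pair signal, so the whole
  framework builds and tests without any download.

## Worked example

Count Bias cannot score a protein it never saw in training, so on a
protein-disjoint split every pair scores 0 and the tie rules pin its metrics
at chance:

```python
from ppibench import (SynthSpec, generate_proteome,
                      generate_scalefree_interactome, assign_heldout_bins,
                      HeldOutConfig, RatioSpec, build_heldout_datasets,
                      ScoredPairs, accuracy, roc_auc, average_precision)
from ppibench.baseline_models import CountBiasModel

spec = SynthSpec(n_proteins=2000, n_interactions=10000, master_seed=1)
proteome = generate_proteome(spec)
interactions = generate_scalefree_interactome(proteome, spec)

bins = assign_heldout_bins(proteome, n_bins=6, rng_seed=101)
cfg = HeldOutConfig(6, frozenset({0}), bins.bin_assignment)
train, test = build_heldout_datasets(
    proteome, interactions, cfg,
    RatioSpec(0.5, 2000), RatioSpec(0.5, "all"), rng_seed=201)

model = CountBiasModel().fit(train)
sp = ScoredPairs(test.pairs, test.labels, model.predict_scores(test.pairs))
print(accuracy(sp), roc_auc(sp))
```

prints

```
50.0 50.0
```

— exactly chance on the balanced held-out test set, even though the same
model scores far above chance on Full-regime data from the same hub-heavy
network (there, hub membership alone separates the classes).  On the 1:9
and 1:332 held-out test sets its average precision is exactly the
prevalence, 10.0 and 0.3.

The same workflow is available from the shell:

```bash
ppibench --out runs/demo --seed 1 synth build-data featurize train evaluate report
```

which writes datasets, feature matrices, per-model score files and a
summary table (`runs/demo/report.tsv`) with accuracy/AUC on the balanced
sets and precision@3 % / average precision on the imbalanced ones.

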
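# Methods

## The benchmark model

`ppibench` treats PPI prediction as binary classification of unordered
protein pairs.  Positive pairs come from a curated interaction set; negative
pairs are random non-interacting pairs, reflecting that non-interaction is
not experimentally certifiable.  Two facts drive the design:

1. the positive network is scale-free (hubs appear in many positives) while
   random negatives use proteins near-uniformly, so per-protein membership
   statistics separate the classes without any pairwise information;
2. true interacting pairs are rare (~0.3 % of pairs), so accuracy and AUC on
   balanced test sets say little about proteome-wide usefulness.

The framework therefore (a) builds test sets at positive fractions 50 %,
10 % and 0.3 %; (b) contrasts the *Full* regime (pair-level train/test
disjointness only) with the *Held-Out* regime (proteins split into
`n_bins = 6` near-equal random bins, 1 or 2 bins — 21 configurations —
reserved exclusively for test pairs, both endpoints held out); and
(c) ships control models whose only input is membership bias, as the floor
any genuine predictor must clear.

### Dataset construction

Ratios are realized as `n_neg = round(n_pos * (1 - f) / f)` when a total is
not given.  Balanced and 1:9 held-out test sets use *all* positive pairs
available inside the held bins; 0.3 % held-out test sets subsample positives
(a seeded capped draw, default one tenth of the available positives) to keep
the implied negative counts tractable.  Held-out test pairs require **both**
endpoints in held bins, and held-out negatives are sampled among held
proteins only — the strictest (fully protein-disjoint) reading.  Full-regime
negatives are sampled over all proteins with known positives and
already-drawn pairs excluded.  The 10 % and 0.3 % test sets share one
20 %-positive training set; balanced test sets pair with balanced training
sets.  All builders are deterministic functions of an explicit seed, and
bin remainders go to the lowest-index bins.

### Sequence descriptors

All encoders produce fixed-dimension vectors; pair features concatenate the
two protein vectors with the lexicographically smaller protein identifier
first, which makes every downstream model orientation-invariant by
construction.  Physicochemical properties (hydrophobicity, hydrophilicity,
polarity, polarizability, charge, solvent-accessible surface area, van der
Waals volume) are standardized to zero mean and unit variance over the 20
amino acids before use.  Non-standard letters (B, J, O, U, X, Z) contribute
zero counts to compositional descriptors and are dropped from property
signals.

Notable parameter choices (all overridable through `EncoderConfig`):

* auto covariance / autocorrelation maximum lag `g = 30` (admissible because
  sequences of ≤ 30 residues are filtered out);
* pseudo amino acid composition: λ = 15, weight w = 0.05, with the classic
  hydrophobicity / hydrophilicity / side-chain-mass property triple;
* quasi-sequence-order: maxlag 30, weight 0.1.  The residue distance matrix
  is an explicit argument; the default is the Euclidean distance between
  standardized 7-property vectors, a documented stand-in for any published
  20×20 distance table the user prefers to supply;
* EBGW: 10 prefix groups over three binary projections of the four
  charge/polarity residue classes;
* local descriptors emit 7 C + 21 T + 35 D = 63 values per region; LD10 uses
  the 4 quarters, 3 adjacent-pair spans, 2 three-quarter spans and the
  central half (630 dims); MLD uses binary splits of depth 0–3 and MCD all
  15 non-empty quarter subsets (945 dims each);
* multivariate mutual information works on the 7-class alphabet with
  adjacent unordered 2-mers and 3-mers.  Terms use the 0·log 0 = 0
  convention rather than additive smoothing: smoothing would make the
  degenerate single-symbol sequence score non-zero, breaking the exact
  homopolymer identity the tests assert;
* wavelet summaries default to the db2 wavelet at 3 levels: the shortest
  admissible sequence (31 residues) supports exactly 3 clean decomposition
  levels for a 4-tap filter, whereas 4 levels of a longer filter would
  over-decompose short sequences;
* the weighted skip-sequential conjoint-triad variant counts equally spaced
  triples (i, i+g, i+2g) for gaps g = 1..3 with weight 1/g (gap 1 recovers
  the plain conjoint triad); the exact weighting is a config knob;
* skip-gram embeddings are trained on single-residue tokens (window 5,
  dimension 20, negative sampling) by a small numpy SGNS trainer — the
  vocabulary is only the 20 residues, so this is tiny and exactly
  reproducible under a fixed seed;
* PSSM descriptors (bi-gram pooling, DCT pooling) read PSI-BLAST ASCII
  matrices; a missing matrix falls back to the BLOSUM62 row encoding.

Dataset-level normalization (min–max to [0, 1] or [−1, 1]) is fit on
training rows only; test values outside the fitted range are clipped.

### Annotation features and de-biasing

Term information content is `−ln p(term)` with annotations propagated to all
ancestors and probabilities computed per namespace (every namespace root has
IC 0).  Terms never observed in the corpus have unbounded IC; their Lin and
Jiang–Conrath similarity to anything but themselves is defined as 0.
Pair-level features aggregate a grid of term-pair scores by average, max,
sum, product or best-matching-average; an empty grid (missing annotation on
either side) scores 0 everywhere, so sequence- and annotation-based models
share datasets.

Interaction-derived features estimate the probability that an annotation
pair belongs to an interacting protein pair.  Counts use `(k + 1) / (n + 2)`
smoothing so that a single (possibly test-set) interaction cannot push a
rare annotation pair to probability 1.  The opportunity denominator `n`
counts labeled training pairs in which the two annotations face each other
across the pair — a documented choice, since no canonical denominator
exists.  Three source modes support leakage audits: `all` interactions,
`non_test` (interactions that are test pairs are dropped) and `held_out`
(interactions touching any held-out protein are dropped); counts are
monotone non-increasing across that sequence by construction.  "Level 2"
GO terms are terms at shortest-path depth 2 from their namespace root;
deeper annotations map up to all their level-2 ancestors, shallower ones
drop out.  The up-to-LCA binary vector marks, for each cross-protein
annotation pair, every term on an ascending path from either annotation up
to and including a deepest common ancestor (inclusive reading).

### Control models and classifier harness

Count Bias scores a pair as the sum of each protein's positive-minus-
negative training appearances; unseen proteins contribute 0.  Sequence
Similarity Bias replaces a protein's own counts with a similarity-weighted
average over its ≤ 5 most similar training proteins; the default similarity
is the cosine between l2-normalized 3-mer count vectors (fast and
alignment-free; an alignment-based function can be passed instead).  The
combined variant takes `max(sequence similarity, accession-overlap Jaccard)`
as the neighbour weight.  Random-vector controls assign each protein a fixed
seeded 500-dimensional normal vector; pairs are classified by a random
forest or a feedforward net whose two input halves pass through shared dense
ReLU layers (64 then 32 units) before concatenation and a sigmoid output,
trained with minibatch gradient descent under a decaying learning rate.

The generic harness fits logistic regression, random forests, gradient
boosting, linear margin classifiers (scored through a logistic link),
feedforward nets, or a PCA-rotation decision-tree ensemble (rotation
forest, implemented from the standard description).  No class weighting is
applied at any ratio: models are evaluated as published.

### Metrics and tie rules

* accuracy: predict positive iff score > 0.5; ties predict negative;
* AUC: Mann–Whitney statistic with half credit for tied scores;
* average precision: precision-weighted recall increments over
  descending-score *tie blocks* (a tied block is one step);
* precision at r % recall: precision of the smallest prefix whose recall
  reaches r, tied blocks included atomically.

These rules are chosen so a zero-information (constant) scorer lands
*exactly* on the analytic baselines — 50 % accuracy on balanced data, AUC
50, average precision and precision@r equal to the prevalence — instead of
a seed-dependent neighbourhood of them.  That exactness is what makes the
held-out control rows a calibration point rather than a noisy estimate.
Hub curves sort each hub's candidate partners by descending score, record
cumulative true positives at each false-positive count, and average across
hubs pointwise.  The missing-data audit reports, per dataset × class, the
percentage of pairs where either protein lacks a given annotation family.

## Synthetic study conditions

The generators emulate the statistical structure the benchmark's argument
rests on, not biological realism:

* proteomes are i.i.d. uniform sequences over the 20 letters, lengths
  31–120 (2,000 proteins by default);
* interactomes grow by preferential attachment over the fixed protein set
  (attachment probability ∝ degree + 1), seeded with a small uniform random
  matching (m/100 edges) so attachment dominates; at the default 2,000
  proteins / 10,000 interactions the maximum degree is ~7× the mean —
  hub-heavy, though far milder than real curated interactomes;
* domain assignments draw ~2 domains per protein from a 30-domain
  vocabulary split across three databases; 5 planted domain pairs are
  declared interacting and the interactome is regenerated with candidate
  edges carrying a planted pair accepted 10× more readily, producing an
  enrichment of planted pairs among positives that pairwise
  (domain-derived) features can recover on held-out proteins;
* a toy single-namespace ontology (depth 3, branching 3, occasional second
  parents) supplies GO-style annotations, with 30 % of proteins left
  unannotated to emulate real coverage gaps.

What passing tests on these data do show: the *mechanisms* — membership
bias inflating Full-regime scores, its exact collapse on protein-disjoint
data, leakage through interaction-derived features, recovery of genuinely
pairwise signal.  What they do not show: absolute performance on real
corpora, which depends on sequence homology, annotation depth and curation
biases the generators deliberately omit (no sequence-identity redundancy
filtering is performed, mirroring the benchmark's gene-level mapping).

## Problem sizes and numerical choices

The shipped test-and-calibration runs use 800–2,000 proteins and
4,000–10,000 interactions — large enough for the hub structure and the
exact baselines, small enough that the full suite runs in well under a
minute per module.  The acceptance run uses 2,000 proteins / 10,000
interactions, one held bin of six, 2,000 training positives per regime, and
averages the random-vector net over 5 seeds.  Degenerate inputs are defined
explicitly: zero-variance property signals give 0 for Moran/Geary,
empty annotation grids give 0, constant feature columns normalize to 0,
and isoform-length ties collapse to the lexicographically smallest
accession.  All randomness flows from explicit integer seeds; master seeds
derive sub-seeds by fixed offsets.

## Known limitations

* PSSMs are read, never computed: profile search against a reference
  database is out of scope, and the BLOSUM62 fallback stands in when no
  matrix is supplied.
* Deep sequence models (CNN/LSTM families) are representable only through
  user-supplied encoders registered into the harness.
* The Full-regime reference sizes (125,000-pair cross-validation sets,
  500,000-pair 0.3 % test sets) are built at a configurable scale factor;
  the default scale 0.01 keeps desk-scale runs fast while preserving every
  ratio exactly.
* Semantic-similarity measure sets beyond the shipped ten, alternative
  pair-probability denominators and alternative conjoint-triad weightings
  are config knobs, not empirically tuned defaults.
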
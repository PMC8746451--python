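"""Bias-control baselines and the generic classifier harness.

The control models deliberately use *illogical* features — how often each
protein appears in positive versus negative training pairs, the same counts
borrowed from sequence-similar neighbours, or plain random vectors — so that
any predictor claiming to capture pairwise compatibility can be compared
against what protein-membership bias alone achieves.  On protein-disjoint
(held-out) test data these controls collapse to chance by construction,
which is exactly the calibration point the benchmark relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from sklearn.decomposition import PCA
from sklearn.ensemble import (
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import normalize as sk_normalize
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .dataset_builder import PairDataset
from .io_formats import Proteome, STANDARD_AMINO_ACIDS

AA_INDEX = {a: i for i, a in enumerate(STANDARD_AMINO_ACIDS)}


# ---------------------------------------------------------------------------
# Count Bias
# ---------------------------------------------------------------------------

@dataclass
class ProteinBiasTable:
    """Per-protein (positive, negative) training appearance counts."""

    counts: dict[str, tuple[int, int]]

    def bias(self, protein_id: str) -> float:
        pos, neg = self.counts.get(protein_id, (0, 0))
        return float(pos - neg)

    def proteins(self) -> list[str]:
        return sorted(self.counts)


def fit_count_bias(train: PairDataset) -> ProteinBiasTable:
    """Count positive/negative training appearances of each protein."""
    counts: dict[str, list[int]] = {}
    for (a, b), y in zip(train.pairs, train.labels):
        for p in (a, b):
            c = counts.setdefault(p, [0, 0])
            c[0 if y == 1 else 1] += 1
    return ProteinBiasTable({p: (c[0], c[1]) for p, c in counts.items()})


def score_count_bias(table: ProteinBiasTable, pair: tuple[str, str]) -> float:
    """score(a, b) = bias(a) + bias(b); unseen proteins contribute 0."""
    a, b = pair
    return table.bias(a) + table.bias(b)


class CountBiasModel:
    """Harness-compatible wrapper around the count-bias table."""

    def fit(self, train: PairDataset) -> "CountBiasModel":
        self.table = fit_count_bias(train)
        return self

    def predict_scores(self, pairs) -> np.ndarray:
        return np.array([score_count_bias(self.table, p) for p in pairs])


# ---------------------------------------------------------------------------
# Sequence-similarity bias
# ---------------------------------------------------------------------------

def kmer_count_matrix(sequences: list[str], k: int = 3) -> csr_matrix:
    """Sparse k-mer count vectors (rows l2-normalized for cosine use)."""
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    for seq in sequences:
        counts: dict[int, float] = {}
        for i in range(len(seq) - k + 1):
            code = 0
            ok = True
            for j in range(k):
                idx = AA_INDEX.get(seq[i + j])
                if idx is None:
                    ok = False
                    break
                code = code * 20 + idx
            if ok:
                counts[code] = counts.get(code, 0.0) + 1.0
        indices.extend(counts.keys())
        data.extend(counts.values())
        indptr.append(len(indices))
    mat = csr_matrix((data, indices, indptr),
                     shape=(len(sequences), 20 ** k))
    return sk_normalize(mat, norm="l2", copy=False)


def kmer_cosine_similarity(proteome: Proteome, k: int = 3):
    """similarity_fn(a, b) -> cosine similarity of k-mer count vectors.

    The default alignment-free sequence similarity for the similarity-bias
    controls; an alignment-based function can be dropped in behind the same
    interface.
    """
    ids = proteome.ids()
    mat = kmer_count_matrix([proteome.sequence(p) for p in ids], k)
    pos = {p: i for i, p in enumerate(ids)}

    def sim(a: str, b: str) -> float:
        ra, rb = mat[pos[a]], mat[pos[b]]
        return float(ra.multiply(rb).sum())

    sim.matrix = mat          # type: ignore[attr-defined]
    sim.index = pos           # type: ignore[attr-defined]
    return sim


class SeqSimBiasModel:
    """Count bias borrowed from the k most sequence-similar training proteins.

    Per query protein the up-to-k most similar training proteins are found
    and their biases combined by a similarity-weighted average; the pair
    score is the sum of the two protein scores.
    """

    def __init__(self, proteome: Proteome, k: int = 5, kmer: int = 3):
        self.proteome = proteome
        self.k = k
        self.kmer = kmer

    def fit(self, train: PairDataset) -> "SeqSimBiasModel":
        self.table = fit_count_bias(train)
        self.train_ids = sorted(train.proteins())
        self._train_mat = kmer_count_matrix(
            [self.proteome.sequence(p) for p in self.train_ids], self.kmer)
        return self

    def _neighbour_weights(self, pid: str) -> list[tuple[str, float]]:
        """(training protein, weight) for the top-k neighbours of pid."""
        q = kmer_count_matrix([self.proteome.sequence(pid)], self.kmer)
        sims = np.asarray((self._train_mat @ q.T).todense()).ravel()
        order = np.argsort(-sims, kind="stable")[:self.k]
        return [(self.train_ids[i], float(sims[i])) for i in order]

    def protein_score(self, pid: str) -> float:
        if self.k == 0 or not self.train_ids:
            return 0.0
        neigh = self._neighbour_weights(pid)
        wsum = sum(w for _, w in neigh)
        if wsum <= 0:
            return 0.0
        return sum(w * self.table.bias(p) for p, w in neigh) / wsum

    def predict_scores(self, pairs) -> np.ndarray:
        cache: dict[str, float] = {}

        def ps(pid: str) -> float:
            if pid not in cache:
                cache[pid] = self.protein_score(pid)
            return cache[pid]

        return np.array([ps(a) + ps(b) for a, b in pairs])


class SeqSimProtBiasModel(SeqSimBiasModel):
    """Similarity-bias variant whose neighbour weights also credit genes that
    share protein accessions: weight = max(sequence similarity, Jaccard
    overlap of the two genes' accession sets).  Without a multiplicity map it
    degrades to plain sequence-similarity bias."""

    def __init__(self, proteome: Proteome,
                 gene_accessions: dict[str, set[str]] | None = None,
                 k: int = 5, kmer: int = 3):
        super().__init__(proteome, k=k, kmer=kmer)
        if gene_accessions is None:
            import logging
            logging.getLogger("ppibench").warning(
                "no gene->accession multiplicity map; falling back to "
                "sequence-similarity bias")
        self.gene_accessions = gene_accessions or {}

    def _overlap(self, a: str, b: str) -> float:
        ga = self.proteome[a].gene_id if a in self.proteome else a
        gb = self.proteome[b].gene_id if b in self.proteome else b
        sa = self.gene_accessions.get(ga, set())
        sb = self.gene_accessions.get(gb, set())
        union = sa | sb
        return len(sa & sb) / len(union) if union else 0.0

    def _neighbour_weights(self, pid: str) -> list[tuple[str, float]]:
        q = kmer_count_matrix([self.proteome.sequence(pid)], self.kmer)
        sims = np.asarray((self._train_mat @ q.T).todense()).ravel()
        combined = np.array([max(float(s), self._overlap(pid, t))
                             for s, t in zip(sims, self.train_ids)])
        order = np.argsort(-combined, kind="stable")[:self.k]
        return [(self.train_ids[i], float(combined[i])) for i in order]


# ---------------------------------------------------------------------------
# Random-vector controls
# ---------------------------------------------------------------------------

@dataclass
class RandomVectorTable:
    """Fixed random vector per protein (default 500 dims)."""

    vectors: dict[str, np.ndarray]
    dim: int = 500

    def get(self, pid: str) -> np.ndarray:
        if pid not in self.vectors:
            raise KeyError(pid)
        return self.vectors[pid]

    def pair_vector(self, pair: tuple[str, str]) -> np.ndarray:
        a, b = sorted(pair)
        return np.concatenate([self.get(a), self.get(b)])


def random_vector_features(protein_ids, dim: int = 500,
                           seed: int = 0) -> RandomVectorTable:
    """Draw one standard-normal vector per protein; deterministic under seed
    (proteins are visited in sorted order)."""
    rng = np.random.default_rng(seed)
    vectors = {pid: rng.standard_normal(dim) for pid in sorted(protein_ids)}
    return RandomVectorTable(vectors=vectors, dim=dim)


# ---------------------------------------------------------------------------
# Shared-layer feedforward network (numpy)
# ---------------------------------------------------------------------------

class SharedLayerNet:
    """Feedforward pair classifier with per-protein shared layers.

    Each protein's half of the input passes through the same two dense ReLU
    layers; the two hidden representations are concatenated and mapped by a
    final sigmoid layer.  Trained with minibatch gradient descent on binary
    cross entropy under a decaying learning rate.
    """

    def __init__(self, protein_dim: int, hidden: tuple[int, int] = (64, 32),
                 lr: float = 0.05, epochs: int = 10, batch_size: int = 128,
                 seed: int = 0):
        self.protein_dim = protein_dim
        self.hidden = hidden
        self.lr, self.epochs, self.batch_size = lr, epochs, batch_size
        self.seed = seed

    def _init_params(self, rng: np.random.Generator) -> None:
        d, (h1, h2) = self.protein_dim, self.hidden
        def glorot(nin, nout):
            return rng.normal(0.0, np.sqrt(2.0 / (nin + nout)), (nin, nout))
        self.W1, self.b1 = glorot(d, h1), np.zeros(h1)
        self.W2, self.b2 = glorot(h1, h2), np.zeros(h2)
        self.W3, self.b3 = glorot(2 * h2, 1), np.zeros(1)

    def _shared(self, X_half: np.ndarray):
        z1 = X_half @ self.W1 + self.b1
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ self.W2 + self.b2
        a2 = np.maximum(z2, 0.0)
        return a1, a2

    def _forward(self, X: np.ndarray):
        d = self.protein_dim
        a1a, a2a = self._shared(X[:, :d])
        a1b, a2b = self._shared(X[:, d:])
        h = np.concatenate([a2a, a2b], axis=1)
        logit = (h @ self.W3 + self.b3).ravel()
        p = 1.0 / (1.0 + np.exp(-np.clip(logit, -30, 30)))
        return p, (a1a, a2a, a1b, a2b, h)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SharedLayerNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[1] != 2 * self.protein_dim:
            raise ValueError("feature width must be 2 * protein_dim")
        rng = np.random.default_rng(self.seed)
        self._init_params(rng)
        n = len(X)
        d = self.protein_dim
        for epoch in range(self.epochs):
            lr = self.lr / (1.0 + 0.5 * epoch)   # decaying learning rate
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], y[idx]
                p, (a1a, a2a, a1b, a2b, h) = self._forward(xb)
                m = len(idx)
                dlogit = (p - yb) / m
                gW3 = h.T @ dlogit[:, None]
                gb3 = dlogit.sum(keepdims=True)
                dh = dlogit[:, None] @ self.W3.T
                h2 = self.hidden[1]
                # backprop through both shared towers, accumulating grads
                gW1 = np.zeros_like(self.W1); gb1 = np.zeros_like(self.b1)
                gW2 = np.zeros_like(self.W2); gb2 = np.zeros_like(self.b2)
                for half, (a1, a2, dh_part) in enumerate(
                        [(a1a, a2a, dh[:, :h2]), (a1b, a2b, dh[:, h2:])]):
                    xh = xb[:, :d] if half == 0 else xb[:, d:]
                    da2 = dh_part * (a2 > 0)
                    gW2 += a1.T @ da2
                    gb2 += da2.sum(axis=0)
                    da1 = (da2 @ self.W2.T) * (a1 > 0)
                    gW1 += xh.T @ da1
                    gb1 += da1.sum(axis=0)
                self.W3 -= lr * gW3; self.b3 -= lr * gb3
                self.W2 -= lr * gW2; self.b2 -= lr * gb2
                self.W1 -= lr * gW1; self.b1 -= lr * gb1
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p, _ = self._forward(np.asarray(X, dtype=float))
        return np.column_stack([1.0 - p, p])


class RandomVectorModel:
    """Random-vector control: per-protein seeded random vectors classified by
    a random forest or the shared-layer feedforward net."""

    def __init__(self, family: str = "feedforward_net", dim: int = 500,
                 seed: int = 0, **kwargs):
        self.family, self.dim, self.seed = family, dim, seed
        self.kwargs = kwargs

    def fit(self, train: PairDataset, protein_ids=None) -> "RandomVectorModel":
        ids = set(protein_ids) if protein_ids else train.proteins()
        self.table = random_vector_features(ids, dim=self.dim, seed=self.seed)
        X = np.stack([self.table.pair_vector(p) for p in train.pairs])
        if self.family == "feedforward_net":
            self._clf = SharedLayerNet(protein_dim=self.dim, seed=self.seed,
                                       **self.kwargs)
            self._clf.fit(X, train.labels)
        elif self.family == "random_forest":
            self._clf = RandomForestClassifier(
                n_estimators=self.kwargs.get("n_estimators", 100),
                random_state=self.seed)
            self._clf.fit(X, train.labels)
        else:
            raise ValueError(f"unsupported family {self.family!r}")
        return self

    def predict_scores(self, pairs) -> np.ndarray:
        missing = {p for pair in pairs for p in pair} - set(self.table.vectors)
        if missing:
            extra = random_vector_features(missing, dim=self.dim,
                                           seed=self.seed + 1)
            self.table.vectors.update(extra.vectors)
        X = np.stack([self.table.pair_vector(p) for p in pairs])
        return self._clf.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# Rotation forest
# ---------------------------------------------------------------------------

class RotationForestClassifier:
    """PCA-rotation decision-tree ensemble.

    Per tree the features are randomly partitioned into subsets; a PCA is fit
    on a bootstrap sample of a random class subset for each feature subset;
    the block-diagonal rotation is applied and a decision tree fit on the
    rotated data.  Scores are averaged tree probabilities.
    """

    def __init__(self, n_estimators: int = 10, subset_size: int = 3,
                 random_state: int = 0, max_depth: int | None = None):
        self.n_estimators = n_estimators
        self.subset_size = subset_size
        self.random_state = random_state
        self.max_depth = max_depth

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RotationForestClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        n, d = X.shape
        self.classes_ = np.unique(y)
        self._members = []
        for t in range(self.n_estimators):
            perm = rng.permutation(d)
            subsets = [perm[i:i + self.subset_size]
                       for i in range(0, d, self.subset_size)]
            rotation = np.zeros((d, d))
            for cols in subsets:
                classes = [c for c in self.classes_ if rng.random() > 0.25]
                mask = np.isin(y, classes if classes else self.classes_)
                rows = np.flatnonzero(mask)
                boot = rng.choice(rows, size=max(int(0.75 * len(rows)),
                                                 len(cols) + 1), replace=True)
                sub = X[np.ix_(boot, cols)]
                k = len(cols)
                pca = PCA(n_components=k,
                          random_state=self.random_state + t)
                try:
                    pca.fit(sub)
                    comp = pca.components_.T
                except Exception:
                    comp = np.eye(k)
                if comp.shape != (k, k):
                    full = np.eye(k)
                    full[:, :comp.shape[1]] = comp
                    comp = full
                rotation[np.ix_(cols, cols)] = comp
            tree = DecisionTreeClassifier(
                random_state=int(rng.integers(0, 2 ** 31 - 1)),
                max_depth=self.max_depth)
            tree.fit(X @ rotation, y)
            self._members.append((rotation, tree))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        acc = np.zeros((len(X), len(self.classes_)))
        for rotation, tree in self._members:
            acc += tree.predict_proba(X @ rotation)
        return acc / len(self._members)


# ---------------------------------------------------------------------------
# Generic classifier harness
# ---------------------------------------------------------------------------

@dataclass
class ClassifierSpec:
    """A model family plus hyperparameters and a seed."""

    family: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    FAMILIES = ("logistic", "random_forest", "rotation_forest",
                "gradient_boosting", "margin_classifier", "feedforward_net")


def _make_classifier(spec: ClassifierSpec, protein_dim: int | None = None):
    hp = dict(spec.hyperparameters)
    if spec.family == "logistic":
        return LogisticRegression(max_iter=hp.pop("max_iter", 1000),
                                  random_state=spec.seed, **hp)
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100),
            random_state=spec.seed, **hp)
    if spec.family == "rotation_forest":
        return RotationForestClassifier(random_state=spec.seed, **hp)
    if spec.family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=spec.seed, **hp)
    if spec.family == "margin_classifier":
        return LinearSVC(random_state=spec.seed, **hp)
    if spec.family == "feedforward_net":
        if protein_dim is not None:
            return SharedLayerNet(protein_dim=protein_dim, seed=spec.seed,
                                  **hp)
        return MLPClassifier(hidden_layer_sizes=hp.pop("hidden", (64, 32)),
                             learning_rate="invscaling",
                             max_iter=hp.pop("max_iter", 300),
                             random_state=spec.seed, **hp)
    raise ValueError(f"unknown model family {spec.family!r}")


class FittedModel:
    """A fitted encoder+classifier combination producing [0, 1] scores."""

    def __init__(self, clf, n_features: int):
        self._clf = clf
        self.n_features = n_features

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature width {X.shape[1]} != fitted width {self.n_features}")
        if hasattr(self._clf, "predict_proba"):
            return self._clf.predict_proba(X)[:, 1]
        margins = self._clf.decision_function(X)
        return 1.0 / (1.0 + np.exp(-margins))


def train_classifier(features: np.ndarray, labels: np.ndarray,
                     spec: ClassifierSpec,
                     protein_dim: int | None = None) -> FittedModel:
    """Fit a classifier of the requested family on pair features.

    No class weighting is applied regardless of the positive ratio, matching
    the benchmark's decision to evaluate models exactly as published.
    Scores from margin classifiers are monotone-mapped to [0, 1] through a
    logistic link.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    clf = _make_classifier(spec, protein_dim=protein_dim)
    clf.fit(X, y)
    return FittedModel(clf, X.shape[1])
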
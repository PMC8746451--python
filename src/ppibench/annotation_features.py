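"""GO- and domain-based pair features and the annotation-based predictors.

Features here are fundamentally *pairwise*: grids of scores between the two
proteins' annotation sets collapsed by an aggregation, or probabilities that
a pair of annotations co-occurs in known interactions.  Because the latter
are derived from the interaction network itself, they can leak test
information; :func:`fit_interaction_stats` therefore supports three source
modes — all interactions, non-test interactions, and interactions not
touching any held-out protein — so the leakage can be audited and removed.

Missing annotations on either side of a pair score zero throughout, so the
same datasets can be used for sequence- and annotation-based models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from .dataset_builder import PairDataset
from .io_formats import (
    AnnotationMap,
    ConfigError,
    InteractionSet,
    OntologyDAG,
    canonical_pair,
)

DOMAIN_DATABASES = ("Pfam", "Prosite", "InterPro")


# ---------------------------------------------------------------------------
# Information content and term-level semantic similarity
# ---------------------------------------------------------------------------

@dataclass
class TermIC:
    """Per-term information content: -ln p(term) with annotation counts
    propagated to ancestors; the root has IC 0."""

    ic: dict[str, float]

    def __getitem__(self, term: str) -> float:
        return self.ic[term]

    def get(self, term: str, default: float = 0.0) -> float:
        return self.ic.get(term, default)


def compute_ic(dag: OntologyDAG, annotations: AnnotationMap) -> TermIC:
    """Information content from a corpus of annotated proteins.

    Each protein's terms are propagated to all ancestors before counting;
    p(term) = (proteins annotated at-or-below term) / (corpus size), computed
    per namespace so that every namespace root has p = 1 and IC = 0.
    """
    ns_of = dag.namespace
    counts: dict[str, int] = {}
    ns_corpus: dict[str, int] = {}
    for pid in annotations.proteins():
        terms = annotations.get(pid)
        propagated: set[str] = set()
        for t in terms:
            if t not in dag:
                raise KeyError(f"annotated term {t!r} not in ontology")
            propagated |= dag.ancestors(t, include_self=True)
        for t in propagated:
            counts[t] = counts.get(t, 0) + 1
        for ns in {ns_of.get(t, "") for t in terms}:
            ns_corpus[ns] = ns_corpus.get(ns, 0) + 1
    ic: dict[str, float] = {}
    for t, c in counts.items():
        total = ns_corpus.get(ns_of.get(t, ""), 0)
        if total == 0 or c <= 0:
            continue
        p = c / total
        ic[t] = -math.log(min(p, 1.0))
    return TermIC(ic)


def _common_ancestors(t1: str, t2: str, dag: OntologyDAG) -> set[str]:
    if dag.namespace.get(t1) != dag.namespace.get(t2):
        return set()
    return dag.ancestors(t1) & dag.ancestors(t2)


def resnik_similarity(t1: str, t2: str, dag: OntologyDAG, ic: TermIC) -> float:
    """IC of the maximum-IC common ancestor; 0 across namespaces."""
    common = _common_ancestors(t1, t2, dag)
    if not common:
        return 0.0
    return max(ic.get(t, 0.0) for t in common)


def lin_similarity(t1: str, t2: str, dag: OntologyDAG, ic: TermIC) -> float:
    """2 IC(MICA) / (IC(t1) + IC(t2)); identical terms score 1.

    Terms never observed in the IC corpus have unbounded IC, so their
    similarity to anything else is 0."""
    if t1 == t2 and t1 in dag:
        return 1.0
    if t1 not in ic.ic or t2 not in ic.ic:
        return 0.0
    denom = ic.get(t1) + ic.get(t2)
    if denom == 0:
        return 0.0
    return 2.0 * resnik_similarity(t1, t2, dag, ic) / denom


def jiang_conrath_similarity(t1: str, t2: str, dag: OntologyDAG,
                             ic: TermIC) -> float:
    """1 / (1 + IC(t1) + IC(t2) - 2 IC(MICA)) — distance turned similarity.

    Unobserved terms are infinitely far from everything but themselves."""
    if t1 == t2 and t1 in dag:
        return 1.0
    if t1 not in ic.ic or t2 not in ic.ic:
        return 0.0
    if not _common_ancestors(t1, t2, dag):
        return 0.0
    dist = ic.get(t1) + ic.get(t2) - \
        2.0 * resnik_similarity(t1, t2, dag, ic)
    return 1.0 / (1.0 + max(dist, 0.0))


def relevance_similarity(t1: str, t2: str, dag: OntologyDAG,
                         ic: TermIC) -> float:
    """Lin similarity weighted by (1 - p(MICA)) so shallow ancestors count
    less."""
    common = _common_ancestors(t1, t2, dag)
    if not common:
        return 0.0
    ic_mica = max(ic.get(t, 0.0) for t in common)
    return lin_similarity(t1, t2, dag, ic) * (1.0 - math.exp(-ic_mica))


def wu_palmer_similarity(t1: str, t2: str, dag: OntologyDAG,
                         ic: TermIC) -> float:
    """2 depth(LCA) / (depth(t1) + depth(t2)) with shortest-path depths."""
    common = _common_ancestors(t1, t2, dag)
    if not common:
        return 0.0
    d_lca = max(dag.depth(t) for t in common)
    denom = dag.depth(t1) + dag.depth(t2)
    if denom == 0:
        return 1.0 if t1 == t2 else 0.0
    return 2.0 * d_lca / denom


def _ancestor_set_measure(kind: str):
    def measure(t1: str, t2: str, dag: OntologyDAG, ic: TermIC) -> float:
        if dag.namespace.get(t1) != dag.namespace.get(t2):
            return 0.0
        a1, a2 = dag.ancestors(t1), dag.ancestors(t2)
        inter, union = len(a1 & a2), len(a1 | a2)
        if kind == "jaccard":
            return inter / union if union else 0.0
        if kind == "dice":
            return 2.0 * inter / (len(a1) + len(a2)) if (a1 or a2) else 0.0
        if kind == "overlap":
            m = min(len(a1), len(a2))
            return inter / m if m else 0.0
        if kind == "cosine":
            d = math.sqrt(len(a1) * len(a2))
            return inter / d if d else 0.0
        raise ValueError(kind)
    measure.__name__ = f"ancestor_{kind}"
    return measure


#: Registry of term-level semantic-similarity measures (10 by default, the
#: multi-measure margin classifier draws its feature set from here).
SIMILARITY_MEASURES: dict[str, callable] = {
    "resnik": resnik_similarity,
    "lin": lin_similarity,
    "jiang_conrath": jiang_conrath_similarity,
    "relevance": relevance_similarity,
    "wu_palmer": wu_palmer_similarity,
    "ancestor_jaccard": _ancestor_set_measure("jaccard"),
    "ancestor_dice": _ancestor_set_measure("dice"),
    "ancestor_overlap": _ancestor_set_measure("overlap"),
    "ancestor_cosine": _ancestor_set_measure("cosine"),
    "resnik_scaled": lambda t1, t2, dag, ic: 1.0 - math.exp(
        -resnik_similarity(t1, t2, dag, ic)),
}


# ---------------------------------------------------------------------------
# Grid aggregation
# ---------------------------------------------------------------------------

def score_grid(terms_a, terms_b, score_fn) -> np.ndarray:
    """Grid of scores between all annotation pairs of the two proteins."""
    ta, tb = sorted(terms_a), sorted(terms_b)
    return np.array([[score_fn(x, y) for y in tb] for x in ta], dtype=float)


def aggregate(grid: np.ndarray, method: str = "bma") -> float:
    """Collapse a pair-score grid to one value.

    Methods: average, max, sum, product, and bma (best matching average:
    the mean of row maxima averaged with the mean of column maxima).
    An empty grid scores 0, the missing-data rule.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        return 0.0
    if method == "average":
        return float(grid.mean())
    if method == "max":
        return float(grid.max())
    if method == "sum":
        return float(grid.sum())
    if method == "product":
        return float(np.prod(grid))
    if method == "bma":
        return 0.5 * (float(grid.max(axis=1).mean()) +
                      float(grid.max(axis=0).mean()))
    raise ValueError(f"unknown aggregation {method!r}")


# ---------------------------------------------------------------------------
# Interaction-derived annotation-pair statistics (and their de-biasing)
# ---------------------------------------------------------------------------

@dataclass
class InteractionDerivedStats:
    """Annotation-pair co-occurrence counts from positive interactions.

    ``counts[(a1, a2)] = (interacting co-occurrences, total co-occurrence
    opportunities)`` with unordered annotation-pair keys.  ``mode`` records
    which interactions were allowed to contribute: every known interaction
    (``all``), interactions that are not test pairs (``non_test``), or
    interactions not touching any held-out protein (``held_out``).
    """

    counts: dict[tuple, tuple[int, int]]
    mode: str = "all"

    def raw_count(self, a1, a2) -> int:
        return self.counts.get(_akey(a1, a2), (0, 0))[0]

    def opportunity(self, a1, a2) -> int:
        return self.counts.get(_akey(a1, a2), (0, 0))[1]

    def probability(self, a1, a2) -> float:
        """Smoothed interaction probability (k + 1) / (n + 2)."""
        k, n = self.counts.get(_akey(a1, a2), (0, 0))
        return (k + 1.0) / (n + 2.0)

    def to_json(self, path: str | Path, manifest: dict | None = None) -> None:
        payload = {
            "mode": self.mode,
            "manifest": manifest or {},
            "counts": [[list(map(str, k)), v[0], v[1]]
                       for k, v in sorted(self.counts.items(),
                                          key=lambda kv: str(kv[0]))],
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


def _akey(a1, a2) -> tuple:
    return (a1, a2) if str(a1) <= str(a2) else (a2, a1)


def fit_interaction_stats(train_interactions: InteractionSet,
                          annotations: AnnotationMap,
                          mode: str = "all",
                          test_pairs: set | None = None,
                          held_proteins: set[str] | None = None,
                          opportunity_pairs=None) -> InteractionDerivedStats:
    """Count annotation-pair co-occurrences in positive interactions.

    ``mode`` controls the exclusion: ``all`` uses every interaction,
    ``non_test`` drops interactions that appear in the test pair list, and
    ``held_out`` drops every interaction touching a held-out protein.  The
    opportunity denominator counts labeled training pairs (positive and
    negative) in which the two annotations face each other across the pair;
    pass the training :class:`PairDataset` (or any pair iterable) as
    ``opportunity_pairs``, else the denominator falls back to the numerator
    universe (positives only).
    """
    if mode not in ("all", "non_test", "held_out"):
        raise ConfigError(f"unknown mode {mode!r}")
    if mode == "non_test" and test_pairs is None:
        raise ConfigError("mode='non_test' requires test_pairs")
    if mode == "held_out" and held_proteins is None:
        raise ConfigError("mode='held_out' requires held_proteins")
    if test_pairs is not None:
        test_pairs = {canonical_pair(*p) for p in test_pairs}

    def allowed(a: str, b: str) -> bool:
        if mode == "non_test" and canonical_pair(a, b) in test_pairs:
            return False
        if mode == "held_out" and (a in held_proteins or b in held_proteins):
            return False
        return True

    numer: dict[tuple, int] = {}
    for a, b in train_interactions:
        if not allowed(a, b):
            continue
        for key in _cross_annotation_keys(annotations.get(a),
                                          annotations.get(b)):
            numer[key] = numer.get(key, 0) + 1

    denom: dict[tuple, int] = {}
    if opportunity_pairs is not None:
        pairs = (opportunity_pairs.pairs
                 if isinstance(opportunity_pairs, PairDataset)
                 else opportunity_pairs)
        for a, b in pairs:
            if not allowed(a, b):
                continue
            for key in _cross_annotation_keys(annotations.get(a),
                                              annotations.get(b)):
                denom[key] = denom.get(key, 0) + 1
    else:
        denom = dict(numer)

    counts = {key: (k, max(denom.get(key, 0), k))
              for key, k in numer.items()}
    for key, n in denom.items():
        counts.setdefault(key, (0, n))
    return InteractionDerivedStats(counts=counts, mode=mode)


def _cross_annotation_keys(anns_a, anns_b):
    keys = set()
    for x in anns_a:
        for y in anns_b:
            keys.add(_akey(x, y))
    return keys


# ---------------------------------------------------------------------------
# Pair feature constructions
# ---------------------------------------------------------------------------

def domain_variant_features(pair: tuple[str, str],
                            stats_per_db: dict[str, InteractionDerivedStats],
                            domains: AnnotationMap) -> np.ndarray:
    """One noisy-OR score per domain database.

    Per database: score = 1 - prod over cross-protein domain pairs of
    (1 - p(d_i, d_j)); proteins without domains in that database score 0.
    """
    a, b = pair
    out = np.zeros(len(stats_per_db))
    for i, (db, stats) in enumerate(sorted(stats_per_db.items())):
        da = {k for k in domains.get(a) if k[0] == db}
        db_ = {k for k in domains.get(b) if k[0] == db}
        if not da or not db_:
            continue
        prod = 1.0
        for x in da:
            for y in db_:
                prod *= (1.0 - stats.probability(x, y))
        out[i] = 1.0 - prod
    return out


def level2_terms(dag: OntologyDAG, term: str) -> set[str]:
    """Depth-2 representation of a term: its level-2 ancestors (and itself
    when it sits exactly at depth 2); terms shallower than depth 2 map to
    nothing."""
    out = set()
    for t in dag.ancestors(term, include_self=True):
        if dag.depth(t) == 2:
            out.add(t)
    return out


def go_frequency_features(pair: tuple[str, str],
                          stats_per_namespace: dict[str, InteractionDerivedStats],
                          annotations: AnnotationMap,
                          dag: OntologyDAG,
                          level2: bool = True,
                          aggregation: str = "bma") -> np.ndarray:
    """Interaction-frequency features of GO annotation pairs, one per
    namespace, aggregated over the pair grid (best matching average)."""
    a, b = pair
    out = np.zeros(len(stats_per_namespace))
    for i, (ns, stats) in enumerate(sorted(stats_per_namespace.items())):
        ta = {t for t in annotations.get(a) if dag.namespace.get(t) == ns}
        tb = {t for t in annotations.get(b) if dag.namespace.get(t) == ns}
        if level2:
            ta = set().union(*(level2_terms(dag, t) for t in ta)) if ta else set()
            tb = set().union(*(level2_terms(dag, t) for t in tb)) if tb else set()
        if not ta or not tb:
            continue
        grid = score_grid(ta, tb, lambda x, y: stats.probability(x, y))
        out[i] = aggregate(grid, aggregation)
    return out


def ulca_vector(pair: tuple[str, str], dag: OntologyDAG,
                annotations: AnnotationMap,
                vocabulary: list[str] | None = None) -> np.ndarray:
    """Binary term vector marking annotations up to the lowest common
    ancestors of the two proteins' annotation sets.

    For each cross-protein annotation pair, the lowest (deepest) common
    ancestors are found and every term on an ascending path from either
    annotation up to and including an LCA is marked.  A pair with an
    unannotated protein yields the zero vector.
    """
    vocab = vocabulary if vocabulary is not None else sorted(dag.terms)
    pos = {t: i for i, t in enumerate(vocab)}
    out = np.zeros(len(vocab))
    a, b = pair
    ta = [t for t in annotations.get(a) if t in dag]
    tb = [t for t in annotations.get(b) if t in dag]
    if not ta or not tb:
        return out
    for x in ta:
        anc_x = dag.ancestors(x)
        for y in tb:
            common = anc_x & dag.ancestors(y)
            if not common:
                continue
            max_depth = max(dag.depth(t) for t in common)
            lcas = {t for t in common if dag.depth(t) == max_depth}
            for t in anc_x | dag.ancestors(y):
                if dag.ancestors(t) & lcas:
                    if t in pos:
                        out[pos[t]] = 1.0
    return out


def domain_binary_sum(pair: tuple[str, str], domains: AnnotationMap,
                      vocabulary: list | None = None) -> np.ndarray:
    """Ternary per-domain vector: [A has d] + [B has d] in {0, 1, 2}."""
    vocab = vocabulary if vocabulary is not None else domains.vocabulary()
    a, b = pair
    da, db = domains.get(a), domains.get(b)
    return np.array([float(d in da) + float(d in db) for d in vocab])


def semantic_similarity_features(pair: tuple[str, str],
                                 annotations: AnnotationMap,
                                 dag: OntologyDAG, ic: TermIC,
                                 measures: list[str],
                                 aggregation: str = "max") -> np.ndarray:
    """Aggregated semantic-similarity scores, one per (measure, namespace)."""
    a, b = pair
    namespaces = sorted(dag.namespaces()) or [""]
    out = np.zeros(len(measures) * len(namespaces))
    i = 0
    for m in measures:
        fn = SIMILARITY_MEASURES[m]
        for ns in namespaces:
            ta = {t for t in annotations.get(a)
                  if t in dag and dag.namespace.get(t) == ns}
            tb = {t for t in annotations.get(b)
                  if t in dag and dag.namespace.get(t) == ns}
            if ta and tb:
                grid = score_grid(ta, tb, lambda x, y: fn(x, y, dag, ic))
                out[i] = aggregate(grid, aggregation)
            i += 1
    return out


# ---------------------------------------------------------------------------
# The annotation-based predictors
# ---------------------------------------------------------------------------

class _LogisticScorer:
    """Shared fit/predict plumbing: logistic regression on pair features."""

    def __init__(self, seed: int = 0):
        self._clf = LogisticRegression(max_iter=1000, random_state=seed)

    def _features(self, pairs) -> np.ndarray:
        raise NotImplementedError

    def fit(self, dataset: PairDataset) -> "_LogisticScorer":
        X = self._features(dataset.pairs)
        self._clf.fit(X, dataset.labels)
        return self

    def predict_scores(self, pairs) -> np.ndarray:
        return self._clf.predict_proba(self._features(pairs))[:, 1]


class DomainVariantModel(_LogisticScorer):
    """Noisy-OR domain-pair interaction probabilities per database, combined
    by logistic regression."""

    def __init__(self, stats_per_db: dict[str, InteractionDerivedStats],
                 domains: AnnotationMap, seed: int = 0):
        super().__init__(seed)
        self.stats_per_db = stats_per_db
        self.domains = domains

    def _features(self, pairs) -> np.ndarray:
        return np.stack([domain_variant_features(p, self.stats_per_db,
                                                 self.domains)
                         for p in pairs])


class GuoSemanticModel(_LogisticScorer):
    """Single semantic-similarity measure per ontology namespace with max
    aggregation, scored by logistic regression."""

    def __init__(self, annotations: AnnotationMap, dag: OntologyDAG,
                 ic: TermIC, measure: str = "resnik", seed: int = 0):
        super().__init__(seed)
        self.annotations, self.dag, self.ic = annotations, dag, ic
        self.measure = measure

    def _features(self, pairs) -> np.ndarray:
        return np.stack([semantic_similarity_features(
            p, self.annotations, self.dag, self.ic, [self.measure])
            for p in pairs])


class ZhangSemanticModel:
    """Ten semantic-similarity measures per namespace feeding a margin
    classifier (linear SVM scored through a logistic link)."""

    def __init__(self, annotations: AnnotationMap, dag: OntologyDAG,
                 ic: TermIC, measures: list[str] | None = None,
                 seed: int = 0):
        from sklearn.svm import LinearSVC
        self.annotations, self.dag, self.ic = annotations, dag, ic
        self.measures = measures or list(SIMILARITY_MEASURES)
        self._clf = LinearSVC(random_state=seed)

    def _features(self, pairs) -> np.ndarray:
        return np.stack([semantic_similarity_features(
            p, self.annotations, self.dag, self.ic, self.measures)
            for p in pairs])

    def fit(self, dataset: PairDataset) -> "ZhangSemanticModel":
        self._clf.fit(self._features(dataset.pairs), dataset.labels)
        return self

    def predict_scores(self, pairs) -> np.ndarray:
        margins = self._clf.decision_function(self._features(pairs))
        return 1.0 / (1.0 + np.exp(-margins))


class SimpleEnsembleModel:
    """Random forest over Resnik similarity, level-2 GO interaction
    frequencies (best matching average) and the three domain-database
    noisy-OR scores."""

    def __init__(self, annotations: AnnotationMap, dag: OntologyDAG,
                 ic: TermIC,
                 go_stats: dict[str, InteractionDerivedStats],
                 domain_stats: dict[str, InteractionDerivedStats],
                 domains: AnnotationMap, seed: int = 0):
        from sklearn.ensemble import RandomForestClassifier
        self.annotations, self.dag, self.ic = annotations, dag, ic
        self.go_stats, self.domain_stats = go_stats, domain_stats
        self.domains = domains
        self._clf = RandomForestClassifier(n_estimators=100,
                                           random_state=seed)

    def _features(self, pairs) -> np.ndarray:
        rows = []
        for p in pairs:
            rows.append(np.concatenate([
                semantic_similarity_features(p, self.annotations, self.dag,
                                             self.ic, ["resnik"]),
                go_frequency_features(p, self.go_stats, self.annotations,
                                      self.dag),
                domain_variant_features(p, self.domain_stats, self.domains),
            ]))
        return np.stack(rows)

    def fit(self, dataset: PairDataset) -> "SimpleEnsembleModel":
        self._clf.fit(self._features(dataset.pairs), dataset.labels)
        return self

    def predict_scores(self, pairs) -> np.ndarray:
        return self._clf.predict_proba(self._features(pairs))[:, 1]


def debias_interaction_source(train_interactions: InteractionSet,
                              annotations: AnnotationMap,
                              test_pairs=None,
                              held_proteins: set[str] | None = None,
                              opportunity_pairs=None,
                              ) -> dict[str, InteractionDerivedStats]:
    """Fit interaction-derived statistics under every applicable source mode.

    Returns ``{"all": ..., "non_test": ..., "held_out": ...}`` (the held-out
    entry only when a held protein set is supplied), enabling side-by-side
    leakage audits."""
    out = {"all": fit_interaction_stats(train_interactions, annotations,
                                        "all",
                                        opportunity_pairs=opportunity_pairs)}
    if test_pairs is not None:
        out["non_test"] = fit_interaction_stats(
            train_interactions, annotations, "non_test",
            test_pairs=test_pairs, opportunity_pairs=opportunity_pairs)
    if held_proteins is not None:
        out["held_out"] = fit_interaction_stats(
            train_interactions, annotations, "held_out",
            test_pairs=test_pairs, held_proteins=held_proteins,
            opportunity_pairs=opportunity_pairs)
    return out
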
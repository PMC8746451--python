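"""GO/domain pair features, semantic similarity and de-biasing modes."""

import math

import numpy as np
import pytest

from ppibench.annotation_features import (
    DOMAIN_DATABASES,
    InteractionDerivedStats,
    SIMILARITY_MEASURES,
    aggregate,
    compute_ic,
    debias_interaction_source,
    domain_binary_sum,
    domain_variant_features,
    fit_interaction_stats,
    go_frequency_features,
    jiang_conrath_similarity,
    level2_terms,
    lin_similarity,
    resnik_similarity,
    score_grid,
    semantic_similarity_features,
    ulca_vector,
)
from ppibench.io_formats import AnnotationMap, ConfigError, InteractionSet, OntologyDAG


class TestComputeIC:
    def test_toy_corpus_values(self, toy_dag, toy_annotations):
        ic = compute_ic(toy_dag, toy_annotations)
        assert ic["root"] == pytest.approx(0.0)
        assert ic["c1"] == pytest.approx(math.log(2))
        assert ic["c2"] == pytest.approx(math.log(2))

    def test_term_annotating_everything_has_zero_ic(self, toy_dag):
        ann = AnnotationMap({f"P{i}": {"c1"} for i in range(4)})
        ic = compute_ic(toy_dag, ann)
        assert ic["c1"] == pytest.approx(0.0)

    def test_child_ic_at_least_parent(self, toy_dag):
        ann = AnnotationMap({"P1": {"d1"}, "P2": {"c1"}, "P3": {"c2"},
                             "P4": {"c2"}})
        ic = compute_ic(toy_dag, ann)
        for child, parents in toy_dag.parents.items():
            for p in parents:
                if child in ic.ic and p in ic.ic:
                    assert ic[child] >= ic[p] - 1e-12

    def test_unknown_term_errors(self, toy_dag):
        with pytest.raises(KeyError):
            compute_ic(toy_dag, AnnotationMap({"P1": {"nope"}}))


class TestResnik:
    def test_siblings_under_zero_ic_root(self, toy_dag, toy_annotations):
        ic = compute_ic(toy_dag, toy_annotations)
        assert resnik_similarity("c1", "c2", toy_dag, ic) == 0.0

    def test_self_similarity_is_own_ic(self, toy_dag, toy_annotations):
        ic = compute_ic(toy_dag, toy_annotations)
        assert resnik_similarity("c1", "c1", toy_dag, ic) == \
            pytest.approx(math.log(2))

    def test_symmetry(self, toy_dag, toy_annotations):
        ic = compute_ic(toy_dag, toy_annotations)
        assert resnik_similarity("c1", "d1", toy_dag, ic) == \
            resnik_similarity("d1", "c1", toy_dag, ic)


class TestOtherMeasures:
    def test_lin_identical_terms(self, toy_dag, toy_annotations):
        ic = compute_ic(toy_dag, toy_annotations)
        assert lin_similarity("c1", "c1", toy_dag, ic) == 1.0

    def test_jiang_conrath_decreases_with_distance(self, toy_dag,
                                                   toy_annotations):
        ic = compute_ic(toy_dag, toy_annotations)
        assert jiang_conrath_similarity("c1", "c1", toy_dag, ic) > \
            jiang_conrath_similarity("c1", "c2", toy_dag, ic)

    def test_registry_has_ten_measures(self):
        assert len(SIMILARITY_MEASURES) == 10


class TestAggregate:
    GRID = np.array([[0.2, 0.8], [0.1, 0.4]])

    def test_max(self):
        assert aggregate(self.GRID, "max") == pytest.approx(0.8)

    def test_bma_identity_grid(self):
        assert aggregate(np.eye(2), "bma") == pytest.approx(1.0)

    @pytest.mark.parametrize("method",
                             ["average", "max", "sum", "product", "bma"])
    def test_empty_grid_scores_zero(self, method):
        assert aggregate(np.zeros((0, 3)), method) == 0.0
        assert aggregate(np.zeros((2, 2)), method) in (0.0,)

    @pytest.mark.parametrize("method", ["max", "sum", "product", "bma"])
    def test_transpose_invariance(self, method):
        rng = np.random.default_rng(0)
        grid = rng.random((3, 5))
        assert aggregate(grid, method) == pytest.approx(
            aggregate(grid.T, method))


class TestFitInteractionStats:
    """Toy: domain pair (d1, d2) supported by 2 positive pairs, one of
    which is a test pair and one touches a held protein."""

    def setup_method(self):
        self.inter = InteractionSet([("A", "B"), ("C", "D")])
        self.ann = AnnotationMap({"A": {"d1"}, "B": {"d2"},
                                  "C": {"d1"}, "D": {"d2"}})

    def test_mode_all(self):
        stats = fit_interaction_stats(self.inter, self.ann, "all")
        assert stats.raw_count("d1", "d2") == 2

    def test_mode_non_test(self):
        stats = fit_interaction_stats(self.inter, self.ann, "non_test",
                                      test_pairs={("C", "D")})
        assert stats.raw_count("d1", "d2") == 1

    def test_mode_held_out_drops_both(self):
        stats = fit_interaction_stats(self.inter, self.ann, "held_out",
                                      held_proteins={"A", "C"})
        assert stats.raw_count("d1", "d2") == 0

    def test_smoothed_probability_from_nothing_is_half(self):
        stats = InteractionDerivedStats(counts={}, mode="all")
        assert stats.probability("x", "y") == pytest.approx(0.5)

    def test_missing_exclusion_input_is_config_error(self):
        with pytest.raises(ConfigError):
            fit_interaction_stats(self.inter, self.ann, "non_test")

    def test_debias_monotonicity(self):
        modes = debias_interaction_source(
            self.inter, self.ann, test_pairs={("C", "D")},
            held_proteins={"A"})
        k_all = modes["all"].raw_count("d1", "d2")
        k_nt = modes["non_test"].raw_count("d1", "d2")
        k_ho = modes["held_out"].raw_count("d1", "d2")
        assert k_all >= k_nt >= k_ho


def _stats_with(prob_counts):
    """Stats whose smoothed probability is controlled: (k, n) per pair."""
    return InteractionDerivedStats(
        counts={tuple(sorted(k, key=str)): v for k, v in prob_counts.items()})


class TestDomainVariantFeatures:
    def test_single_pair_probability_half(self):
        doms = AnnotationMap({"A": {("Pfam", "x")}, "B": {("Pfam", "y")}})
        stats = {"Pfam": _stats_with({})}  # (0+1)/(0+2) = 0.5
        out = domain_variant_features(("A", "B"), stats, doms)
        assert out[0] == pytest.approx(0.5)

    def test_two_pairs_noisy_or(self):
        doms = AnnotationMap({"A": {("Pfam", "x1"), ("Pfam", "x2")},
                              "B": {("Pfam", "y")}})
        stats = {"Pfam": _stats_with({})}
        out = domain_variant_features(("A", "B"), stats, doms)
        assert out[0] == pytest.approx(0.75)  # 1 - 0.5 * 0.5

    def test_no_domains_scores_zero(self):
        doms = AnnotationMap({"A": set(), "B": {("Pfam", "y")}})
        stats = {"Pfam": _stats_with({})}
        assert domain_variant_features(("A", "B"), stats, doms)[0] == 0.0


class TestGoFrequencyFeatures:
    def test_dominant_term_pair_scores_higher(self, toy_dag):
        ann = AnnotationMap({"A": {"c1"}, "B": {"c2"},
                             "X": {"c1"}, "Y": {"c1"}})
        # (c1, c2) co-observed in 9 of 10 interacting opportunities;
        # (c1, c1) in 0 of 10
        stats = {"biological_process": _stats_with({("c1", "c2"): (9, 10),
                                                    ("c1", "c1"): (0, 10)})}
        hot = go_frequency_features(("A", "B"), stats, ann, toy_dag,
                                    level2=False)
        cold = go_frequency_features(("X", "Y"), stats, ann, toy_dag,
                                     level2=False)
        assert hot[0] > cold[0]

    def test_empty_annotations_score_zero(self, toy_dag):
        ann = AnnotationMap({"A": set(), "B": {"c1"}})
        stats = {"biological_process": _stats_with({})}
        assert go_frequency_features(("A", "B"), stats, ann, toy_dag)[0] == 0.0

    def test_level2_mapping(self):
        dag = OntologyDAG({"r": set(), "a": {"r"}, "b": {"a"},
                           "c": {"b"}},
                          namespace={t: "bp" for t in "rabc"})
        assert level2_terms(dag, "c") == {"b"}
        assert level2_terms(dag, "b") == {"b"}
        assert level2_terms(dag, "a") == set()


class TestUlcaVector:
    def test_lca_is_root(self, toy_dag):
        ann = AnnotationMap({"A": {"c1"}, "B": {"c2"}})
        vec = ulca_vector(("A", "B"), toy_dag, ann)
        vocab = sorted(toy_dag.terms)
        marked = {t for t, v in zip(vocab, vec) if v == 1.0}
        assert marked == {"c1", "c2", "root"}

    def test_shared_term_marks_only_itself(self, toy_dag):
        ann = AnnotationMap({"A": {"c1"}, "B": {"c1"}})
        vec = ulca_vector(("A", "B"), toy_dag, ann)
        vocab = sorted(toy_dag.terms)
        marked = {t for t, v in zip(vocab, vec) if v == 1.0}
        assert marked == {"c1"}

    def test_unannotated_protein_zero_vector(self, toy_dag):
        ann = AnnotationMap({"A": {"c1"}, "B": set()})
        assert np.allclose(ulca_vector(("A", "B"), toy_dag, ann), 0.0)

    def test_symmetric_in_pair(self, toy_dag):
        ann = AnnotationMap({"A": {"d1"}, "B": {"c2"}})
        np.testing.assert_array_equal(
            ulca_vector(("A", "B"), toy_dag, ann),
            ulca_vector(("B", "A"), toy_dag, ann))


class TestDomainBinarySum:
    def test_values_and_symmetry(self):
        doms = AnnotationMap({"A": {("Pfam", "d"), ("Pfam", "e")},
                              "B": {("Pfam", "d")}})
        vocab = [("Pfam", "d"), ("Pfam", "e"), ("Pfam", "f")]
        vec = domain_binary_sum(("A", "B"), doms, vocab)
        np.testing.assert_array_equal(vec, [2.0, 1.0, 0.0])
        np.testing.assert_array_equal(
            vec, domain_binary_sum(("B", "A"), doms, vocab))


class TestSemanticSimilarityFeatures:
    def test_identical_sets_lin_max_is_one(self, toy_dag, toy_annotations):
        ic = compute_ic(toy_dag, toy_annotations)
        ann = AnnotationMap({"A": {"c1", "d1"}, "B": {"c1", "d1"}})
        out = semantic_similarity_features(("A", "B"), ann, toy_dag, ic,
                                           ["lin"])
        assert out[0] == pytest.approx(1.0)

    def test_resnik_siblings_zero(self, toy_dag, toy_annotations):
        ic = compute_ic(toy_dag, toy_annotations)
        ann = AnnotationMap({"A": {"c1"}, "B": {"c2"}})
        out = semantic_similarity_features(("A", "B"), ann, toy_dag, ic,
                                           ["resnik"])
        assert out[0] == 0.0

    def test_unannotated_scores_zero(self, toy_dag, toy_annotations):
        ic = compute_ic(toy_dag, toy_annotations)
        ann = AnnotationMap({"A": set(), "B": {"c1"}})
        out = semantic_similarity_features(("A", "B"), ann, toy_dag, ic,
                                           ["resnik", "lin"])
        assert np.allclose(out, 0.0)
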
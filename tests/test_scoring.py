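import numpy as np
import pytest

from funcascade import (
    BRANCH_INTERACTION,
    BRANCH_PSEAAC,
    BRANCH_SIMILARITY,
    Dataset,
    EvidenceBundle,
    FunctionCascade,
    FunctionScheme,
    build_annotation_matrix,
    predict_combined,
    pseaac_encode,
    score_by_interaction,
    score_by_pseaac,
    score_by_similarity,
)

from _oracles import naive_vote


@pytest.fixture
def refs24():
    scheme = FunctionScheme.funcat24()
    return build_annotation_matrix(
        [("mc10000007", {8, 10}), ("pA", {1}), ("pB", {1, 2}), ("pC", {12})],
        scheme,
    )


class TestSimilarityScoring:
    def test_single_hit_transfers_both_functions(self, refs24):
        bundle = EvidenceBundle(similarity={"mc10000007": 100.0})
        sv = score_by_similarity(bundle, refs24)
        assert sv.source == BRANCH_SIMILARITY
        scheme = refs24.scheme
        assert sv.scores[scheme.index(8)] == 100.0
        assert sv.scores[scheme.index(10)] == 100.0
        assert sv.scores.sum() == 200.0

    def test_two_hits_accumulate(self, refs24):
        bundle = EvidenceBundle(similarity={"pA": 3.0, "pB": 5.0})
        sv = score_by_similarity(bundle, refs24)
        scheme = refs24.scheme
        assert sv.scores[scheme.index(1)] == 8.0
        assert sv.scores[scheme.index(2)] == 5.0
        assert sv.scores.sum() == 13.0

    def test_no_hits_is_distinguishable_not_a_crash(self, refs24):
        assert score_by_similarity(EvidenceBundle(), refs24) is None

    def test_negative_weight_rejected(self, refs24):
        with pytest.raises(ValueError):
            score_by_similarity(EvidenceBundle(similarity={"pA": -1.0}), refs24)


class TestInteractionScoring:
    def test_single_edge(self, refs24):
        sv = score_by_interaction(EvidenceBundle(interaction={"pC": 900.0}), refs24)
        assert sv.source == BRANCH_INTERACTION
        assert sv.scores[refs24.scheme.index(12)] == 900.0
        assert sv.scores.sum() == 900.0

    def test_no_edges_is_distinguishable(self, refs24):
        assert score_by_interaction(EvidenceBundle(), refs24) is None

    def test_equal_weights_tie(self, refs24):
        sv = score_by_interaction(
            EvidenceBundle(interaction={"pA": 7.0, "pC": 7.0}), refs24
        )
        scheme = refs24.scheme
        assert sv.scores[scheme.index(1)] == sv.scores[scheme.index(12)]


class TestPseaacScoring:
    def test_identical_reference_dominates(self, refs24):
        v = pseaac_encode("ACDEF", lam=2)
        bundle = EvidenceBundle(
            pseaac_query=v,
            pseaac_refs={"pA": v, "pB": np.eye(1, v.size, 1).ravel()},
        )
        sv = score_by_pseaac(bundle, refs24)
        assert sv.source == BRANCH_PSEAAC
        assert sv.scores[refs24.scheme.index(1)] == pytest.approx(
            1.0 + sv.scores[refs24.scheme.index(2)]
        )

    def test_hand_computed_cosine_vote(self, refs24):
        # cosines 0.9 (pA, {1}) and 0.6 (pB, {1,2}) -> r1 = 1.5, r2 = 0.6
        q = np.array([1.0, 0.0])
        refA = np.array([0.9, np.sqrt(1 - 0.81)])
        refB = np.array([0.6, np.sqrt(1 - 0.36)])
        bundle = EvidenceBundle(pseaac_query=q, pseaac_refs={"pA": refA, "pB": refB})
        sv = score_by_pseaac(bundle, refs24)
        scheme = refs24.scheme
        assert sv.scores[scheme.index(1)] == pytest.approx(1.5, abs=1e-12)
        assert sv.scores[scheme.index(2)] == pytest.approx(0.6, abs=1e-12)

    def test_no_references_rejected(self, refs24):
        with pytest.raises(ValueError):
            score_by_pseaac(EvidenceBundle(pseaac_query=np.ones(3)), refs24)

    def test_top_k_restriction(self, refs24):
        q = np.array([1.0, 0.0])
        bundle = EvidenceBundle(
            pseaac_query=q,
            pseaac_refs={
                "pA": np.array([0.9, 0.44]),
                "pC": np.array([0.1, 0.99]),
            },
        )
        sv = score_by_pseaac(bundle, refs24, top_k=1)
        assert sv.scores[refs24.scheme.index(12)] == 0.0


class TestCascade:
    def test_similarity_wins_over_interaction(self, refs24):
        bundle = EvidenceBundle(
            similarity={"pA": 1.0}, interaction={"pC": 900.0}
        )
        assert predict_combined(bundle, refs24).branch == BRANCH_SIMILARITY

    def test_interaction_when_no_homologues(self, refs24):
        bundle = EvidenceBundle(interaction={"pC": 900.0})
        assert predict_combined(bundle, refs24).branch == BRANCH_INTERACTION

    def test_pseaac_fallback(self, refs24):
        bundle = EvidenceBundle(
            pseaac_query=np.ones(4), pseaac_refs={"pA": np.ones(4)}
        )
        assert predict_combined(bundle, refs24).branch == BRANCH_PSEAAC

    def test_empty_reference_set_rejected(self):
        scheme = FunctionScheme.generic(3)
        refs = build_annotation_matrix([], scheme)
        with pytest.raises(ValueError):
            predict_combined(EvidenceBundle(similarity={"x": 1.0}), refs)


class TestScoringProperties:
    def _random_instance(self, rng, n_refs):
        scheme = FunctionScheme.funcat24()
        annotations = {
            f"r{i}": set(
                rng.choice(range(1, 25), size=rng.integers(1, 5), replace=False)
            )
            for i in range(n_refs)
        }
        refs = build_annotation_matrix(annotations.items(), scheme)
        weights = {f"r{i}": float(rng.random() * 10) for i in range(n_refs)}
        return scheme, annotations, refs, weights

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            scheme, annotations, refs, weights = self._random_instance(
                rng, int(rng.integers(1, 50))
            )
            sv = score_by_similarity(EvidenceBundle(similarity=weights), refs)
            expected = naive_vote(weights, annotations, scheme.numbers)
            np.testing.assert_allclose(sv.scores, expected, atol=1e-9)

    def test_linearity_and_additivity(self):
        rng = np.random.default_rng(5)
        scheme, annotations, refs, weights = self._random_instance(rng, 30)
        base = score_by_similarity(EvidenceBundle(similarity=weights), refs).scores
        doubled = score_by_similarity(
            EvidenceBundle(similarity={k: 2 * v for k, v in weights.items()}), refs
        ).scores
        np.testing.assert_allclose(doubled, 2 * base, atol=1e-9)

        keys = list(weights)
        left = {k: weights[k] for k in keys[:15]}
        right = {k: weights[k] for k in keys[15:]}
        s_left = score_by_similarity(EvidenceBundle(similarity=left), refs).scores
        s_right = score_by_similarity(EvidenceBundle(similarity=right), refs).scores
        np.testing.assert_allclose(s_left + s_right, base, atol=1e-9)


class TestFunctionCascadeEstimator:
    def test_branch_selection_and_exclusion(self, cascade_dataset, scheme4):
        model = FunctionCascade(scheme=scheme4).fit(cascade_dataset)
        assert model.predict_one("p1", exclude={"p1"}).branch == BRANCH_SIMILARITY
        assert model.predict_one("p3", exclude={"p3"}).branch == BRANCH_INTERACTION
        assert model.predict_one("p4", exclude={"p4"}).branch == BRANCH_PSEAAC
        # excluding the only homologue pushes p1 down the cascade
        assert model.predict_one("p1", exclude={"p1", "p2"}).branch == BRANCH_PSEAAC

    def test_self_hit_always_removed(self, scheme4):
        dataset = Dataset(
            sequences={"a": "ACDE", "b": "GHIK"},
            annotations={"a": frozenset({1}), "b": frozenset({2})},
            similarity_hits=[("a", "a", 999.0), ("a", "b", 1.0)],
        )
        model = FunctionCascade(scheme=scheme4).fit(dataset)
        pred = model.predict_one("a")
        assert pred.branch == BRANCH_SIMILARITY
        assert pred.scores.scores[scheme4.index(2)] == 1.0
        assert pred.scores.scores[scheme4.index(1)] == 0.0

    def test_id_map_routes_interaction_evidence(self, scheme4):
        dataset = Dataset(
            sequences={"a": "ACDE", "b": "GHIK"},
            annotations={"a": frozenset({1}), "b": frozenset({2})},
            interaction_edges=[("netA", "netB", 700.0)],
            id_map={"a": "netA", "b": "netB"},
        )
        model = FunctionCascade(scheme=scheme4).fit(dataset)
        pred = model.predict_one("a")
        assert pred.branch == BRANCH_INTERACTION
        assert pred.scores.scores[scheme4.index(2)] == 700.0

    def test_unmapped_protein_lacks_interaction_evidence(self, scheme4):
        dataset = Dataset(
            sequences={"a": "ACDE", "b": "GHIK"},
            annotations={"a": frozenset({1}), "b": frozenset({2})},
            interaction_edges=[("netA", "netB", 700.0)],
            id_map={"b": "netB"},  # 'a' has no network identity
        )
        model = FunctionCascade(scheme=scheme4).fit(dataset)
        assert model.predict_one("a").branch == BRANCH_PSEAAC

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        model = FunctionCascade(lam=9, top_k=3)
        cloned = clone(model)
        assert cloned.get_params()["lam"] == 9
        assert cloned.get_params()["top_k"] == 3

    def test_vectorized_pseaac_matches_bundle_scoring(self, scheme4):
        rng = np.random.default_rng(3)
        from conftest import random_sequence

        sequences = {f"p{i}": random_sequence(rng, 10, 30) for i in range(12)}
        annotations = {
            f"p{i}": frozenset({int(rng.integers(1, 5))}) for i in range(12)
        }
        dataset = Dataset(sequences=sequences, annotations=annotations)
        model = FunctionCascade(scheme=scheme4, lam=5).fit(dataset)
        pred = model.predict_one("p0", exclude={"p0"})
        bundle = EvidenceBundle(
            pseaac_query=model.features_["p0"],
            pseaac_refs={p: model.features_[p] for p in sequences if p != "p0"},
        )
        refs = build_annotation_matrix(
            [(p, annotations[p]) for p in annotations if p != "p0"], scheme4
        )
        expected = score_by_pseaac(bundle, refs)
        np.testing.assert_allclose(
            pred.scores.scores, expected.scores, atol=1e-9
        )
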
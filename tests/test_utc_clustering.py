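"""UTC: tf-idf matrix, spectral co-embedding, concurrent k-means, labels and
cluster-quality metrics.

Independent oracles: scikit-learn's TfidfTransformer for the document
weights, explicit full-space cosine computation for the embedding, exhaustive
2-partition search for small k-means instances, and direct pair enumeration
for the quality metrics.
"""

import itertools
import math

import numpy as np
import pytest
from sklearn.feature_extraction.text import TfidfTransformer

from trialminer.protocol_io import TrialProtocol, corpus_truth, generate_corpus
from trialminer.term_extraction import CandidateTerm, terms_facet
from trialminer.utc_clustering import (
    ClusterSolution,
    Embedding,
    WeightedMatrix,
    build_matrix,
    cluster,
    co_embed,
    label_clusters,
    quality,
    utc,
)

from conftest import make_corpus_spec


def _term(*tokens):
    return CandidateTerm(
        tokens=tuple(tokens), f=2, nested_in=frozenset(), nestedness=2.0, cvalue=2.0
    )


def _docs(texts):
    return [TrialProtocol(id=f"NCT{i}", brief_summary=t) for i, t in enumerate(texts)]


def _cosine(a, b):
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


class TestBuildMatrix:
    def test_term_columns_live_on_their_own_tokens(self):
        docs = _docs(["lung cancer treatment", "lung disease"])
        m = build_matrix(docs, [_term("lung", "cancer")])
        col = m.matrix[:, 2]
        nonzero_feats = {m.features[i] for i in np.nonzero(col)[0]}
        assert nonzero_feats == {"lung", "cancer"}

    def test_ubiquitous_unigram_zero_without_smoothing(self):
        docs = _docs(["lung cancer", "lung disease", "lung injury"])
        m = build_matrix(docs, [_term("lung", "cancer")], smooth_idf=False)
        row = list(m.features).index("lung")
        assert np.allclose(m.matrix[row, :], 0.0)  # idf = ln(N/N) = 0

    def test_doc_weights_match_sklearn_tfidf(self):
        docs = _docs(
            ["lung cancer cancer treatment", "lung disease", "cancer screening basics"]
        )
        m = build_matrix(docs, [_term("lung", "cancer")])
        counts = np.zeros((3, len(m.features)))
        texts = [d.brief_summary.split() for d in docs]
        for j, toks in enumerate(texts):
            for t in toks:
                counts[j, list(m.features).index(t)] += 1
        oracle = TfidfTransformer(norm=None, smooth_idf=True, sublinear_tf=False)
        expected = oracle.fit_transform(counts).toarray().T  # features x docs
        assert np.allclose(m.doc_columns(), expected)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_matrix([], [_term("a", "b")])
        with pytest.raises(ValueError):
            build_matrix(_docs(["some text"]), [])


class TestCoEmbed:
    def test_identical_columns_get_identical_coordinates(self):
        docs = _docs(["alpha beta gamma", "alpha beta gamma", "delta epsilon"])
        m = build_matrix(docs, [_term("alpha", "beta")])
        rank = np.linalg.matrix_rank(m.matrix)
        e = co_embed(m, rank)
        assert np.allclose(e.coordinates[0], e.coordinates[1])

    def test_full_rank_preserves_cosines(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.random((rng.integers(4, 9), rng.integers(3, 7)))
            m = WeightedMatrix(
                matrix=x,
                features=tuple(f"f{i}" for i in range(x.shape[0])),
                object_ids=tuple(f"d{j}" for j in range(x.shape[1])),
                column_kinds=("DOC",) * x.shape[1],
            )
            e = co_embed(m, np.linalg.matrix_rank(x))
            for i, j in itertools.combinations(range(x.shape[1]), 2):
                assert math.isclose(
                    _cosine(e.coordinates[i], e.coordinates[j]),
                    _cosine(x[:, i], x[:, j]),
                    abs_tol=1e-9,
                )

    def test_disjoint_vocabulary_docs_are_orthogonal(self):
        docs = _docs(["alpha beta alpha", "gamma delta delta"])
        m = build_matrix(docs, [_term("alpha", "beta")])
        e = co_embed(m, int(np.linalg.matrix_rank(m.matrix)))
        assert abs(_cosine(e.coordinates[0], e.coordinates[1])) < 1e-9

    def test_k_beyond_rank_rejected(self):
        docs = _docs(["alpha beta", "alpha beta"])
        m = build_matrix(docs, [_term("alpha", "beta")])
        with pytest.raises(ValueError, match="rank"):
            co_embed(m, 5)


class TestCluster:
    def _embedding(self, points, kinds=None):
        pts = np.asarray(points, dtype=float)
        kinds = kinds or ("DOC",) * len(pts)
        return Embedding(
            coordinates=pts,
            object_ids=tuple(f"o{i}" for i in range(len(pts))),
            column_kinds=tuple(kinds),
            k=pts.shape[1],
        )

    def test_single_cluster_takes_everything(self):
        e = self._embedding([[1, 0], [0, 1], [1, 1]])
        sol = cluster(e, 1, seed=0)
        assert set(sol.assignment.values()) == {0}

    def test_recovers_separated_groups_exactly(self):
        # two tight direction groups; brute-force over all 2-partitions
        # confirms the returned partition minimizes spherical WCSS
        pts = np.array(
            [[1.0, 0.02], [1.0, -0.02], [0.99, 0.0], [0.02, 1.0], [-0.02, 1.0], [0.0, 0.98]]
        )
        e = self._embedding(pts)
        sol = cluster(e, 2, seed=3)
        got = frozenset(
            frozenset(i for i in range(6) if sol.assignment[("DOC", f"o{i}")] == c)
            for c in set(sol.assignment.values())
        )
        unit = pts / np.linalg.norm(pts, axis=1, keepdims=True)

        def wcss(partition):
            total = 0.0
            for group in partition:
                members = unit[sorted(group)]
                total += ((members - members.mean(axis=0)) ** 2).sum()
            return total

        best = min(
            (
                frozenset({frozenset(g), frozenset(set(range(6)) - set(g))})
                for r in range(1, 6)
                for g in itertools.combinations(range(6), r)
            ),
            key=wcss,
        )
        assert got == best

    def test_seeded_determinism(self):
        rng = np.random.default_rng(0)
        e = self._embedding(rng.random((30, 4)))
        assert cluster(e, 4, seed=9).assignment == cluster(e, 4, seed=9).assignment

    def test_invalid_n_clusters(self):
        e = self._embedding([[1, 0], [0, 1]])
        with pytest.raises(ValueError):
            cluster(e, 0)
        with pytest.raises(ValueError):
            cluster(e, 3)

    def test_hard_assignment_total_on_documents(self):
        rng = np.random.default_rng(2)
        e = self._embedding(rng.random((10, 3)), kinds=["DOC"] * 6 + ["TERM"] * 4)
        sol = cluster(e, 2, seed=1)
        assert len(sol.doc_assignment()) == 6
        assert all(0 <= c < 2 for c in sol.assignment.values())


class TestLabels:
    def test_single_term_single_doc(self):
        e = Embedding(
            coordinates=np.array([[1.0, 0.2], [0.9, 0.1]]),
            object_ids=("d", "lung cancer"),
            column_kinds=("DOC", "TERM"),
            k=2,
        )
        sol = ClusterSolution(assignment={("DOC", "d"): 0, ("TERM", "lung cancer"): 0}, n_clusters=1)
        labelled = label_clusters(sol, e)
        assert labelled.labels == {0: "lung cancer"}
        assert labelled.term_scores[("lung cancer", 0)] == pytest.approx(
            _cosine(e.coordinates[0], e.coordinates[1])
        )

    def test_scores_equal_hand_computed_cosine_sums(self):
        coords = np.array(
            [[1.0, 0.0], [0.8, 0.6], [0.0, 1.0], [0.9, 0.1], [0.1, 0.9]]
        )
        e = Embedding(
            coordinates=coords,
            object_ids=("d1", "d2", "d3", "term a", "term b"),
            column_kinds=("DOC", "DOC", "DOC", "TERM", "TERM"),
            k=2,
        )
        assignment = {
            ("DOC", "d1"): 0, ("DOC", "d2"): 0, ("DOC", "d3"): 1,
            ("TERM", "term a"): 0, ("TERM", "term b"): 1,
        }
        labelled = label_clusters(ClusterSolution(assignment=assignment, n_clusters=2), e)
        expected_a = _cosine(coords[3], coords[0]) + _cosine(coords[3], coords[1])
        assert labelled.term_scores[("term a", 0)] == pytest.approx(expected_a)
        assert labelled.term_scores[("term b", 1)] == pytest.approx(_cosine(coords[4], coords[2]))
        assert labelled.labels == {0: "term a", 1: "term b"}

    def test_labels_on_fixture_are_short_terms(self):
        corpus = generate_corpus(make_corpus_spec())
        term_list, _ = terms_facet(corpus)
        sol, _, _ = utc(corpus, term_list, n_clusters=3, seed=0)
        for label in sol.labels.values():
            assert 2 <= len(label.split()) <= 4


class TestQuality:
    def _solution(self, groups):
        assignment = {("DOC", d): c for c, docs in enumerate(groups) for d in docs}
        return ClusterSolution(assignment=assignment, n_clusters=len(groups))

    def _matrix(self, ids):
        rng = np.random.default_rng(1)
        x = rng.random((4, len(ids)))
        return WeightedMatrix(
            matrix=x, features=("f1", "f2", "f3", "f4"),
            object_ids=tuple(ids), column_kinds=("DOC",) * len(ids),
        )

    def test_perfect_partition(self):
        sol = self._solution([["a", "b"], ["c"]])
        rep = quality(sol, {"a": 1, "b": 1, "c": 2}, self._matrix(["a", "b", "c"]))
        assert rep.purity == 1.0
        assert rep.pairwise_contamination == 0.0

    def test_mixed_three_doc_cluster(self):
        # one cluster {a, b (class 1), c (class 2)}: purity 2/3 and 2 of the
        # 3 pairs straddle classes
        sol = self._solution([["a", "b", "c"]])
        rep = quality(sol, {"a": 1, "b": 1, "c": 2}, self._matrix(["a", "b", "c"]))
        assert rep.purity == pytest.approx(2 / 3)
        assert rep.pairwise_contamination == pytest.approx(2 / 3)

    def test_singletons_have_no_contamination(self):
        sol = self._solution([["a"], ["b"], ["c"]])
        rep = quality(sol, {"a": 1, "b": 2, "c": 3}, self._matrix(["a", "b", "c"]))
        assert rep.pairwise_contamination == 0.0
        assert rep.within_cluster_similarity == 0.0

    def test_unknown_document_rejected(self):
        sol = self._solution([["a", "b"]])
        with pytest.raises(ValueError, match="missing from truth"):
            quality(sol, {"a": 1}, self._matrix(["a", "b"]))

    def test_agrees_with_pair_enumeration_on_random_partitions(self):
        rng = np.random.default_rng(4)
        ids = [f"d{i}" for i in range(15)]
        m = self._matrix(ids)
        for _ in range(10):
            assign = {d: int(rng.integers(0, 4)) for d in ids}
            truth = {d: int(rng.integers(0, 3)) for d in ids}
            sol = ClusterSolution(
                assignment={("DOC", d): c for d, c in assign.items()}, n_clusters=4
            )
            rep = quality(sol, truth, m)
            mixed = pairs = 0
            majority = 0
            for c in set(assign.values()):
                docs = [d for d in ids if assign[d] == c]
                counts = {}
                for d in docs:
                    counts[truth[d]] = counts.get(truth[d], 0) + 1
                majority += max(counts.values())
                for a, b in itertools.combinations(docs, 2):
                    pairs += 1
                    mixed += truth[a] != truth[b]
            assert rep.purity == pytest.approx(majority / len(ids))
            assert rep.pairwise_contamination == pytest.approx(mixed / pairs if pairs else 0.0)


class TestEndToEndRecovery:
    def test_planted_clusters_recovered(self):
        spec = make_corpus_spec()  # 3 clusters x 20 docs, disjoint vocabularies
        corpus = generate_corpus(spec)
        term_list, _ = terms_facet(corpus)
        sol, _, m = utc(corpus, term_list, n_clusters=3, seed=0)
        rep = quality(sol, corpus_truth(corpus), m)
        assert rep.purity >= 0.95
        assert rep.pairwise_contamination <= 0.05
        truth = corpus_truth(corpus)
        doc_assign = sol.doc_assignment()
        for c, label in sol.labels.items():
            members = [d for d, cc in doc_assign.items() if cc == c]
            true_cluster = max(set(truth[d] for d in members), key=[truth[d] for d in members].count)
            vocab = set(spec.vocabulary_per_cluster[true_cluster])
            assert set(label.split()) <= vocab
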
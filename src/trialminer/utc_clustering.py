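"""Unigram and Term-based Clustering (UTC) of search results.

UTC clusters protocols and labels the clusters with multiword terms in one
pass.  Both documents and extracted multiword terms are represented in the
same vector space: a term is viewed as a very short document made of its own
tokens, so the feature-by-object tf-idf matrix has a column per document and
a column per term.  A truncated spectral factorization (SVD) of that combined
matrix co-embeds all columns in a common low-dimensional semantic space,
where documents and terms are *concurrently* clustered by k-means (hard
assignment).  Within each cluster, every term is scored by its total cosine
similarity to the cluster's documents, and the highest-scoring term becomes
the cluster label — which is why labels come out short and meaningful: a term
competes on semantic proximity, not on looking like a document.

Cluster quality against an external ground truth is reported as purity
(fraction of documents in their cluster's majority class), pairwise cluster
contamination (fraction of same-cluster document pairs whose true classes
differ) and within-cluster similarity (mean pairwise cosine of same-cluster
documents in tf-idf space).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ._text import index_tokens
from .protocol_io import TrialProtocol
from .term_extraction import CandidateTerm

__all__ = [
    "WeightedMatrix",
    "Embedding",
    "ClusterSolution",
    "QualityReport",
    "build_matrix",
    "co_embed",
    "cluster",
    "label_clusters",
    "quality",
    "utc",
]

DOC = "DOC"
TERM = "TERM"


@dataclass(frozen=True)
class WeightedMatrix:
    """Feature-by-object tf-idf matrix; documents first, then terms."""

    matrix: np.ndarray  # (n_features, n_docs + n_terms)
    features: tuple[str, ...]
    object_ids: tuple[str, ...]
    column_kinds: tuple[str, ...]

    @property
    def n_docs(self) -> int:
        return sum(1 for k in self.column_kinds if k == DOC)

    def doc_columns(self) -> np.ndarray:
        return self.matrix[:, [i for i, k in enumerate(self.column_kinds) if k == DOC]]


@dataclass(frozen=True)
class Embedding:
    coordinates: np.ndarray  # (n_objects, k)
    object_ids: tuple[str, ...]
    column_kinds: tuple[str, ...]
    k: int


@dataclass
class ClusterSolution:
    """Hard partition of documents and terms, with one label per cluster."""

    assignment: dict[tuple[str, str], int]  # (kind, id) -> cluster
    n_clusters: int
    labels: dict[int, str] = field(default_factory=dict)
    term_scores: dict[tuple[str, int], float] = field(default_factory=dict)

    def doc_assignment(self) -> dict[str, int]:
        return {oid: c for (kind, oid), c in self.assignment.items() if kind == DOC}

    def term_assignment(self) -> dict[str, int]:
        return {oid: c for (kind, oid), c in self.assignment.items() if kind == TERM}


@dataclass(frozen=True)
class QualityReport:
    purity: float
    pairwise_contamination: float
    within_cluster_similarity: float


def _doc_text(p: TrialProtocol) -> str:
    return "\n".join((p.brief_summary, p.detailed_description, p.eligibility_text))


def build_matrix(
    docs: list[TrialProtocol],
    terms: list[CandidateTerm],
    smooth_idf: bool = True,
) -> WeightedMatrix:
    """Assemble the combined document + term-pseudo-document tf-idf matrix.

    Unigram features come from the documents; idf is fitted on the document
    columns only (smoothed: ln((1+N)/(1+df)) + 1; unsmoothed: ln(N/df)) and
    reused to weigh the term columns, so a term column has nonzero weight
    exactly on the rows of its own tokens.  Features without document support
    are dropped.  No column normalization — cosine geometry is applied
    downstream.
    """
    if not docs or not terms:
        raise ValueError("need at least one document and one term")
    doc_tokens = [index_tokens(_doc_text(p)) for p in docs]
    vocab = sorted({t for toks in doc_tokens for t in toks})
    if not vocab:
        raise ValueError("empty vocabulary after tokenization")
    row = {t: i for i, t in enumerate(vocab)}

    n_docs = len(docs)
    df = np.zeros(len(vocab))
    tf_docs = np.zeros((len(vocab), n_docs))
    for j, toks in enumerate(doc_tokens):
        counts = Counter(toks)
        for t, c in counts.items():
            tf_docs[row[t], j] = c
        for t in counts:
            df[row[t]] += 1

    if smooth_idf:
        idf = np.log((1.0 + n_docs) / (1.0 + df)) + 1.0
    else:
        idf = np.log(n_docs / df)

    tf_terms = np.zeros((len(vocab), len(terms)))
    for j, term in enumerate(terms):
        for t, c in Counter(term.tokens).items():
            if t in row:
                tf_terms[row[t], j] = c

    matrix = np.hstack([tf_docs, tf_terms]) * idf[:, None]
    object_ids = tuple(p.id for p in docs) + tuple(" ".join(t.tokens) for t in terms)
    kinds = (DOC,) * n_docs + (TERM,) * len(terms)
    return WeightedMatrix(
        matrix=matrix, features=tuple(vocab), object_ids=object_ids, column_kinds=kinds
    )


def co_embed(m: WeightedMatrix, k: int) -> Embedding:
    """Rank-k spectral co-embedding of all columns (documents and terms).

    With X = U S V', each column j maps to (S V')[:, j] truncated to the top
    k components — at k = rank(X) this preserves all pairwise column cosines
    exactly, since U has orthonormal columns.  Sign convention: the
    largest-magnitude entry of each left singular vector is made positive, so
    the embedding is reproducible across linear-algebra backends.
    """
    u, s, vt = np.linalg.svd(m.matrix, full_matrices=False)
    tol = max(m.matrix.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if not 1 <= k <= rank:
        raise ValueError(f"embedding dimension k={k} outside [1, rank={rank}]")
    # flip sign where the basis vector's largest-|.| entry is negative
    for i in range(u.shape[1]):
        col = u[:, i]
        if col[np.argmax(np.abs(col))] < 0:
            u[:, i] = -col
            vt[i, :] = -vt[i, :]
    coords = (s[:k, None] * vt[:k, :]).T  # (n_objects, k)
    return Embedding(
        coordinates=coords, object_ids=m.object_ids, column_kinds=m.column_kinds, k=k
    )


def default_dim(m: WeightedMatrix) -> int:
    """Default embedding dimension: min(50, rank-1), at least 1."""
    rank = np.linalg.matrix_rank(m.matrix)
    return max(1, min(50, rank - 1))


def cluster(
    e: Embedding, n_clusters: int, seed: int = 0, normalize: bool = True
) -> ClusterSolution:
    """Concurrent k-means over documents and terms in the common space.

    k-means++ initialization with a fixed seed and multiple restarts; the
    assignment is hard and reproducible for a given seed.  By default the
    embedded vectors are L2-normalized first (spherical k-means): documents
    and term pseudo-documents differ hugely in norm but are compared by
    direction throughout (cosine), and without normalization the short term
    vectors would all collapse into one near-origin cluster instead of
    joining their topic's documents.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    n_docs = sum(1 for k_ in e.column_kinds if k_ == DOC)
    if n_clusters > n_docs:
        raise ValueError("n_clusters exceeds the number of documents")
    points = e.coordinates
    if normalize:
        norms = np.linalg.norm(points, axis=1, keepdims=True)
        points = points / np.where(norms == 0.0, 1.0, norms)
    km = KMeans(
        n_clusters=n_clusters,
        init="k-means++",
        n_init=50,
        max_iter=300,
        random_state=seed & 0x7FFFFFFF,
    )
    labels = km.fit_predict(points)
    assignment = {
        (kind, oid): int(c)
        for kind, oid, c in zip(e.column_kinds, e.object_ids, labels)
    }
    return ClusterSolution(assignment=assignment, n_clusters=n_clusters)


def _cosine_rows(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def label_clusters(
    sol: ClusterSolution, e: Embedding, m: WeightedMatrix | None = None
) -> ClusterSolution:
    """Label every non-empty document cluster.

    Each term t in cluster c scores score(t, c) = sum over documents d in c
    of cosine(e[t], e[d]); the cluster's label is its highest-scoring term
    (ties break lexicographically).  A cluster containing no term falls back
    to the highest-total-tf-idf unigram of its documents (requires ``m``).
    """
    pos = {(kind, oid): i for i, (kind, oid) in enumerate(zip(e.column_kinds, e.object_ids))}
    doc_members: dict[int, list[str]] = {}
    term_members: dict[int, list[str]] = {}
    for (kind, oid), c in sol.assignment.items():
        (doc_members if kind == DOC else term_members).setdefault(c, []).append(oid)

    labels: dict[int, str] = {}
    term_scores: dict[tuple[str, int], float] = {}
    for c, docs_in_c in sorted(doc_members.items()):
        best: tuple[float, str] | None = None
        for t in sorted(term_members.get(c, [])):
            score = sum(
                _cosine_rows(
                    e.coordinates[pos[(TERM, t)]], e.coordinates[pos[(DOC, d)]]
                )
                for d in docs_in_c
            )
            term_scores[(t, c)] = score
            if best is None or score > best[0]:
                best = (score, t)
        if best is not None:
            labels[c] = best[1]
        elif m is not None:
            cols = [m.object_ids.index(d) for d in docs_in_c]
            totals = m.matrix[:, cols].sum(axis=1)
            labels[c] = m.features[int(np.argmax(totals))]
        else:
            labels[c] = ""
    return ClusterSolution(
        assignment=sol.assignment,
        n_clusters=sol.n_clusters,
        labels=labels,
        term_scores=term_scores,
    )


def quality(
    sol: ClusterSolution, truth: dict[str, int | str], m: WeightedMatrix
) -> QualityReport:
    """External cluster-quality metrics over documents (terms excluded).

    purity: (1/N) * sum over clusters of the majority true-class size;
    pairwise contamination: fraction of same-cluster document pairs with
    differing true classes (0 if there are no pairs); within-cluster
    similarity: mean pairwise cosine of same-cluster documents in tf-idf
    space (0 if there are no pairs).
    """
    doc_assign = sol.doc_assignment()
    unknown = set(doc_assign) - set(truth)
    if unknown:
        raise ValueError(f"documents missing from truth: {sorted(unknown)[:5]}")

    members: dict[int, list[str]] = {}
    for d, c in doc_assign.items():
        members.setdefault(c, []).append(d)
    n = len(doc_assign)

    purity = sum(
        Counter(truth[d] for d in docs).most_common(1)[0][1] for docs in members.values()
    ) / n

    col = {oid: i for i, (kind, oid) in enumerate(zip(m.column_kinds, m.object_ids)) if kind == DOC}
    mixed = total_pairs = 0
    sims: list[float] = []
    for docs in members.values():
        docs = sorted(docs)
        for i in range(len(docs)):
            for j in range(i + 1, len(docs)):
                total_pairs += 1
                if truth[docs[i]] != truth[docs[j]]:
                    mixed += 1
                sims.append(
                    _cosine_rows(m.matrix[:, col[docs[i]]], m.matrix[:, col[docs[j]]])
                )
    contamination = mixed / total_pairs if total_pairs else 0.0
    wcs = float(np.mean(sims)) if sims else 0.0
    return QualityReport(
        purity=purity, pairwise_contamination=contamination, within_cluster_similarity=wcs
    )


def utc(
    docs: list[TrialProtocol],
    terms: list[CandidateTerm],
    n_clusters: int = 10,
    dim: int | None = None,
    seed: int = 0,
) -> tuple[ClusterSolution, Embedding, WeightedMatrix]:
    """Run the full UTC pipeline: matrix, co-embedding, clustering, labels."""
    m = build_matrix(docs, terms)
    k = dim if dim is not None else default_dim(m)
    e = co_embed(m, k)
    sol = label_clusters(cluster(e, n_clusters, seed), e, m)
    return sol, e, m
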
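"""Semantic relevance scoring of genes against a disease query.

Each gene's functional annotations (GO terms, pathway names, phenotype
descriptions, ...) are flattened into one bag-of-words document. Documents
are weighted by TF-IDF (term frequency times log(N / n_w), with N the
number of documents and n_w the number of documents containing the word),
reduced with latent semantic analysis (truncated SVD of the term-document
matrix M = T S D^T), and each gene is scored by the dot product between
its document vector and a disease query vector expressed in the same
reduced space.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._stem import stem

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def load_stopwords(path=None) -> frozenset[str]:
    """Load the stop-word list (shipped default if ``path`` is None)."""
    if path is None:
        text = (
            resources.files("gwasnet").joinpath("data/stopwords.txt").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    words = set()
    for line in text.splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


@dataclass
class GeneDocument:
    """Bag of stemmed, stop-word-filtered tokens for one gene (or query)."""

    gene: str
    tokens: Counter = field(default_factory=Counter)


def preprocess(
    gene: str, raw_terms: Iterable[str], stopwords: frozenset[str] | set[str]
) -> GeneDocument:
    """Tokenise, lowercase, drop stop words and stem a list of term strings.

    Each raw term may be a multi-word phrase ("insulin secretion"); it is
    split on non-alphanumeric characters. Multiset counts are preserved so
    repeated annotation of the same concept carries weight.
    """
    tokens: Counter = Counter()
    for term in raw_terms:
        for word in _TOKEN_RE.findall(term.lower()):
            if word in stopwords:
                continue
            tokens[stem(word)] += 1
    return GeneDocument(gene=gene, tokens=tokens)


@dataclass
class TermWeightMatrix:
    """TF-IDF weighted term x document matrix over a gene corpus."""

    weights: pd.DataFrame  # terms (rows) x genes (columns)
    idf: pd.Series  # per-term log(N / n_w)
    n_doc_containing: pd.Series
    corpus_size: int


def compute_tfidf(corpus: list[GeneDocument]) -> TermWeightMatrix:
    """Weight each word w in document g as f_{g,w} * log(N / n_w).

    N is the number of documents in the corpus and n_w the number of
    documents containing w (natural logarithm). A word present in every
    document therefore receives weight zero everywhere.
    """
    if not corpus:
        raise ValueError("empty corpus")
    n_docs = len(corpus)
    vocab = sorted({w for doc in corpus for w in doc.tokens})
    genes = [doc.gene for doc in corpus]
    counts = pd.DataFrame(0.0, index=vocab, columns=genes)
    for doc in corpus:
        if doc.tokens:
            col = pd.Series(doc.tokens, dtype=float)
            counts.loc[col.index, doc.gene] = col.values
    n_w = (counts > 0).sum(axis=1).astype(float)
    idf = np.log(n_docs / n_w)
    weights = counts.mul(idf, axis=0)
    return TermWeightMatrix(
        weights=weights,
        idf=idf,
        n_doc_containing=n_w.astype(int),
        corpus_size=n_docs,
    )


@dataclass
class LsaModel:
    """Truncated SVD of the TF-IDF matrix, M ~= T_d S_d D_d^T."""

    term_matrix: np.ndarray  # T_d, terms x d
    singular_values: np.ndarray  # S_d diagonal, length d
    document_matrix: np.ndarray  # D_d, documents x d
    n_dims: int
    terms: pd.Index
    documents: pd.Index


def fit_lsa(matrix: TermWeightMatrix, share: float = 0.5) -> LsaModel:
    """SVD of the weight matrix keeping the leading singular dimensions.

    The retained dimensionality is the smallest d whose singular values
    account for at least ``share`` of the singular-value total (the
    dimension-share rule of the R ``lsa`` package).
    """
    if matrix.weights.shape[1] < 2:
        raise ValueError("LSA requires at least 2 documents")
    m = matrix.weights.to_numpy(dtype=float)
    t, s, dt = np.linalg.svd(m, full_matrices=False)
    tol = max(m.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if rank == 0:
        raise ValueError("degenerate corpus: rank-0 weight matrix")
    s = s[:rank]
    frac = np.cumsum(s) / np.sum(s)
    n_dims = int(np.searchsorted(frac, share) + 1)
    n_dims = min(n_dims, rank)
    return LsaModel(
        term_matrix=t[:, :n_dims],
        singular_values=s[:n_dims],
        document_matrix=dt[:n_dims, :].T,
        n_dims=n_dims,
        terms=matrix.weights.index,
        documents=matrix.weights.columns,
    )


@dataclass
class SemanticScore:
    gene: str
    score: float


def _query_vector(matrix: TermWeightMatrix, query: GeneDocument) -> np.ndarray:
    """TF-IDF weight the query against the corpus vocabulary/IDF."""
    q = np.zeros(len(matrix.weights.index))
    lookup = {t: i for i, t in enumerate(matrix.weights.index)}
    n_oov = 0
    for word, count in query.tokens.items():
        i = lookup.get(word)
        if i is None:
            n_oov += 1
            continue
        q[i] = count * matrix.idf.iloc[i]
    if query.tokens and not np.any(q):
        warnings.warn(
            "query shares no (non-saturated) vocabulary with the corpus; "
            "all semantic scores will be 0",
            stacklevel=3,
        )
    return q


def score_genes(
    model: LsaModel,
    matrix: TermWeightMatrix,
    query: GeneDocument,
    space: str = "reduced",
) -> list[SemanticScore]:
    """Dot-product similarity S_{g,q} between each gene and the query.

    In the default reduced space the query is folded in as q_d = T_d^T q
    and compared with document coordinates S_d D_d^T; at full rank this
    reproduces the raw TF-IDF dot products exactly. ``space="raw"``
    computes the dot product on the unreduced TF-IDF vectors.
    """
    q = _query_vector(matrix, query)
    if space == "raw":
        scores = q @ matrix.weights.to_numpy(dtype=float)
    elif space == "reduced":
        q_d = model.term_matrix.T @ q
        doc_coords = model.singular_values[:, None] * model.document_matrix.T
        scores = q_d @ doc_coords
    else:
        raise ValueError(f"unknown space {space!r}")
    return [
        SemanticScore(gene=g, score=float(s))
        for g, s in zip(matrix.weights.columns, scores)
    ]


def semantic_scores_from_corpus(
    corpus: Mapping[str, list[str]],
    query_terms: list[str],
    stopwords: frozenset[str] | None = None,
    share: float = 0.5,
    space: str = "reduced",
) -> dict[str, float]:
    """Convenience wrapper: raw corpus + query terms -> {gene: score}."""
    if stopwords is None:
        stopwords = load_stopwords()
    docs = [preprocess(g, terms, stopwords) for g, terms in corpus.items()]
    matrix = compute_tfidf(docs)
    model = fit_lsa(matrix, share=share)
    query = preprocess("__query__", query_terms, stopwords)
    return {r.gene: r.score for r in score_genes(model, matrix, query, space=space)}
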
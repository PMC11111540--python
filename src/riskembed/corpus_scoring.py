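"""Applying a fitted risk model to a document corpus.

Three analyses on a headline corpus:

* *coverage* — the proportion of documents containing at least 1, 2, or 3
  distinct words from a model's scorable vocabulary (a vocabulary-size
  criterion orthogonal to predictive accuracy);
* *riskiness scoring* — per-document mean of the predicted word riskiness
  over covered words, min-max rescaled across documents onto [-100, 100]
  (all-equal means map to 0);
* *document-term matrix* — raw-count tf weighted by idf = log(N / df),
  suitable as input to a 2-D projection (e.g. UMAP) supplied as a pluggable
  reducer.

Tokenization is deliberately plain: lowercase, strip punctuation,
whitespace-split.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import HeadlineCorpus

__all__ = [
    "CoverageReport",
    "RiskinessScores",
    "DocumentTermMatrix",
    "tokenize",
    "coverage",
    "score_documents",
    "tfidf_matrix",
    "project_documents",
]

_PUNCT = re.compile(r"[^\w\s]|_", flags=re.UNICODE)


@dataclass
class CoverageReport:
    """Proportion of documents with at least 1 / 2 / 3 distinct
    in-vocabulary words."""

    proportions: dict[int, float]
    n_documents: int

    def __post_init__(self) -> None:
        p = self.proportions
        if not (1.0 >= p[1] >= p[2] >= p[3] >= 0.0):
            raise ValueError("coverage proportions must be monotone in the threshold")


@dataclass
class RiskinessScores:
    """Per-document riskiness: raw mean word score, the min-max scaled score
    on [-100, 100], and the covered word count.  Documents with no scored
    word are flagged unscored (NaN scores)."""

    df: pd.DataFrame  # columns: guid, mean_riskiness, scaled_riskiness, covered_words


@dataclass
class DocumentTermMatrix:
    """Sparse document x token tf-idf matrix with its vocabulary."""

    matrix: sp.csr_matrix
    tokens: list[str]
    guids: list[str]


def tokenize(document: str) -> list[str]:
    """Lowercase, strip punctuation (replaced by spaces), split on
    whitespace."""
    return _PUNCT.sub(" ", document.lower()).split()


def coverage(corpus: HeadlineCorpus, vocabulary: set[str]) -> CoverageReport:
    """Coverage of a vocabulary over headline titles at thresholds 1, 2, 3.

    Counts *distinct* in-vocabulary tokens per document (a headline
    repeating one risk word still counts 1).
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    vocab = set(vocabulary)
    counts = np.array(
        [len(set(tokenize(title)) & vocab) for title in corpus.titles]
    )
    n = len(counts)
    return CoverageReport(
        proportions={k: float((counts >= k).sum() / n) for k in (1, 2, 3)},
        n_documents=n,
    )


def score_documents(
    corpus: HeadlineCorpus, word_scores: Mapping[str, float]
) -> RiskinessScores:
    """Predicted riskiness per document.

    Each document's raw score is the mean predicted riskiness of its
    distinct scored words; raw means are affinely rescaled across scoreable
    documents so the minimum maps to -100 and the maximum to +100 (all
    equal -> 0).  Documents containing no scored word get NaN scores.
    """
    means = []
    covered = []
    for title in corpus.titles:
        toks = sorted(set(tokenize(title)) & set(word_scores))
        covered.append(len(toks))
        means.append(np.mean([word_scores[t] for t in toks]) if toks else np.nan)
    means = np.array(means, dtype=float)
    scoreable = ~np.isnan(means)
    if not scoreable.any():
        raise ValueError("no document contains a scored word")
    lo, hi = np.nanmin(means), np.nanmax(means)
    scaled = np.full_like(means, np.nan)
    if hi > lo:
        scaled[scoreable] = -100.0 + 200.0 * (means[scoreable] - lo) / (hi - lo)
    else:
        scaled[scoreable] = 0.0
    return RiskinessScores(
        df=pd.DataFrame(
            {
                "guid": corpus.guids,
                "mean_riskiness": means,
                "scaled_riskiness": scaled,
                "covered_words": covered,
            }
        )
    )


def tfidf_matrix(corpus: HeadlineCorpus) -> DocumentTermMatrix:
    """Document x token matrix with tf = raw within-document count and
    idf = log(N / df).

    A token present in every document has idf exactly 0 (a zero column);
    tokens absent from a document contribute exact zeros.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    docs = [tokenize(t) for t in corpus.titles]
    vocab = sorted({tok for doc in docs for tok in doc})
    index = {tok: j for j, tok in enumerate(vocab)}
    rows, cols, data = [], [], []
    for i, doc in enumerate(docs):
        seen: dict[int, int] = {}
        for tok in doc:
            j = index[tok]
            seen[j] = seen.get(j, 0) + 1
        for j, tf in seen.items():
            rows.append(i)
            cols.append(j)
            data.append(tf)
    tf = sp.csr_matrix(
        (np.array(data, dtype=float), (rows, cols)), shape=(len(docs), len(vocab))
    )
    df = np.asarray((tf > 0).sum(axis=0)).ravel()
    idf = np.log(len(docs) / np.maximum(df, 1))
    out = tf.multiply(idf).tocsr()
    out.eliminate_zeros()
    return DocumentTermMatrix(matrix=out, tokens=vocab, guids=corpus.guids)


def project_documents(
    dtm: DocumentTermMatrix,
    reducer: Callable[[sp.csr_matrix], np.ndarray],
) -> pd.DataFrame:
    """Project the tf-idf matrix to 2-D with a user-supplied reducer (e.g. a
    fitted UMAP's ``fit_transform``).  The reducer must return one (x, y)
    pair per document."""
    coords = np.asarray(reducer(dtm.matrix), dtype=float)
    if coords.shape != (len(dtm.guids), 2):
        raise ValueError(
            f"reducer returned shape {coords.shape}, expected ({len(dtm.guids)}, 2)"
        )
    return pd.DataFrame({"guid": dtm.guids, "x": coords[:, 0], "y": coords[:, 1]})
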
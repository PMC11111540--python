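"""Predictor-matrix construction: term lookup, groupwise scaling, and
feature-block concatenation.

Ensembles are built by horizontally concatenating feature blocks (e.g. two
300-dimensional embeddings give a 600-dimensional ensemble; adding the nine
psychometric items gives 609 predictors).  Because the downstream elastic
net does not standardize predictors, each non-reference block is multiplied
by a single scalar so that its *mean column standard deviation* equals that
of a reference block (conventionally the psychometric block).  This
equalizes the average regularization pressure per block while leaving the
within-block variance profile — informative after an SVD — untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assoc_embed import Embedding

__all__ = [
    "FeatureBlock",
    "EnsembleMatrix",
    "lookup_terms",
    "groupwise_scale",
    "concat",
    "mean_column_sd",
]


@dataclass
class FeatureBlock:
    """A named (terms x dims) feature matrix from an embedding or the
    psychometric items."""

    name: str
    source: str  # "embedding" or "psychometric"
    terms: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.source not in {"embedding", "psychometric"}:
            raise ValueError(f"unknown block source {self.source!r}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError(f"block {self.name!r} has duplicate terms")
        if self.matrix.shape[0] != len(self.terms):
            raise ValueError(f"block {self.name!r}: matrix/term length mismatch")
        if not np.isfinite(self.matrix).all():
            raise ValueError(f"block {self.name!r} contains non-finite values")


@dataclass
class EnsembleMatrix:
    """Concatenated design matrix with named column spans per block."""

    terms: list[str]
    matrix: np.ndarray
    block_spans: dict[str, tuple[int, int]]

    def block(self, name: str) -> np.ndarray:
        start, stop = self.block_spans[name]
        return self.matrix[:, start:stop]


def mean_column_sd(matrix: np.ndarray) -> float:
    """Mean over columns of the sample (n-1 denominator) standard
    deviation."""
    return float(np.mean(np.std(matrix, axis=0, ddof=1)))


def lookup_terms(
    embedding: Embedding,
    terms: list[str],
    bigram_policy: str = "mean_of_words",
) -> FeatureBlock:
    """Resolve risk terms (single words or bigrams) against an embedding.

    Policies
    --------
    ``mean_of_words``
        multi-word terms get the arithmetic mean of their constituent word
        vectors; terms with any missing word are dropped.
    ``phrase_then_mean``
        try the underscore-joined phrase token first, fall back to the mean
        of words.
    ``strict``
        only exact vocabulary matches resolve (vocabulary-intersection
        behavior); multi-word terms resolve only via their underscore-joined
        phrase token.
    """
    if not terms:
        raise ValueError("no terms to look up")
    if bigram_policy not in {"mean_of_words", "phrase_then_mean", "strict"}:
        raise ValueError(f"unknown bigram_policy {bigram_policy!r}")
    resolved: list[str] = []
    vectors: list[np.ndarray] = []
    for term in terms:
        words = term.split()
        phrase = "_".join(words)
        vec: np.ndarray | None = None
        if len(words) == 1:
            if term in embedding:
                vec = embedding.get(term)
        elif bigram_policy == "strict":
            if phrase in embedding:
                vec = embedding.get(phrase)
        else:
            if bigram_policy == "phrase_then_mean" and phrase in embedding:
                vec = embedding.get(phrase)
            elif all(w in embedding for w in words):
                vec = np.mean([embedding.get(w) for w in words], axis=0)
        if vec is not None:
            resolved.append(term)
            vectors.append(vec)
    if not resolved:
        raise ValueError("no term resolvable against the embedding vocabulary")
    return FeatureBlock(
        name="embedding", source="embedding", terms=resolved, matrix=np.vstack(vectors)
    )


def groupwise_scale(
    blocks: list[FeatureBlock], reference: FeatureBlock
) -> list[FeatureBlock]:
    """Rescale each block by one scalar so its mean column SD equals the
    reference's.

    The reference block itself is never rescaled (its scalar is exactly 1).
    Columns are *not* individually standardized.  Idempotent.
    """
    ref_sd = mean_column_sd(reference.matrix)
    if ref_sd <= 0:
        raise ValueError("reference block has zero mean column SD")
    out: list[FeatureBlock] = []
    for block in blocks:
        if block.terms != reference.terms:
            raise ValueError(
                f"block {block.name!r} terms differ from reference terms"
            )
        sd = mean_column_sd(block.matrix)
        if sd <= 0:
            raise ValueError(f"block {block.name!r} has zero variance in all columns")
        out.append(
            FeatureBlock(
                name=block.name,
                source=block.source,
                terms=list(block.terms),
                matrix=block.matrix * (ref_sd / sd),
            )
        )
    return out


def concat(blocks: list[FeatureBlock]) -> EnsembleMatrix:
    """Horizontally concatenate feature blocks into one design matrix with
    recorded column spans."""
    if not blocks:
        raise ValueError("no blocks to concatenate")
    terms = blocks[0].terms
    for block in blocks[1:]:
        if block.terms != terms:
            offending = sorted(set(block.terms) ^ set(terms))
            raise ValueError(
                f"term mismatch between blocks {blocks[0].name!r} and "
                f"{block.name!r}: {offending[:10]}"
            )
    spans: dict[str, tuple[int, int]] = {}
    start = 0
    for block in blocks:
        width = block.matrix.shape[1]
        if block.name in spans:
            raise ValueError(f"duplicate block name {block.name!r}")
        spans[block.name] = (start, start + width)
        start += width
    return EnsembleMatrix(
        terms=list(terms),
        matrix=np.hstack([b.matrix for b in blocks]),
        block_spans=spans,
    )
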
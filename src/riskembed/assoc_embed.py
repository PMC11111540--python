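"""Free-association embeddings via PPMI + truncated SVD.

The training procedure has three steps:

1. aggregate free-association responses into a cue x response count matrix
   ``M``, keeping only responses whose total count exceeds a frequency
   threshold (default: strictly greater than 5);
2. reweight ``M`` into ``M'`` by positive pointwise mutual information,
   PPMI(c, r) = max(0, log[(n_cr / N) / ((n_c. / N)(n_.r / N))]), the standard
   association-strength transform in computational semantics (natural log;
   cells with zero joint count stay exactly zero);
3. factorize ``M' ~ U S V*`` by rank-k truncated SVD and keep the rows of
   ``U S`` as the cue embedding (``V*`` is discarded).

Sign indeterminacy of the SVD is resolved deterministically: each left
singular vector is flipped so its largest-magnitude entry is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .io_formats import AssociationTable

__all__ = [
    "CueResponseMatrix",
    "PpmiMatrix",
    "Embedding",
    "build_cue_response_matrix",
    "ppmi_transform",
    "svd_embed",
    "train_association_embedding",
]


@dataclass
class CueResponseMatrix:
    """Cue x response count matrix with ordered row/column token labels."""

    cues: list[str]
    responses: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        if len(set(self.cues)) != len(self.cues):
            raise ValueError("duplicate cue labels")
        if len(set(self.responses)) != len(self.responses):
            raise ValueError("duplicate response labels")
        if self.counts.shape != (len(self.cues), len(self.responses)):
            raise ValueError("count matrix shape does not match label lists")
        if (self.counts.data < 0).any():
            raise ValueError("negative counts")
        if self.counts.sum() <= 0:
            raise ValueError("count matrix has zero total count")


@dataclass
class PpmiMatrix:
    """Nonnegative PPMI-transformed matrix sharing labels with its source
    count matrix; entries are exactly zero wherever the joint count was."""

    cues: list[str]
    responses: list[str]
    values: sp.csr_matrix


@dataclass
class Embedding:
    """Token -> k-dimensional vector map backed by a dense matrix."""

    tokens: list[str]
    vectors: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.tokens):
            raise ValueError("vector matrix shape does not match token list")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in embedding")
        if not np.isfinite(self.vectors).all():
            raise ValueError("non-finite values in embedding")
        self._index = {t: i for i, t in enumerate(self.tokens)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __len__(self) -> int:
        return len(self.tokens)

    def get(self, token: str) -> np.ndarray:
        """The vector of ``token`` (KeyError if absent)."""
        return self.vectors[self._index[token]]

    def subset(self, tokens: list[str]) -> "Embedding":
        idx = [self._index[t] for t in tokens]
        return Embedding(tokens=list(tokens), vectors=self.vectors[idx])


def build_cue_response_matrix(
    table: AssociationTable, min_response_freq: int = 5
) -> CueResponseMatrix:
    """Build the cue x response count matrix, restricting columns to
    responses whose total count across all cues is *strictly greater than*
    ``min_response_freq``.
    """
    if min_response_freq < 1:
        raise ValueError("min_response_freq must be >= 1")
    df = table.df
    totals = df.groupby("response")["count"].sum()
    kept = set(totals.index[totals > min_response_freq])
    if not kept:
        raise ValueError(
            f"no response exceeds the frequency threshold {min_response_freq}"
        )
    cues = sorted(df["cue"].unique())
    responses = sorted(kept)
    cue_idx = {c: i for i, c in enumerate(cues)}
    resp_idx = {r: j for j, r in enumerate(responses)}
    sub = df[df["response"].isin(kept)]
    rows = sub["cue"].map(cue_idx).to_numpy()
    cols = sub["response"].map(resp_idx).to_numpy()
    counts = sp.csr_matrix(
        (sub["count"].to_numpy(dtype=float), (rows, cols)),
        shape=(len(cues), len(responses)),
    )
    return CueResponseMatrix(cues=cues, responses=responses, counts=counts)


def ppmi_transform(M: CueResponseMatrix) -> PpmiMatrix:
    """Positive pointwise mutual information of a count matrix.

    Only cells with a positive joint count are evaluated; the log never sees
    a zero.  Natural logarithm.
    """
    counts = M.counts.tocoo()
    if (counts.data < 0).any():
        raise ValueError("negative counts")
    total = counts.data.sum()
    row_sums = np.asarray(M.counts.sum(axis=1)).ravel()
    col_sums = np.asarray(M.counts.sum(axis=0)).ravel()
    # PMI = log(n_cr * N / (n_c. * n_.r)); clip negatives to zero.
    pmi = np.log(counts.data * total / (row_sums[counts.row] * col_sums[counts.col]))
    ppmi = np.maximum(pmi, 0.0)
    values = sp.csr_matrix((ppmi, (counts.row, counts.col)), shape=M.counts.shape)
    values.eliminate_zeros()
    return PpmiMatrix(cues=list(M.cues), responses=list(M.responses), values=values)


def svd_embed(Mp: PpmiMatrix, k: int) -> Embedding:
    """Rank-k truncated SVD embedding ``U S`` of a PPMI matrix.

    Singular values come out in descending order; signs are fixed so the
    largest-magnitude entry of each left singular vector is positive, which
    makes the output deterministic across linear-algebra backends (exact ties
    among singular values keep the backend's ordering).
    """
    n_rows, n_cols = Mp.values.shape
    if not 1 <= k <= min(n_rows, n_cols):
        raise ValueError(f"k={k} outside [1, {min(n_rows, n_cols)}]")
    dense = Mp.values.toarray()
    U, s, _ = scipy.linalg.svd(dense, full_matrices=False)
    U = U[:, :k]
    s = s[:k]
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    U = U * flip
    return Embedding(tokens=list(Mp.cues), vectors=U * s)


def train_association_embedding(
    table: AssociationTable, k: int = 300, min_response_freq: int = 5
) -> Embedding:
    """Convenience wrapper running the full three-step training procedure."""
    M = build_cue_response_matrix(table, min_response_freq=min_response_freq)
    return svd_embed(ppmi_transform(M), k)
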
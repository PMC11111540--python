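"""Risk-vocabulary generation by combined human and machine voting.

A candidate word enters the preliminary risk list when it receives either
two human votes, or one human vote and at least two out of three machine
votes.  A machine vote comes from an embedding: the candidate's cosine
similarity to a seed list of previously studied risks is computed, and the
acceptance threshold is set so the machine's positive rate matches the
human raters' positive rate.  The preliminary list is then filtered by
dropping very-low-frequency words, keeping one word per lemma (e.g. "ashes"
vs "ash"), and removing sensitive words.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assoc_embed import Embedding

__all__ = [
    "CandidateRecord",
    "machine_vote",
    "combine_votes",
    "filter_candidates",
]


@dataclass
class CandidateRecord:
    """A candidate word with its votes and filtering attributes."""

    word: str
    human_votes: int
    machine_votes: int
    frequency: float
    lemma: str
    sensitive: bool = False

    def __post_init__(self) -> None:
        if self.human_votes < 0:
            raise ValueError("human_votes must be nonnegative")
        if not 0 <= self.machine_votes <= 3:
            raise ValueError("machine_votes must lie in [0, 3]")
        if self.frequency < 0:
            raise ValueError("frequency must be nonnegative")


def machine_vote(
    candidates: list[str],
    embedding: Embedding,
    seed_risks: list[str],
    human_positive_rate: float,
    similarity_stat: str = "max",
) -> np.ndarray:
    """One embedding's boolean vote per candidate.

    Each candidate is scored by the chosen statistic (``max`` or ``mean``)
    of its cosine similarities to the seed risks; the threshold is the
    empirical (1 - ``human_positive_rate``) quantile of the candidate
    scores, so the machine's positive rate matches the human rate up to
    ties.  Candidates missing from the embedding vocabulary score -inf and
    never vote positive.
    """
    if not seed_risks:
        raise ValueError("empty seed risk list")
    if not 0 < human_positive_rate < 1:
        raise ValueError("human_positive_rate must lie in (0, 1)")
    if similarity_stat not in {"max", "mean"}:
        raise ValueError(f"unknown similarity_stat {similarity_stat!r}")
    missing = [s for s in seed_risks if s not in embedding]
    if missing:
        raise ValueError(f"seed risks missing from embedding: {missing[:5]}")
    seed_vecs = np.vstack([embedding.get(s) for s in seed_risks])
    seed_unit = seed_vecs / np.linalg.norm(seed_vecs, axis=1, keepdims=True)
    scores = np.full(len(candidates), -np.inf)
    for i, word in enumerate(candidates):
        if word not in embedding:
            continue
        vec = embedding.get(word)
        nrm = np.linalg.norm(vec)
        if nrm == 0:
            continue
        sims = seed_unit @ (vec / nrm)
        scores[i] = sims.max() if similarity_stat == "max" else sims.mean()
    # Threshold at the k-th largest score, k = round(rate * n): the positive
    # rate then equals the requested rate up to ties.
    k = max(1, int(round(human_positive_rate * len(candidates))))
    threshold = np.sort(scores)[::-1][k - 1]
    if not np.isfinite(threshold):
        return np.zeros(len(candidates), dtype=bool)
    return scores >= threshold


def combine_votes(human_votes: int, machine_votes: int) -> bool:
    """The inclusion rule: accepted iff two human votes, or one human vote
    plus at least two of three machine votes."""
    if human_votes < 0 or machine_votes < 0:
        raise ValueError("votes must be nonnegative")
    return human_votes >= 2 or (human_votes == 1 and machine_votes >= 2)


def filter_candidates(
    accepted: list[CandidateRecord],
    min_frequency: float,
    sensitive_list: set[str] | None = None,
) -> list[str]:
    """Final filters on the preliminary list.

    Drops words with frequency below ``min_frequency``, keeps exactly one
    word per lemma (the most frequent; lexicographically first on ties),
    and drops words in ``sensitive_list`` or flagged sensitive.  The output
    is sorted, hence deterministic regardless of input order.
    """
    sensitive = set(sensitive_list or ())
    frequent = [r for r in accepted if r.frequency >= min_frequency]
    by_lemma: dict[str, CandidateRecord] = {}
    for rec in frequent:
        if not rec.lemma:
            raise ValueError(f"candidate {rec.word!r} has an empty lemma")
        best = by_lemma.get(rec.lemma)
        if best is None or (rec.frequency, _neg(rec.word)) > (best.frequency, _neg(best.word)):
            by_lemma[rec.lemma] = rec
    survivors = [
        rec.word
        for rec in by_lemma.values()
        if not rec.sensitive and rec.word not in sensitive
    ]
    return sorted(survivors)


class _neg(str):
    """Reverses string comparison so (freq, _neg(word)) max-selection breaks
    frequency ties by *smallest* word."""

    def __lt__(self, other) -> bool:  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:
        return str.__lt__(self, other)
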
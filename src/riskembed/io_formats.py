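"""Readers and writers for the external formats the pipeline touches.

Formats handled here:

* free-association tables (long ``cue,response,count`` triples, or the wide
  participant-level export with one cue and up to three response columns),
* word vectors in the word2vec *text* format (``"n dim"`` header, then one
  token plus ``dim`` floats per line),
* risk-rating tables (mean risk on a -100..100 scale plus nine psychometric
  item means on a 1..7 scale),
* psycholinguistic word-norm tables (affect / concreteness / frequency
  groups),
* news-headline corpora (title, publication date, GUID, link, description).

All readers apply a single token-normalization policy: Unicode NFC plus
surrounding-whitespace stripping, with lowercasing off by default and
switchable uniformly via ``lowercase=True``.  CSV files are comma-separated
UTF-8 with a header row.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - type-only import, avoids a cycle
    from .assoc_embed import Embedding

__all__ = [
    "PSYCHOMETRIC_ITEMS",
    "NORM_GROUPS",
    "AssociationTable",
    "RatingsTable",
    "NormTable",
    "HeadlineCorpus",
    "normalize_token",
    "read_associations",
    "write_associations",
    "read_word_vectors",
    "write_word_vectors",
    "read_ratings",
    "write_ratings",
    "read_norms",
    "write_norms",
    "read_headlines",
    "write_headlines",
]

#: The nine bipolar psychometric items rated on a 1..7 scale.
PSYCHOMETRIC_ITEMS: tuple[str, ...] = (
    "voluntary_involuntary",
    "immediate_delayed",
    "known_unknown",
    "known_unknown_science",
    "controllable_uncontrollable",
    "new_old",
    "chronic_catastrophic",
    "calm_dread",
    "notfatal_fatal",
)

#: Canonical word-norm names and their psychological group.
NORM_GROUPS: dict[str, str] = {
    **{
        name: "affect"
        for name in (
            "valence",
            "dominance",
            "arousal",
            "fear",
            "anger",
            "sadness",
            "disgust",
            "joy",
            "trust",
            "surprise",
            "anticipation",
        )
    },
    **{name: "frequency" for name in ("age of acquisition", "familiarity", "frequency")},
    **{name: "concreteness" for name in ("concreteness", "imageability")},
}

_VALID_NORM_GROUPS = frozenset({"affect", "concreteness", "frequency"})

#: Cell values treated as "no response" in the wide association dialect.
DEFAULT_MISSING_SENTINELS = frozenset({"", "NA", "N/A", "—", "No more responses", "Unknown word"})


def normalize_token(token: str, lowercase: bool = False) -> str:
    """Normalize a token: Unicode NFC, strip surrounding whitespace,
    optionally lowercase."""
    out = unicodedata.normalize("NFC", str(token)).strip()
    return out.lower() if lowercase else out


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class AssociationTable:
    """Aggregated free-association counts: one row per (cue, response) pair.

    ``df`` has columns ``cue``, ``response``, ``count`` with counts >= 1,
    unique pairs, and deterministic (cue, response) ordering.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = {"cue", "response", "count"} - set(df.columns)
        if missing:
            raise FormatError(f"association table missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise FormatError("association table is empty")
        if (df["count"] < 1).any():
            raise FormatError("association counts must be >= 1")
        if (df["cue"].str.len() == 0).any() or (df["response"].str.len() == 0).any():
            raise FormatError("empty cue or response token")
        if df.duplicated(["cue", "response"]).any():
            raise FormatError("duplicate (cue, response) pairs after aggregation")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int]], lowercase: bool = False
    ) -> "AssociationTable":
        """Build a table from raw (cue, response, count) triples, normalizing
        tokens and aggregating duplicate pairs."""
        rows = [
            (normalize_token(c, lowercase), normalize_token(r, lowercase), int(n))
            for c, r, n in records
        ]
        df = pd.DataFrame(rows, columns=["cue", "response", "count"])
        df = (
            df.groupby(["cue", "response"], as_index=False, sort=True)["count"]
            .sum()
            .sort_values(["cue", "response"], kind="mergesort")
            .reset_index(drop=True)
        )
        return cls(df)

    @property
    def cues(self) -> list[str]:
        return sorted(self.df["cue"].unique())

    @property
    def responses(self) -> list[str]:
        return sorted(self.df["response"].unique())


@dataclass
class RatingsTable:
    """Per-risk mean risk rating (-100..100) and nine psychometric item means
    (1..7), with split-half reliabilities of both rating types."""

    df: pd.DataFrame
    reliability_risk: float = 0.995
    reliability_psych: float = 0.97

    def __post_init__(self) -> None:
        df = self.df
        required = {"risk_term", "risk_mean", *PSYCHOMETRIC_ITEMS}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"ratings table missing columns: {sorted(missing)}")
        dup = df["risk_term"][df["risk_term"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate risk terms: {sorted(dup.unique())[:5]}")
        bad = df.loc[(df["risk_mean"] < -100) | (df["risk_mean"] > 100), "risk_term"]
        if len(bad):
            raise FormatError(f"risk_mean out of [-100, 100] for terms: {list(bad[:5])}")
        for item in PSYCHOMETRIC_ITEMS:
            bad = df.loc[(df[item] < 1) | (df[item] > 7), "risk_term"]
            if len(bad):
                raise FormatError(f"{item} out of [1, 7] for terms: {list(bad[:5])}")
        for name in ("reliability_risk", "reliability_psych"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise FormatError(f"{name} must lie in [0, 1], got {val}")

    @property
    def terms(self) -> list[str]:
        return list(self.df["risk_term"])

    def psychometric_matrix(self) -> np.ndarray:
        """The terms x 9 matrix of psychometric item means."""
        return self.df[list(PSYCHOMETRIC_ITEMS)].to_numpy(dtype=float)


@dataclass
class NormTable:
    """Per-token psycholinguistic norms, each norm assigned to exactly one of
    the groups affect / concreteness / frequency."""

    df: pd.DataFrame
    groups: Mapping[str, str] = field(default_factory=lambda: dict(NORM_GROUPS))

    def __post_init__(self) -> None:
        if "token" not in self.df.columns:
            raise FormatError("norm table missing 'token' column")
        if self.df["token"].duplicated().any():
            raise FormatError("duplicate tokens in norm table")
        self.groups = dict(self.groups)
        for norm in self.norm_names:
            if norm not in self.groups:
                raise FormatError(f"unknown norm group for norm {norm!r}")
            if self.groups[norm] not in _VALID_NORM_GROUPS:
                raise FormatError(
                    f"norm {norm!r} assigned to invalid group {self.groups[norm]!r}"
                )

    @property
    def norm_names(self) -> list[str]:
        return [c for c in self.df.columns if c != "token"]

    @property
    def tokens(self) -> list[str]:
        return list(self.df["token"])


@dataclass
class HeadlineCorpus:
    """News-headline documents with title, publication date, GUID, link and
    description."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"title", "publication_date", "guid", "link", "description"}
        missing = required - set(self.df.columns)
        if missing:
            raise FormatError(f"headline corpus missing columns: {sorted(missing)}")
        if (self.df["title"].astype(str).str.strip().str.len() == 0).any():
            raise FormatError("empty headline title")
        if self.df["guid"].duplicated().any():
            raise FormatError("duplicate GUIDs in headline corpus")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def titles(self) -> list[str]:
        return list(self.df["title"].astype(str))

    @property
    def guids(self) -> list[str]:
        return list(self.df["guid"].astype(str))


# ---------------------------------------------------------------------------
# Free-association tables
# ---------------------------------------------------------------------------


def read_associations(
    path: str | Path,
    dialect: str = "long_triple",
    lowercase: bool = False,
    missing_sentinels: Iterable[str] = DEFAULT_MISSING_SENTINELS,
) -> AssociationTable:
    """Read a free-association file and aggregate it into unique
    (cue, response, count) records.

    Parameters
    ----------
    path
        CSV file. ``long_triple`` expects columns ``cue, response, count``;
        ``swow_wide`` expects one participant row per line with a ``cue``
        column and response columns ``R1, R2, R3`` (missing responses are
        empty cells or sentinel strings and are skipped).
    dialect
        ``"long_triple"`` or ``"swow_wide"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long_triple":
        df = pd.read_csv(path, dtype={"cue": str, "response": str}, keep_default_na=False)
        missing = {"cue", "response", "count"} - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        counts = pd.to_numeric(df["count"], errors="coerce")
        bad = counts.isna() | (counts < 1) | (counts != counts.round())
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 one-based
            raise FormatError(f"{path}: malformed count on line {line}")
        records = zip(df["cue"], df["response"], counts.astype(int))
        return AssociationTable.from_records(records, lowercase=lowercase)
    if dialect == "swow_wide":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if "cue" not in df.columns:
            raise FormatError(f"{path}: swow_wide file lacks a 'cue' column")
        resp_cols = [c for c in df.columns if c.upper() in {"R1", "R2", "R3"}]
        if not resp_cols:
            raise FormatError(f"{path}: swow_wide file lacks response columns R1..R3")
        sentinels = set(missing_sentinels)
        records: list[tuple[str, str, int]] = []
        for i, row in enumerate(df.itertuples(index=False)):
            cue = normalize_token(getattr(row, "cue"), lowercase)
            if not cue:
                raise FormatError(f"{path}: empty cue on line {i + 2}")
            for col in resp_cols:
                raw = getattr(row, col)
                if raw is None or raw.strip() in sentinels:
                    continue
                records.append((cue, raw, 1))
        if not records:
            raise FormatError(f"{path}: no responses after sentinel filtering")
        return AssociationTable.from_records(records, lowercase=lowercase)
    raise FormatError(f"unknown association dialect: {dialect!r}")


def write_associations(table: AssociationTable, path: str | Path) -> None:
    """Write an association table as a long_triple CSV."""
    table.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# word2vec text format
# ---------------------------------------------------------------------------


def read_word_vectors(path: str | Path) -> "Embedding":
    """Read an embedding from word2vec text format.

    The first line is ``"<n_tokens> <dim>"``; each subsequent line is a token
    followed by ``dim`` whitespace-separated floats.  Duplicate tokens and
    per-row dimension mismatches are errors.
    """
    from .assoc_embed import Embedding

    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: malformed word2vec header")
        n_tokens, dim = int(header[0]), int(header[1])
        tokens: list[str] = []
        seen: set[str] = set()
        vectors = np.empty((n_tokens, dim), dtype=float)
        for i in range(n_tokens):
            parts = fh.readline().split()
            if len(parts) != dim + 1:
                raise FormatError(f"{path}: dimension mismatch on line {i + 2}")
            token = normalize_token(parts[0])
            if token in seen:
                raise FormatError(f"{path}: duplicate token {token!r} on line {i + 2}")
            seen.add(token)
            tokens.append(token)
            vectors[i] = [float(x) for x in parts[1:]]
    return Embedding(tokens=tokens, vectors=vectors)


def write_word_vectors(embedding: "Embedding", path: str | Path) -> None:
    """Write an embedding in word2vec text format (round-trips through
    :func:`read_word_vectors` within 1e-6)."""
    if len(embedding.tokens) == 0:
        raise FormatError("cannot write an empty embedding")
    for token in embedding.tokens:
        if any(ch.isspace() for ch in token):
            raise FormatError(
                f"token {token!r} contains whitespace; word2vec text cannot represent it"
            )
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(embedding.tokens)} {embedding.dim}\n")
        for token, vec in zip(embedding.tokens, embedding.vectors):
            fh.write(token + " " + " ".join(format(v, ".8g") for v in vec) + "\n")


# ---------------------------------------------------------------------------
# Ratings, norms, headlines
# ---------------------------------------------------------------------------


def read_ratings(path: str | Path, lowercase: bool = False) -> RatingsTable:
    """Read a per-risk ratings CSV: ``risk_term, risk_mean`` plus the nine
    psychometric item columns, optionally ``reliability_risk`` /
    ``reliability_psych`` columns (constant)."""
    df = pd.read_csv(path)
    df["risk_term"] = df["risk_term"].map(lambda t: normalize_token(t, lowercase))
    kwargs = {}
    for rel in ("reliability_risk", "reliability_psych"):
        if rel in df.columns:
            kwargs[rel] = float(df[rel].iloc[0])
            df = df.drop(columns=[rel])
    return RatingsTable(df, **kwargs)


def write_ratings(ratings: RatingsTable, path: str | Path) -> None:
    df = ratings.df.copy()
    df["reliability_risk"] = ratings.reliability_risk
    df["reliability_psych"] = ratings.reliability_psych
    df.to_csv(path, index=False)


def read_norms(
    path: str | Path,
    groups: Mapping[str, str] | None = None,
    lowercase: bool = False,
) -> NormTable:
    """Read a wide norm CSV (``token`` column plus one column per norm).

    ``groups`` maps norm name -> group; it defaults to the canonical
    affect / concreteness / frequency assignment and any column without a
    group is an error.
    """
    df = pd.read_csv(path)
    df["token"] = df["token"].map(lambda t: normalize_token(t, lowercase))
    return NormTable(df, groups=dict(groups) if groups is not None else dict(NORM_GROUPS))


def write_norms(norms: NormTable, path: str | Path) -> None:
    norms.df.to_csv(path, index=False)


def read_headlines(path: str | Path) -> HeadlineCorpus:
    """Read a headline corpus CSV with columns title, publication_date, guid,
    link, description."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return HeadlineCorpus(df)


def write_headlines(corpus: HeadlineCorpus, path: str | Path) -> None:
    corpus.df.to_csv(path, index=False)
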
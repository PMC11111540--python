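"""Synthetic worlds with planted, recoverable structure.

Every pipeline stage is testable without external downloads by generating
data from a latent semantic space:

* each word gets a ``k_latent``-dimensional latent vector drawn standard
  normal and normalized onto the unit sphere: the word's semantic *direction*
  is the quantity both free associations (via cosine similarity) and ratings
  read, so keeping magnitudes fixed makes the two channels share exactly the
  same information and keeps the recovery ceiling attainable end to end;
* mean risk ratings are a noisy linear function of the latent vector,
  affinely mapped into [-100, 100]; the noise is calibrated in closed form
  so the population R^2 of the best linear predictor equals a requested
  ceiling (noise variance = signal variance x (1 - R^2) / R^2, with signal
  variance = |w|^2 / k for unit-sphere latents);
* the nine psychometric item means are independent noisy linear functions
  mapped into [1, 7]; with ``k_latent <= 9`` their span generically contains
  the risk direction, mirroring the strength of psychometric surveys;
* word norms are noisy linear functions of designated directions: affect
  norms load on the risk direction (planting the baseline correlation with
  risk), concreteness and frequency norms on directions orthogonal to it;
* free associations are drawn, per cue, from a softmax over cosine
  similarity / temperature across the word set (self excluded) — the
  simplest response model whose PPMI+SVD embedding aligns with the latent
  space;
* headline corpora sample words with probability increasing in true
  riskiness for a "risky topic" subset of documents, uniformly otherwise.

Rating clipping to the scale bounds is applied after the noise, with the
affine map chosen so clipping affects well under 1% of values and the
linear ceiling calculation stays valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    NORM_GROUPS,
    PSYCHOMETRIC_ITEMS,
    AssociationTable,
    HeadlineCorpus,
    NormTable,
    RatingsTable,
)

__all__ = [
    "SyntheticWorld",
    "make_world",
    "sample_associations",
    "sample_ratings",
    "sample_norms",
    "sample_corpus",
]

# z beyond which ratings are clipped; P(|Z| > 2.81) ~ 0.50%, keeping the
# affine rating map effectively linear.
_CLIP_Z = 2.81


@dataclass
class SyntheticWorld:
    """A frozen latent semantic space plus the linear maps from it to
    ratings, psychometric items and norms."""

    n_words: int
    k_latent: int
    latent_vectors: np.ndarray  # (n_words, k_latent)
    words: list[str]
    risk_weights: np.ndarray  # (k_latent,)
    psychometric_weights: np.ndarray  # (9, k_latent)
    norm_weights: dict[str, np.ndarray]
    norm_groups: dict[str, str]
    noise_sd_risk: float
    noise_sd_psych: float
    noise_sd_norm: float
    target_ceiling_r2: float
    seed: int

    def true_risk_signal(self) -> np.ndarray:
        """The noiseless linear risk score of every word."""
        return self.latent_vectors @ self.risk_weights


def _orthogonal_unit(rng: np.random.Generator, against: np.ndarray) -> np.ndarray:
    """A random unit vector orthogonal to ``against``."""
    v = rng.standard_normal(against.shape[0])
    v -= (v @ against) / (against @ against) * against
    return v / np.linalg.norm(v)


def make_world(
    n_words: int = 1000,
    k_latent: int = 9,
    seed: int = 0,
    target_ceiling_r2: float = 0.8,
    reliability_psych: float = 0.97,
    affect_alignment: float = 0.8,
) -> SyntheticWorld:
    """Create a reproducible synthetic world.

    Parameters
    ----------
    target_ceiling_r2
        Population R^2 of the best linear predictor of risk from the latent
        features, in the open interval (0, 1).  The risk noise SD follows in
        closed form: noise variance = signal variance x (1 - R^2) / R^2.
    reliability_psych
        Sets the psychometric item noise by the same closed form.
    affect_alignment
        Cosine between each affect norm's weight vector and the risk weight
        direction (the planted baseline correlation); concreteness and
        frequency norms are orthogonal to the risk direction.
    """
    if n_words < 50:
        raise ValueError("n_words must be >= 50")
    if not 1 <= k_latent <= 50:
        raise ValueError("k_latent must lie in [1, 50]")
    if not 0 < target_ceiling_r2 < 1:
        raise ValueError("target_ceiling_r2 must lie in the open interval (0, 1)")
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n_words, k_latent))
    latent /= np.linalg.norm(latent, axis=1, keepdims=True)
    words = [f"w{i:04d}" for i in range(n_words)]
    risk_weights = rng.standard_normal(k_latent)
    # Var(u @ w) = |w|^2 / k for u uniform on the unit sphere.
    signal_var = float(risk_weights @ risk_weights) / k_latent
    noise_var = signal_var * (1 - target_ceiling_r2) / target_ceiling_r2
    psych_weights = rng.standard_normal((9, k_latent))
    if k_latent <= 9:
        # Orthonormalize the latent->item map (columns of the 9 x k weight
        # matrix): a well-designed item battery measures complementary
        # dimensions, and condition number 1 keeps the psychometric model's
        # attainable R^2 stable across seeds.
        psych_weights, _ = np.linalg.qr(psych_weights)
    psych_signal = float(np.mean(np.sum(psych_weights**2, axis=1))) / k_latent
    psych_noise_var = psych_signal * (1 - reliability_psych) / reliability_psych
    w_unit = risk_weights / np.linalg.norm(risk_weights)
    norm_weights: dict[str, np.ndarray] = {}
    for name, group in NORM_GROUPS.items():
        if k_latent == 1:
            direction = w_unit if group == "affect" else w_unit * 0.0
        elif group == "affect":
            ortho = _orthogonal_unit(rng, w_unit)
            direction = affect_alignment * w_unit + np.sqrt(1 - affect_alignment**2) * ortho
        else:
            direction = _orthogonal_unit(rng, w_unit)
        norm_weights[name] = direction
    return SyntheticWorld(
        n_words=n_words,
        k_latent=k_latent,
        latent_vectors=latent,
        words=words,
        risk_weights=risk_weights,
        psychometric_weights=psych_weights,
        norm_weights=norm_weights,
        norm_groups=dict(NORM_GROUPS),
        noise_sd_risk=float(np.sqrt(noise_var)),
        noise_sd_psych=float(np.sqrt(psych_noise_var)),
        noise_sd_norm=0.5,
        target_ceiling_r2=target_ceiling_r2,
        seed=seed,
    )


def sample_associations(
    world: SyntheticWorld,
    n_cues: int,
    responses_per_cue: int = 300,
    temperature: float = 0.15,
    seed: int = 0,
) -> AssociationTable:
    """Draw a free-association table.

    For each cue (the first ``n_cues`` words), ``responses_per_cue``
    responses are drawn from softmax(cos(cue, word) / temperature) over all
    other words and aggregated into counts.  ``responses_per_cue`` defaults
    to 300, the order of response tokens per cue in large citizen-science
    association studies; the temperature controls how concentrated responses
    are on semantic neighbors.
    """
    if n_cues > world.n_words:
        raise ValueError("n_cues exceeds the number of words in the world")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    unit = world.latent_vectors / np.linalg.norm(
        world.latent_vectors, axis=1, keepdims=True
    )
    records: list[tuple[str, str, int]] = []
    for i in range(n_cues):
        logits = (unit[i] @ unit.T) / temperature
        logits[i] = -np.inf  # no self-responses
        probs = np.exp(logits - logits.max())
        probs /= probs.sum()
        counts = rng.multinomial(responses_per_cue, probs)
        for j in np.flatnonzero(counts):
            records.append((world.words[i], world.words[j], int(counts[j])))
    return AssociationTable.from_records(records)


def _scaled_ratings(raw: np.ndarray, sd_pop: float, center: float, half_range: float):
    """Affine map of a ~N(0, sd_pop) variable into a bounded rating scale,
    clipping the ~0.5% of values beyond +-_CLIP_Z standard deviations."""
    scaled = center + half_range * raw / (_CLIP_Z * sd_pop)
    return np.clip(scaled, center - half_range, center + half_range)


def sample_ratings(world: SyntheticWorld, seed: int = 0) -> RatingsTable:
    """Draw mean risk ratings (-100..100) and psychometric item means (1..7)
    for every word in the world."""
    rng = np.random.default_rng(seed)
    signal = world.true_risk_signal()
    raw = signal + rng.normal(0.0, world.noise_sd_risk, world.n_words)
    signal_var = float(world.risk_weights @ world.risk_weights) / world.k_latent
    sd_pop = float(np.sqrt(signal_var + world.noise_sd_risk**2))
    risk_mean = _scaled_ratings(raw, sd_pop, 0.0, 100.0)
    data = {"risk_term": world.words, "risk_mean": risk_mean}
    for j, item in enumerate(PSYCHOMETRIC_ITEMS):
        w = world.psychometric_weights[j]
        raw_item = world.latent_vectors @ w + rng.normal(
            0.0, world.noise_sd_psych, world.n_words
        )
        sd_item = float(np.sqrt(w @ w / world.k_latent + world.noise_sd_psych**2))
        data[item] = _scaled_ratings(raw_item, sd_item, 4.0, 3.0)
    return RatingsTable(pd.DataFrame(data))


def sample_norms(world: SyntheticWorld, seed: int = 0) -> NormTable:
    """Draw word norms: each norm is its weight direction's latent
    projection plus Gaussian noise (SD ``world.noise_sd_norm``)."""
    rng = np.random.default_rng(seed)
    data: dict[str, object] = {"token": world.words}
    for name, w in world.norm_weights.items():
        data[name] = world.latent_vectors @ w + rng.normal(
            0.0, world.noise_sd_norm, world.n_words
        )
    return NormTable(pd.DataFrame(data), groups=dict(world.norm_groups))


def sample_corpus(
    world: SyntheticWorld,
    n_docs: int,
    words_per_doc: int = 8,
    seed: int = 0,
    risky_fraction: float = 0.5,
) -> HeadlineCorpus:
    """Draw a headline corpus.

    A ``risky_fraction`` of documents are "risky topics": their words are
    sampled with probability proportional to softmax of the standardized
    true risk signal, so riskier words appear more often.  The remaining
    documents sample words uniformly.
    """
    if n_docs < 1 or words_per_doc < 1:
        raise ValueError("n_docs and words_per_doc must be positive")
    rng = np.random.default_rng(seed)
    z = world.true_risk_signal()
    z = (z - z.mean()) / z.std()
    risky_probs = np.exp(z)
    risky_probs /= risky_probs.sum()
    uniform = np.full(world.n_words, 1.0 / world.n_words)
    rows = []
    base_date = pd.Timestamp("2017-05-09")
    for i in range(n_docs):
        risky = rng.random() < risky_fraction
        probs = risky_probs if risky else uniform
        idx = rng.choice(world.n_words, size=words_per_doc, replace=False, p=probs)
        title = " ".join(world.words[j] for j in idx)
        desc_idx = rng.choice(world.n_words, size=words_per_doc, replace=False, p=probs)
        rows.append(
            {
                "title": title,
                "publication_date": (base_date + pd.Timedelta(days=int(i))).date().isoformat(),
                "guid": f"doc-{i:05d}",
                "link": f"https://example.org/doc-{i:05d}",
                "description": " ".join(world.words[j] for j in desc_idx),
            }
        )
    return HeadlineCorpus(pd.DataFrame(rows))
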
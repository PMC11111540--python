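"""Synthetic-world generators: calibration, determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from riskembed import (
    make_world,
    sample_associations,
    sample_corpus,
    sample_norms,
    sample_ratings,
    train_association_embedding,
)


class TestMakeWorld:
    def test_noise_calibration_closed_form(self):
        w = make_world(n_words=100, k_latent=4, seed=0, target_ceiling_r2=0.8)
        signal_var = float(w.risk_weights @ w.risk_weights) / w.k_latent
        # noise variance = signal variance * (1 - R2) / R2; at R2=0.8 the
        # ratio is exactly 1/4
        assert w.noise_sd_risk**2 == pytest.approx(signal_var * 0.25)
        assert w.noise_sd_risk**2 == pytest.approx(signal_var * (1 - 0.8) / 0.8)

    def test_ceiling_must_be_in_open_interval(self):
        with pytest.raises(ValueError):
            make_world(n_words=100, seed=0, target_ceiling_r2=1.0)
        with pytest.raises(ValueError):
            make_world(n_words=100, seed=0, target_ceiling_r2=0.0)

    def test_same_seed_gives_identical_worlds(self):
        a = make_world(n_words=80, k_latent=3, seed=42)
        b = make_world(n_words=80, k_latent=3, seed=42)
        np.testing.assert_array_equal(a.latent_vectors, b.latent_vectors)
        np.testing.assert_array_equal(a.risk_weights, b.risk_weights)
        for name in a.norm_weights:
            np.testing.assert_array_equal(a.norm_weights[name], b.norm_weights[name])

    def test_size_bounds_enforced(self):
        with pytest.raises(ValueError):
            make_world(n_words=10)
        with pytest.raises(ValueError):
            make_world(n_words=100, k_latent=51)


class TestAssociations:
    def test_deterministic_under_seed(self, small_world):
        a = sample_associations(small_world, n_cues=30, responses_per_cue=40, seed=5)
        b = sample_associations(small_world, n_cues=30, responses_per_cue=40, seed=5)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_nonpositive_temperature_rejected(self, small_world):
        with pytest.raises(ValueError, match="temperature"):
            sample_associations(small_world, n_cues=10, temperature=0.0)

    def test_high_temperature_limit_is_uniform(self, small_world):
        table = sample_associations(
            small_world, n_cues=1, responses_per_cue=20000, temperature=1e9, seed=6
        )
        counts = np.zeros(small_world.n_words - 1)
        others = [w for w in small_world.words if w != small_world.words[0]]
        lookup = {w: i for i, w in enumerate(others)}
        for _, row in table.df.iterrows():
            counts[lookup[row["response"]]] = row["count"]
        stat, p = chisquare(counts)
        assert p > 1e-3

    def test_low_temperature_limit_hits_nearest_neighbor(self, small_world):
        unit = small_world.latent_vectors
        sims = unit[0] @ unit.T
        sims[0] = -np.inf
        nearest = small_world.words[int(np.argmax(sims))]
        table = sample_associations(
            small_world, n_cues=1, responses_per_cue=50, temperature=1e-6, seed=7
        )
        assert table.df["response"].tolist() == [nearest]
        assert table.df["count"].tolist() == [50]

    def test_trained_embedding_recovers_latent_neighbors(self, small_world):
        table = sample_associations(small_world, n_cues=120, responses_per_cue=200, seed=8)
        emb = train_association_embedding(table, k=small_world.k_latent, min_response_freq=3)
        idx = {w: i for i, w in enumerate(small_world.words)}
        latent = small_world.latent_vectors

        def topk(vectors, tokens, i, k=5):
            sims = vectors[i] @ vectors.T / (
                np.linalg.norm(vectors[i]) * np.linalg.norm(vectors, axis=1)
            )
            sims[i] = -np.inf
            return {tokens[j] for j in np.argsort(sims)[-k:]}

        toks = emb.tokens
        sub_latent = np.vstack([latent[idx[t]] for t in toks])
        overlap = np.mean(
            [len(topk(emb.vectors, toks, i) & topk(sub_latent, toks, i)) for i in range(40)]
        )
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(toks))
        shuffled = sub_latent[perm]
        control = np.mean(
            [len(topk(emb.vectors, toks, i) & topk(shuffled, toks, i)) for i in range(40)]
        )
        assert overlap > control + 1.0


class TestRatingsNormsCorpus:
    def test_zero_noise_world_gives_affine_risk_means(self):
        w = make_world(n_words=100, k_latent=4, seed=3, target_ceiling_r2=0.999999)
        ratings = sample_ratings(w, seed=1)
        signal = w.true_risk_signal()
        y = ratings.df["risk_mean"].to_numpy()
        inner = ~((y <= -100 + 1e-9) | (y >= 100 - 1e-9))  # ignore clipped tails
        r = np.corrcoef(signal[inner], y[inner])[0, 1]
        assert r > 0.9999

    def test_ratings_and_psychometrics_within_bounds(self, small_world):
        df = sample_ratings(small_world, seed=2).df
        assert df["risk_mean"].between(-100, 100).all()
        assert df.drop(columns=["risk_term", "risk_mean"]).apply(
            lambda c: c.between(1, 7).all()
        ).all()

    def test_affect_norms_planted_on_risk_dimension(self):
        w = make_world(n_words=1000, k_latent=9, seed=4, target_ceiling_r2=0.8)
        ratings = sample_ratings(w, seed=5)
        norms = sample_norms(w, seed=6)
        y = ratings.df["risk_mean"].to_numpy()
        rs = {
            name: abs(np.corrcoef(norms.df[name], y)[0, 1]) for name in norms.norm_names
        }
        affect = np.mean([rs[n] for n, g in w.norm_groups.items() if g == "affect"])
        other = np.mean([rs[n] for n, g in w.norm_groups.items() if g != "affect"])
        assert affect - other >= 0.3

    def test_corpus_risky_documents_use_riskier_words(self, small_world):
        corpus = sample_corpus(small_world, n_docs=300, seed=9)
        risk = dict(zip(small_world.words, small_world.true_risk_signal()))
        doc_means = [
            np.mean([risk[t] for t in title.split()]) for title in corpus.titles
        ]
        # risky-topic half pulls the mean document riskiness above zero
        assert np.mean(doc_means) > 0.05

    def test_generators_deterministic_and_validated(self, small_world):
        a = sample_corpus(small_world, n_docs=25, seed=10)
        b = sample_corpus(small_world, n_docs=25, seed=10)
        pd.testing.assert_frame_equal(a.df, b.df)
        n1 = sample_norms(small_world, seed=11)
        n2 = sample_norms(small_world, seed=11)
        pd.testing.assert_frame_equal(n1.df, n2.df)
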
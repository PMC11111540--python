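"""Norm-association baseline, residual correlations, and drop analysis."""

import numpy as np
import pandas as pd
import pytest

from riskembed import (
    CvConfig,
    NormTable,
    RatingsTable,
    baseline_norm_association,
    drop_analysis,
    residual_norm_association,
)
from riskembed.io_formats import PSYCHOMETRIC_ITEMS


def _ratings_from(y, terms):
    data = {"risk_term": terms, "risk_mean": np.clip(y, -100, 100)}
    for item in PSYCHOMETRIC_ITEMS:
        data[item] = np.full(len(terms), 4.0)
    return RatingsTable(pd.DataFrame(data))


def _norm_table(tokens, columns, groups):
    return NormTable(pd.DataFrame({"token": tokens, **columns}), groups=groups)


class TestBaseline:
    def test_norm_equal_to_ratings_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        terms = [f"t{i}" for i in range(50)]
        y = rng.uniform(-50, 50, 50)
        norms = _norm_table(terms, {"self": y, "noise": rng.standard_normal(50)},
                            {"self": "affect", "noise": "frequency"})
        report = baseline_norm_association(
            norms, _ratings_from(y, terms), CvConfig(outer_folds=5, repeats=1, seed=0)
        )
        per = report.per_norm.set_index("norm")
        assert per.loc["self", "abs_r"] == pytest.approx(1.0)
        assert 0 <= report.shared_variance <= 1

    def test_independent_norm_stays_at_null_level(self):
        rng = np.random.default_rng(1)
        n = 1000
        terms = [f"t{i}" for i in range(n)]
        y = rng.uniform(-50, 50, n)
        norms = _norm_table(terms, {"unrelated": rng.standard_normal(n)},
                            {"unrelated": "concreteness"})
        report = baseline_norm_association(
            norms, _ratings_from(y, terms),
            CvConfig(outer_folds=5, repeats=1, seed=0),
            shared_variance_method="in_sample",
        )
        assert report.per_norm["abs_r"].iloc[0] <= 0.08

    def test_constant_norm_flagged_and_excluded_from_group_mean(self):
        rng = np.random.default_rng(2)
        terms = [f"t{i}" for i in range(30)]
        y = rng.uniform(-50, 50, 30)
        norms = _norm_table(
            terms,
            {"flat": np.ones(30), "ok": y + rng.standard_normal(30)},
            {"flat": "affect", "ok": "affect"},
        )
        report = baseline_norm_association(
            norms, _ratings_from(y, terms),
            CvConfig(outer_folds=3, repeats=1, seed=0),
            shared_variance_method="in_sample",
        )
        per = report.per_norm.set_index("norm")
        assert not per.loc["flat", "valid"]
        grp = report.per_group.set_index("group")
        assert grp.loc["affect", "n_norms"] == 1

    def test_too_few_shared_terms_rejected(self):
        norms = _norm_table(["a", "b"], {"v": [1.0, 2.0]}, {"v": "affect"})
        with pytest.raises(ValueError, match="shared"):
            baseline_norm_association(
                norms, _ratings_from(np.array([1.0, 2.0]), ["a", "b"]),
                shared_variance_method="in_sample",
            )


class TestResidual:
    def test_orthogonalized_norms_have_zero_correlation(self):
        rng = np.random.default_rng(3)
        n = 200
        terms = [f"t{i}" for i in range(n)]
        resid = rng.standard_normal(n)
        raw = rng.standard_normal(n)
        # Pearson r centers both vectors, so orthogonalize the centered ones
        rc = resid - resid.mean()
        raw_c = raw - raw.mean()
        ortho = raw_c - (raw_c @ rc) / (rc @ rc) * rc
        norms = _norm_table(terms, {"ortho": ortho}, {"ortho": "affect"})
        report = residual_norm_association(pd.Series(resid, index=terms), norms)
        assert report.per_norm["abs_r"].iloc[0] <= 1e-10

    def test_norm_equal_to_residuals_has_unit_correlation(self):
        rng = np.random.default_rng(4)
        terms = [f"t{i}" for i in range(40)]
        resid = rng.standard_normal(40)
        norms = _norm_table(terms, {"same": resid}, {"same": "frequency"})
        report = residual_norm_association(pd.Series(resid, index=terms), norms)
        assert report.per_norm["abs_r"].iloc[0] == pytest.approx(1.0)

    def test_group_mean_is_convex_combination_of_members(self):
        rng = np.random.default_rng(5)
        n = 100
        terms = [f"t{i}" for i in range(n)]
        resid = rng.standard_normal(n)
        cols = {f"n{i}": resid * (i + 1) / 5 + rng.standard_normal(n) for i in range(4)}
        norms = _norm_table(terms, cols, {k: "affect" for k in cols})
        report = residual_norm_association(pd.Series(resid, index=terms), norms)
        rs = report.per_norm["abs_r"]
        grp = report.per_group["mean_abs_r"].iloc[0]
        assert rs.min() - 1e-12 <= grp <= rs.max() + 1e-12


class TestDrops:
    def _report(self, abs_rs, groups):
        per_norm = pd.DataFrame(
            {
                "norm": list(abs_rs),
                "group": [groups[k] for k in abs_rs],
                "abs_r": list(abs_rs.values()),
                "ci_low": 0.0,
                "ci_high": 1.0,
                "valid": True,
            }
        )
        per_group = (
            per_norm.groupby("group")["abs_r"].agg(mean_abs_r="mean", n_norms="size").reset_index()
        )
        from riskembed import NormAssociationReport

        return NormAssociationReport(per_norm=per_norm, per_group=per_group)

    def test_identical_stages_have_zero_drop(self):
        g = {"a": "affect", "b": "affect"}
        s = self._report({"a": 0.4, "b": 0.2}, g)
        out = drop_analysis([s, s])
        assert (out["delta"] == 0).all()

    def test_hand_built_two_stage_delta(self):
        g = {"a": "affect", "b": "affect", "f": "frequency"}
        s1 = self._report({"a": 0.5, "b": 0.3, "f": 0.2}, g)
        s2 = self._report({"a": 0.1, "b": 0.1, "f": 0.15}, g)
        out = drop_analysis([s1, s2]).set_index("group")
        assert out.loc["affect", "delta"] == pytest.approx(0.4 - 0.1)
        assert out.loc["frequency", "delta"] == pytest.approx(0.05)

    def test_antisymmetric_under_stage_reversal(self):
        g = {"a": "affect", "f": "frequency"}
        s1 = self._report({"a": 0.5, "f": 0.2}, g)
        s2 = self._report({"a": 0.2, "f": 0.4}, g)
        fwd = drop_analysis([s1, s2]).set_index("group")["delta"]
        rev = drop_analysis([s2, s1]).set_index("group")["delta"]
        pd.testing.assert_series_equal(fwd, -rev)

    def test_mismatched_norm_sets_rejected(self):
        s1 = self._report({"a": 0.5}, {"a": "affect"})
        s2 = self._report({"b": 0.5}, {"b": "affect"})
        with pytest.raises(ValueError, match="norm set"):
            drop_analysis([s1, s2])
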
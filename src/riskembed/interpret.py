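"""Residual-norm interpretability analysis.

The idea: psycholinguistic word norms (valence, arousal, concreteness,
frequency, ...) are interpretable probes of what a risk-prediction model
does and does not capture.  Three stages are compared:

1. *baseline* — absolute Pearson correlation of each norm with the mean
   risk ratings themselves (how much risk-perception variance the norm could
   in principle explain), plus the variance the norms share with the ratings
   when used jointly as predictors;
2. *model residuals* — the same correlations computed against a model's
   residuals (observed minus predicted risk).  Signal that survives in the
   residuals is variance the model failed to capture;
3. *drops* — per-group differences in mean absolute correlation between
   consecutive stages: a large drop means the model absorbed that group's
   signal.

Per-norm confidence intervals use the Fisher z transform.  A norm that is
constant over the shared terms has an undefined correlation; it is flagged
and excluded from group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm as _normal

from .io_formats import NormTable, RatingsTable
from .predictor import CvConfig, nested_cv_evaluate

__all__ = [
    "NormAssociationReport",
    "baseline_norm_association",
    "residual_norm_association",
    "drop_analysis",
]


@dataclass
class NormAssociationReport:
    """Per-norm absolute Pearson correlations with a target vector, grouped
    summaries, and (for the baseline stage) the variance the norms jointly
    share with the target."""

    per_norm: pd.DataFrame  # columns: norm, group, abs_r, ci_low, ci_high, valid
    per_group: pd.DataFrame  # columns: group, mean_abs_r, n_norms
    shared_variance: float | None = None
    n_terms: int = 0

    @property
    def norm_names(self) -> list[str]:
        return list(self.per_norm["norm"])


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation, reported on
    the absolute-correlation scale."""
    if n <= 3 or abs(r) >= 1.0:
        return (abs(r), abs(r))
    z = np.arctanh(r)
    half = _normal.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    if r < 0:
        lo, hi = -hi, -lo
    return (float(lo), float(hi))


def _correlate_norms(
    norm_matrix: pd.DataFrame,
    groups: dict[str, str],
    target: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Absolute Pearson r of each norm column with ``target`` plus grouped
    means over valid norms."""
    n = len(target)
    rows = []
    for name in norm_matrix.columns:
        vals = norm_matrix[name].to_numpy(dtype=float)
        if np.ptp(vals) == 0 or np.ptp(target) == 0:
            rows.append((name, groups[name], np.nan, np.nan, np.nan, False))
            continue
        r = float(np.corrcoef(vals, target)[0, 1])
        lo, hi = _fisher_ci(r, n)
        rows.append((name, groups[name], abs(r), lo, hi, True))
    per_norm = pd.DataFrame(
        rows, columns=["norm", "group", "abs_r", "ci_low", "ci_high", "valid"]
    )
    valid = per_norm[per_norm["valid"]]
    per_group = (
        valid.groupby("group")["abs_r"]
        .agg(mean_abs_r="mean", n_norms="size")
        .reset_index()
    )
    return per_norm, per_group


def _align(norms: NormTable, terms: list[str]) -> tuple[pd.DataFrame, np.ndarray]:
    """Inner-join norm tokens with a term list; returns the norm matrix for
    shared terms and the boolean mask into ``terms``."""
    norm_df = norms.df.set_index("token")
    mask = np.array([t in norm_df.index for t in terms])
    shared = [t for t, m in zip(terms, mask) if m]
    return norm_df.loc[shared, norms.norm_names], mask


def baseline_norm_association(
    norms: NormTable,
    ratings: RatingsTable,
    config: CvConfig | None = None,
    shared_variance_method: str = "cv",
) -> NormAssociationReport:
    """Stage-1 report: each norm's absolute correlation with the mean risk
    ratings, and the variance all norms jointly share with them.

    ``shared_variance_method="cv"`` estimates the joint share as the grand
    mean out-of-sample R^2 of an elastic net predicting risk from all norms
    (the same protocol used for the risk models); ``"in_sample"`` uses the
    ordinary multiple-R^2 of a least-squares fit.
    """
    terms = ratings.terms
    norm_matrix, mask = _align(norms, terms)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 terms shared between norms and ratings")
    y = ratings.df["risk_mean"].to_numpy(dtype=float)[mask]
    per_norm, per_group = _correlate_norms(norm_matrix, dict(norms.groups), y)
    X = norm_matrix.to_numpy(dtype=float)
    keep = np.ptp(X, axis=0) > 0
    X = X[:, keep]
    if shared_variance_method == "cv":
        shared = float(
            np.clip(nested_cv_evaluate(X, y, config or CvConfig()).grand_mean_r2, 0, 1)
        )
    elif shared_variance_method == "in_sample":
        Xc = np.column_stack([np.ones(len(y)), X])
        resid = y - Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
        shared = float(1 - resid.var() / y.var())
    else:
        raise ValueError(f"unknown shared_variance_method {shared_variance_method!r}")
    return NormAssociationReport(
        per_norm=per_norm,
        per_group=per_group,
        shared_variance=shared,
        n_terms=int(mask.sum()),
    )


def residual_norm_association(
    residuals: pd.Series | np.ndarray,
    norms: NormTable,
    terms: list[str] | None = None,
) -> NormAssociationReport:
    """Stage-2 report: each norm's absolute correlation with a model's
    per-term residuals.

    ``residuals`` may be a pandas Series indexed by term, or an array with
    ``terms`` given separately.
    """
    if isinstance(residuals, pd.Series):
        terms = list(residuals.index)
        values = residuals.to_numpy(dtype=float)
    else:
        if terms is None:
            raise ValueError("terms must accompany a bare residual array")
        values = np.asarray(residuals, dtype=float)
    norm_matrix, mask = _align(norms, list(terms))
    if mask.sum() < 3:
        raise ValueError("fewer than 3 terms shared between norms and residuals")
    per_norm, per_group = _correlate_norms(
        norm_matrix, dict(norms.groups), values[mask]
    )
    return NormAssociationReport(
        per_norm=per_norm, per_group=per_group, n_terms=int(mask.sum())
    )


def drop_analysis(stages: list[NormAssociationReport]) -> pd.DataFrame:
    """Per-group drops in mean absolute correlation between consecutive
    stages.

    Returns a frame with columns ``group, stage_from, stage_to, delta`` where
    ``delta = mean |r| at stage i  -  mean |r| at stage i+1``; a positive
    delta means the later stage's model absorbed that group's signal.
    """
    if len(stages) < 2:
        raise ValueError("need at least two stages")
    names = [set(s.per_norm["norm"]) for s in stages]
    for i, other in enumerate(names[1:], start=1):
        if other != names[0]:
            raise ValueError(f"stage {i} norm set differs from stage 0")
    rows = []
    for i in range(len(stages) - 1):
        a = stages[i].per_group.set_index("group")["mean_abs_r"]
        b = stages[i + 1].per_group.set_index("group")["mean_abs_r"]
        for group in a.index:
            rows.append((group, i, i + 1, float(a[group] - b.get(group, np.nan))))
    return pd.DataFrame(rows, columns=["group", "stage_from", "stage_to", "delta"])
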
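"""Rule-support (Albright) score handling.

The score is a [0, 1] measure of how strongly a past-tense form is
supported by learned morphophonological rules (high = rule-like, e.g.
sent; low = exceptional, e.g. flew).  Scores are consumed as inputs (one
per regular/irregular item).  Because the score correlates with surface
frequency, it is residualized (orthogonalized) against log surface
frequency at the item level before interaction testing, so the retained
predictor is uncorrelated with the frequency confound.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .clusterperm import ClusterTestResult, permutation_test
from .containers import EpochSet

__all__ = [
    "Orthogonalizer",
    "orthogonalize",
    "bin_albright",
    "add_orthogonalized_score",
    "read_scores",
    "interaction_analysis",
]


class Orthogonalizer(TransformerMixin, BaseEstimator):
    """Residualize a variable against [1, covariate] by least squares.

    The transform output has exactly zero mean and zero sample correlation
    with the covariate, and is idempotent.
    """

    def fit(self, X, y=None, covariate=None):
        covariate = np.asarray(covariate, dtype=float)
        if np.ptp(covariate) == 0:
            raise ValueError("covariate is constant; cannot orthogonalize")
        self.covariate_ = covariate
        C = np.column_stack([np.ones(len(covariate)), covariate])
        # hat projector is tiny (2 columns); keep the normal-equations form
        self.proj_ = C @ np.linalg.inv(C.T @ C) @ C.T
        return self

    def transform(self, X):
        x = np.asarray(X, dtype=float).ravel()
        if len(x) != len(self.covariate_):
            raise ValueError("length mismatch with fitted covariate")
        return x - self.proj_ @ x


def orthogonalize(x, covariate) -> np.ndarray:
    """Residuals of the regression of ``x`` on [1, covariate]."""
    x = np.asarray(x, dtype=float).ravel()
    covariate = np.asarray(covariate, dtype=float).ravel()
    if len(x) != len(covariate):
        raise ValueError("x and covariate must have equal length")
    return Orthogonalizer().fit(None, covariate=covariate).transform(x)


def bin_albright(scores, cutpoint: float = 0.5) -> np.ndarray:
    """Split scores into "high" (> cutpoint), "low" (< cutpoint) and
    "excluded" (exactly at the cutpoint, which the strict inequalities
    leave unassigned)."""
    scores = np.asarray(scores, dtype=float)
    if np.nanmin(scores) < 0 or np.nanmax(scores) > 1:
        raise ValueError("scores must lie in [0, 1]")
    labels = np.where(scores > cutpoint, "high",
                      np.where(scores < cutpoint, "low", "excluded"))
    return labels.astype(object)


def read_scores(path, sep: str = "\t") -> pd.DataFrame:
    """Two-column delimited file: item_id, albright_score."""
    df = pd.read_csv(path, sep=sep)
    if not {"item_id", "albright_score"} <= set(df.columns):
        raise ValueError("score file needs item_id and albright_score columns")
    return df[["item_id", "albright_score"]]


def add_orthogonalized_score(
    trials: pd.DataFrame,
    score_col: str = "albright_score",
    freq_col: str = "log_surface_freq",
    out_col: str = "albright_score_o",
) -> pd.DataFrame:
    """Attach the frequency-orthogonalized score as a new column.

    Residualization is done at the item level (each item has one score and
    one frequency), then broadcast back to trials.  Rows without a score
    get NaN.
    """
    items = (
        trials.dropna(subset=[score_col])
        .drop_duplicates("item_id")[["item_id", score_col, freq_col]]
        .sort_values("item_id")
    )
    resid = orthogonalize(items[score_col], items[freq_col])
    mapping = dict(zip(items["item_id"], resid))
    out = trials.copy()
    out[out_col] = out["item_id"].map(mapping)
    return out


def interaction_analysis(
    epochs: EpochSet,
    trials: pd.DataFrame,
    score_term: str = "albright_score_o",
    factor: str = "prime_type",
    condition: str = "irregular",
    window_ms=None,
    threshold: float = 1.96,
    n_perm: int = 10000,
    seed: int | None = None,
) -> ClusterTestResult:
    """Cluster-corrected test of the score x prime-type interaction.

    Runs the sqrt(chi^2) millisecond-wise LRT with cluster-mass
    permutation correction on the trials of one condition (irregulars by
    default); the score must already be orthogonalized (see
    :func:`add_orthogonalized_score`).
    """
    sub = trials[trials["condition"] == condition]
    if sub[score_term].isna().any():
        raise ValueError(f"{score_term} missing for some {condition} trials")
    return permutation_test(
        epochs, sub, term=factor, term_b=score_term, window_ms=window_ms,
        threshold=threshold, n_perm=n_perm, seed=seed,
    )
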
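"""Millisecond-wise statistics with cluster-mass permutation correction.

The inferential engine: at every time point of an analysis window a
crossed random-intercepts LMM is fitted to the single-trial amplitudes
and the fixed-effect t-value (or, for interactions, the square root of a
nested-model likelihood-ratio chi^2) is recorded.  Temporal clusters are
maximal runs of consecutive supra-threshold statistics of one sign; a
cluster's mass is the sum of its member statistics (Sigma-t).  Family-wise
correction compares each observed |mass| with the permutation null of the
maximum |mass|, obtained by relabeling the independent variable within
subject and re-deriving the whole statistic series per relabeling.

Permutations reuse the variance ratios estimated from the observed fit at
each time point (a score-type approximation; an ``exact-refit`` mode that
re-optimizes per permutation is available for validation on small
fixtures).  p-values use the add-one estimator and are therefore in
(0, 1], never exactly zero.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import EpochSet
from .mixedmodel import (
    CrossedLMM,
    GroupStructure,
    _term_column,
    _whiten_factor,
    batched_interaction_chisq,
    batched_term_t,
    free_permutations,
    lrt_nested,
    within_group_permutations,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StatSeries",
    "Cluster",
    "ClusterTestResult",
    "pointwise_stats",
    "pointwise_interaction_stats",
    "find_clusters",
    "permutation_test",
    "ClusterPermutationTest",
]


# --------------------------------------------------------------------------
# data types
# --------------------------------------------------------------------------

@dataclasses.dataclass
class StatSeries:
    """Per-timepoint test statistic over an analysis window."""

    values: np.ndarray
    time_ms: np.ndarray
    kind: str = "t"  # "t" or "sqrt_chisq"
    term: str | None = None
    n_nonconverged: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.values.shape != self.time_ms.shape:
            raise ValueError("values/time_ms length mismatch")
        if self.kind not in ("t", "sqrt_chisq"):
            raise ValueError(f"unknown kind {self.kind!r}")


@dataclasses.dataclass
class Cluster:
    """Maximal run of consecutive supra-threshold statistics of one sign."""

    start_ms: float
    end_ms: float
    sign: int  # +1 or -1 (always +1 for sqrt_chisq series)
    mass: float  # Sigma-t over member time points
    start_idx: int
    end_idx: int  # inclusive
    mc_p: float | None = None


@dataclasses.dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    max_abs_mass: float
    null_distribution: np.ndarray
    threshold: float
    n_perm: int
    seed: int | None
    kind: str
    window_ms: tuple[float, float]
    stat_series: StatSeries | None = None

    @property
    def p_value(self) -> float:
        """Family-wise p of the strongest cluster (1.0 when none)."""
        if not self.clusters:
            return 1.0
        return min(c.mc_p for c in self.clusters)

    def to_dict(self, include_null: bool = False) -> dict:
        d = dict(
            clusters=[
                dict(
                    start_ms=float(c.start_ms),
                    end_ms=float(c.end_ms),
                    sign=int(c.sign),
                    mass=float(c.mass),
                    mc_p=None if c.mc_p is None else float(c.mc_p),
                )
                for c in self.clusters
            ],
            max_abs_mass=float(self.max_abs_mass),
            threshold=float(self.threshold),
            n_perm=int(self.n_perm),
            seed=self.seed,
            kind=self.kind,
            window_ms=[float(self.window_ms[0]), float(self.window_ms[1])],
            p_value=float(self.p_value),
        )
        if include_null:
            d["null_distribution"] = [float(v) for v in self.null_distribution]
        return d

    def to_json(self, path=None, include_null: bool = False) -> str:
        text = json.dumps(self.to_dict(include_null), sort_keys=True, indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text


# --------------------------------------------------------------------------
# cluster finding
# --------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> np.ndarray:
    """(k, 2) array of [start, stop) bounds of True runs."""
    padded = np.concatenate(([0], mask.astype(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    return edges.reshape(-1, 2)


def find_clusters(series: StatSeries, threshold: float = 1.96) -> list[Cluster]:
    """Temporal clusters of strictly supra-threshold values of one sign.

    Values exactly at the threshold are not members.  For ``sqrt_chisq``
    series only positive clusters exist.  Clusters touching the window
    edge are legal clusters.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    v = series.values
    clusters: list[Cluster] = []
    signs = (1,) if series.kind == "sqrt_chisq" else (1, -1)
    for sign in signs:
        mask = v > threshold if sign > 0 else v < -threshold
        for start, stop in _runs(mask):
            clusters.append(
                Cluster(
                    start_ms=float(series.time_ms[start]),
                    end_ms=float(series.time_ms[stop - 1]),
                    sign=sign,
                    mass=float(v[start:stop].sum()),
                    start_idx=int(start),
                    end_idx=int(stop - 1),
                )
            )
    clusters.sort(key=lambda c: c.start_idx)
    return clusters


def _max_cluster_mass(values: np.ndarray, threshold: float,
                      positive_only: bool) -> float:
    best = 0.0
    for start, stop in _runs(values > threshold):
        best = max(best, values[start:stop].sum())
    if not positive_only:
        for start, stop in _runs(values < -threshold):
            best = max(best, -values[start:stop].sum())
    return best


# --------------------------------------------------------------------------
# pointwise model fits
# --------------------------------------------------------------------------

def _aligned_window(epochs: EpochSet, trials: pd.DataFrame, window_ms):
    ep = epochs.subset(trials.index)
    if window_ms is None:
        window_ms = (ep.time_ms[0], ep.time_ms[-1])
    sl = ep.window_slice(window_ms)
    if sl.stop <= sl.start:
        raise ValueError("analysis window is empty")
    return ep.data[:, sl], ep.time_ms[sl], tuple(window_ms)


def _pointwise_t(Y, time_ms, trials, term, method="REML"):
    """Per-timepoint term t-values; also returns the per-timepoint
    variance ratios for reuse by the permutation engine."""
    col, name = _term_column(trials, term)
    if np.ptp(col) == 0:
        raise ValueError(f"term {term!r} is constant")
    n, T = Y.shape
    X = np.column_stack([np.ones(n), col])
    struct = GroupStructure(trials["subject_id"], trials["item_id"])
    values = np.zeros(T)
    lams = np.zeros((T, 2))
    n_bad = 0
    start = (0.3, 0.3)
    for t in range(T):
        y = Y[:, t]
        if np.ptp(y) == 0.0:
            values[t] = 0.0
            lams[t] = (0.0, 0.0)
            continue
        est = CrossedLMM(method=method, start=start)
        est.fit(X, y, subjects=trials["subject_id"], items=trials["item_id"],
                term_names=["Intercept", name])
        if est.converged_:
            values[t] = est.tvalues_[1]
            start = (max(est.ratios_[0], 1e-4), max(est.ratios_[1], 1e-4))
        else:
            values[t] = 0.0
            n_bad += 1
            logger.warning("pointwise fit did not converge at %.0f ms", time_ms[t])
        lams[t] = est.ratios_
    series = StatSeries(values, time_ms, kind="t", term=name, n_nonconverged=n_bad)
    return series, struct, col, lams


def _pointwise_sqrt_chisq(Y, time_ms, trials, term_a, term_b):
    """Per-timepoint sqrt(chi^2) for the a x b interaction via nested ML
    refits; returns the full-model variance ratios per timepoint."""
    col_a, name_a = _term_column(trials, term_a)
    col_b, name_b = _term_column(trials, term_b)
    if np.ptp(col_a) == 0 or np.ptp(col_b) == 0:
        raise ValueError("interaction terms must both vary")
    n, T = Y.shape
    ones = np.ones(n)
    Xr = np.column_stack([ones, col_a, col_b])
    Xf = np.column_stack([ones, col_a, col_b, col_a * col_b])
    names_r = ["Intercept", name_a, name_b]
    names_f = names_r + [f"{term_a}:{term_b}"]
    struct = GroupStructure(trials["subject_id"], trials["item_id"])
    values = np.zeros(T)
    lams = np.zeros((T, 2))
    n_bad = 0
    for t in range(T):
        y = Y[:, t]
        if np.ptp(y) == 0.0:
            continue
        chi2, _, _ = lrt_nested(y, Xr, Xf, trials["subject_id"], trials["item_id"],
                                names_reduced=names_r, names_full=names_f)
        values[t] = np.sqrt(chi2)
        full = CrossedLMM(method="ML")
        full.fit(Xf, y, subjects=trials["subject_id"], items=trials["item_id"],
                 term_names=names_f)
        lams[t] = full.ratios_
    series = StatSeries(values, time_ms, kind="sqrt_chisq",
                        term=f"{term_a}:{term_b}", n_nonconverged=n_bad)
    return series, struct, col_a, col_b, lams


def pointwise_stats(
    epochs: EpochSet,
    trials: pd.DataFrame,
    term: str = "prime_type",
    window_ms=None,
    method: str = "REML",
) -> StatSeries:
    """t-value of ``term`` from a separate crossed-intercepts LMM at each
    time point of the window."""
    Y, time_ms, _ = _aligned_window(epochs, trials, window_ms)
    return _pointwise_t(Y, time_ms, trials, term, method=method)[0]


def pointwise_interaction_stats(
    epochs: EpochSet,
    trials: pd.DataFrame,
    term_a: str = "prime_type",
    term_b: str = "albright_score_o",
    window_ms=None,
) -> StatSeries:
    """sqrt(chi^2) of the a x b interaction (nested-model ML LRT) at each
    time point of the window."""
    Y, time_ms, _ = _aligned_window(epochs, trials, window_ms)
    return _pointwise_sqrt_chisq(Y, time_ms, trials, term_a, term_b)[0]


# --------------------------------------------------------------------------
# permutation test
# --------------------------------------------------------------------------

def _perm_indices(scheme, struct, n, n_perm, rng):
    if scheme == "within_subject":
        return within_group_permutations(struct.si, n_perm, rng)
    if scheme == "free":
        return free_permutations(n, n_perm, rng)
    raise ValueError(f"unknown permutation scheme {scheme!r}")


def _null_max_masses_score(Y, struct, lams, col, col_b, idx, threshold, kind):
    """Max |cluster mass| per permutation, score-type approximation.

    ``idx`` is (m, n) permutation row indices.  Variance ratios per time
    point are fixed at the observed estimates; the whitening factor per
    time point is computed once and shared across permutations.
    """
    n, T = Y.shape
    m = idx.shape[0]
    P = col[idx].T.copy()  # (n, m)
    stats_mat = np.empty((m, T))
    whitens = {}
    for t in range(T):
        key = (round(float(lams[t, 0]), 12), round(float(lams[t, 1]), 12))
        if key not in whitens:
            whitens[key] = _whiten_factor(struct, *key)
        whiten = whitens[key]
        y = Y[:, t]
        if np.ptp(y) == 0.0:
            stats_mat[:, t] = 0.0
            continue
        if kind == "t":
            stats_mat[:, t] = batched_term_t(
                struct, key, np.ones((n, 1)), P, y, whiten=whiten
            )
        else:
            chi2 = batched_interaction_chisq(struct, key, col_b, P, y, whiten=whiten)
            stats_mat[:, t] = np.sqrt(chi2)
    positive_only = kind != "t"
    return np.array(
        [_max_cluster_mass(stats_mat[j], threshold, positive_only) for j in range(m)]
    )


def _null_max_masses_refit(Y, time_ms, trials, term, term_b, idx, threshold, kind):
    """Exact-refit permutation null (slow; for validation on small data)."""
    out = np.empty(idx.shape[0])
    for j, row in enumerate(idx):
        permuted = trials.copy()
        permuted[term] = trials[term].to_numpy()[row]
        if kind == "t":
            series = _pointwise_t(Y, time_ms, permuted, term)[0]
        else:
            series = _pointwise_sqrt_chisq(Y, time_ms, permuted, term, term_b)[0]
        out[j] = _max_cluster_mass(series.values, threshold, kind != "t")
    return out


def permutation_test(
    epochs: EpochSet,
    trials: pd.DataFrame,
    term: str = "prime_type",
    term_b: str | None = None,
    window_ms=None,
    threshold: float = 1.96,
    n_perm: int = 10000,
    seed: int | None = None,
    scheme: str = "within_subject",
    mode: str = "score",
    keep_series: bool = True,
) -> ClusterTestResult:
    """Cluster-mass permutation test of ``term`` (or of the
    ``term`` x ``term_b`` interaction when ``term_b`` is given).

    The independent variable is relabeled within subject (each subject's
    related/unrelated counts are preserved; for the interaction variant
    only the A x B pairing is broken: A is permuted while B stays fixed);
    ``scheme="free"`` permutes across subjects instead.  Per cluster,
    mc_p = (1 + #{null max >= |mass|}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y, time_ms, window = _aligned_window(epochs, trials, window_ms)
    kind = "t" if term_b is None else "sqrt_chisq"
    if kind == "t":
        series, struct, col, lams = _pointwise_t(Y, time_ms, trials, term)
        col_b = None
    else:
        series, struct, col, col_b, lams = _pointwise_sqrt_chisq(
            Y, time_ms, trials, term, term_b
        )
    clusters = find_clusters(series, threshold)
    rng = np.random.default_rng(seed)

    null = np.empty(n_perm)
    chunk = max(1, min(n_perm, 512))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        idx = _perm_indices(scheme, struct, len(trials), m, rng)
        if mode == "score":
            null[done:done + m] = _null_max_masses_score(
                Y, struct, lams, col, col_b, idx, threshold, kind
            )
        elif mode == "refit":
            null[done:done + m] = _null_max_masses_refit(
                Y, time_ms, trials, term, term_b, idx, threshold, kind
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        done += m

    for c in clusters:
        c.mc_p = float((1 + np.sum(null >= abs(c.mass) - 1e-12)) / (1 + n_perm))
    max_abs = max((abs(c.mass) for c in clusters), default=0.0)
    return ClusterTestResult(
        clusters=clusters,
        max_abs_mass=float(max_abs),
        null_distribution=null,
        threshold=threshold,
        n_perm=n_perm,
        seed=seed,
        kind=kind,
        window_ms=window,
        stat_series=series if keep_series else None,
    )


class ClusterPermutationTest(BaseEstimator):
    """Estimator wrapper around :func:`permutation_test`.

    ``fit(epochs, trials)`` stores ``result_``, ``clusters_``,
    ``pvalues_`` (one per cluster), ``stat_series_`` and
    ``null_distribution_``.
    """

    def __init__(
        self,
        term: str = "prime_type",
        term_b: str | None = None,
        window_ms=None,
        threshold: float = 1.96,
        n_perm: int = 10000,
        seed: int | None = None,
        scheme: str = "within_subject",
        mode: str = "score",
    ):
        self.term = term
        self.term_b = term_b
        self.window_ms = window_ms
        self.threshold = threshold
        self.n_perm = n_perm
        self.seed = seed
        self.scheme = scheme
        self.mode = mode

    def fit(self, X: EpochSet, y: pd.DataFrame):
        result = permutation_test(
            X, y, term=self.term, term_b=self.term_b, window_ms=self.window_ms,
            threshold=self.threshold, n_perm=self.n_perm, seed=self.seed,
            scheme=self.scheme, mode=self.mode,
        )
        self.result_ = result
        self.clusters_ = result.clusters
        self.pvalues_ = np.array([c.mc_p for c in result.clusters])
        self.stat_series_ = result.stat_series
        self.null_distribution_ = result.null_distribution
        return self
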
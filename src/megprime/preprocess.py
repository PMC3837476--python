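"""Trial- and subject-level filtering and signal conditioning.

Implements the screening rules applied before any model fitting:
per-trial baseline correction against the pre-target interval, zero-phase
low-pass filtering, amplitude-threshold trial rejection on raw-mode
epochs, 2-SD subject exclusion on reaction-time summaries, and per-trial
RT trimming (300 ms floor, condition-wise 2-SD ceiling).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import EpochSet

__all__ = [
    "BaselineCorrector",
    "LowpassFilter",
    "AmplitudeOutlierRejector",
    "baseline_correct",
    "lowpass_filter",
    "reject_amplitude_outliers",
    "exclude_subjects_by_rt",
    "trim_rt_trials",
    "TrimResult",
]


class BaselineCorrector(TransformerMixin, BaseEstimator):
    """Subtract each trial's mean amplitude over a baseline interval.

    Idempotent: applying the corrector twice equals applying it once.
    """

    def __init__(self, interval_ms: tuple[float, float] = (-150.0, -50.0)):
        self.interval_ms = interval_ms

    def fit(self, X: EpochSet, y=None):
        X.window_slice(self.interval_ms)  # validates the interval
        return self

    def transform(self, X: EpochSet) -> EpochSet:
        sl = X.window_slice(self.interval_ms)
        out = X.copy()
        out.data -= out.data[:, sl].mean(axis=1, keepdims=True)
        return out


class LowpassFilter(TransformerMixin, BaseEstimator):
    """Zero-phase low-pass (4th-order Butterworth, forward-backward).

    Forward-backward application doubles the effective order (~48 dB one
    octave above cutoff) and cancels group delay, so symmetric peaks keep
    their latency.
    """

    def __init__(self, cutoff_hz: float = 40.0, order: int = 4):
        self.cutoff_hz = cutoff_hz
        self.order = order

    def fit(self, X: EpochSet, y=None):
        nyquist = X.sampling_rate_hz / 2.0
        if not 0 < self.cutoff_hz < nyquist:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must be in (0, Nyquist={nyquist}) Hz"
            )
        return self

    def transform(self, X: EpochSet) -> EpochSet:
        self.fit(X)
        sos = signal.butter(
            self.order, self.cutoff_hz, btype="low", fs=X.sampling_rate_hz,
            output="sos",
        )
        out = X.copy()
        out.data = signal.sosfiltfilt(sos, out.data, axis=1)
        return out


class AmplitudeOutlierRejector(BaseEstimator):
    """Flag trials whose peak |amplitude| exceeds a threshold in a window.

    The threshold is in the units of the epochs it is applied to (pT for
    raw-channel-mode data, where the conventional cut is +/-2.5 pT over
    (-150, +300) ms).  ``predict`` returns True for *rejected* trials.
    """

    def __init__(
        self,
        threshold: float = 2.5,
        window_ms: tuple[float, float] = (-150.0, 300.0),
    ):
        self.threshold = threshold
        self.window_ms = window_ms

    def fit(self, X: EpochSet, y=None):
        X.window_slice(self.window_ms)
        return self

    def predict(self, X: EpochSet) -> np.ndarray:
        sl = X.window_slice(self.window_ms)
        peak = np.abs(X.data[:, sl]).max(axis=1)
        return peak > self.threshold

    def fit_predict(self, X: EpochSet, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


def baseline_correct(epochs: EpochSet, interval_ms=(-150.0, -50.0)) -> EpochSet:
    return BaselineCorrector(interval_ms).fit(epochs).transform(epochs)


def lowpass_filter(epochs: EpochSet, cutoff_hz: float = 40.0) -> EpochSet:
    return LowpassFilter(cutoff_hz).fit(epochs).transform(epochs)


def reject_amplitude_outliers(
    raw_epochs: EpochSet,
    threshold: float = 2.5,
    window_ms: tuple[float, float] = (-150.0, 300.0),
) -> np.ndarray:
    """Boolean mask, True where a trial is rejected (peak |amp| > threshold)."""
    return AmplitudeOutlierRejector(threshold, window_ms).fit_predict(raw_epochs)


def exclude_subjects_by_rt(trials: pd.DataFrame) -> set:
    """Retained subjects after the 2-SD screening of RT summaries.

    Computed on correct word-target trials.  A subject is excluded when
    their mean RT exceeds the group mean of subject means by more than two
    SDs of the subject means, or their RT SD exceeds the group mean of
    subject SDs by more than two SDs of the subject SDs.  Statistics are
    computed inclusively (no leave-one-out).
    """
    ok = trials[
        (trials["condition"] != "nonword")
        & (trials.get("accuracy", 1) == 1)
        & trials["rt_ms"].notna()
    ]
    per_subj = ok.groupby("subject_id")["rt_ms"].agg(["mean", "std"])
    if len(per_subj) < 3:
        raise ValueError("need at least 3 subjects for the 2-SD exclusion rule")
    mean_cut = per_subj["mean"].mean() + 2.0 * per_subj["mean"].std(ddof=1)
    sd_cut = per_subj["std"].mean() + 2.0 * per_subj["std"].std(ddof=1)
    keep = per_subj[(per_subj["mean"] <= mean_cut) & (per_subj["std"] <= sd_cut)]
    return set(keep.index)


@dataclasses.dataclass
class TrimResult:
    """Outcome of RT trial trimming: the retained table plus a log of the
    removed trials (trial index, rule fired, offending value)."""

    trials: pd.DataFrame
    log: pd.DataFrame

    def __iter__(self):  # allow `kept, log = trim_rt_trials(...)`
        return iter((self.trials, self.log))


def trim_rt_trials(
    trials: pd.DataFrame,
    floor_ms: float = 300.0,
    n_sd: float = 2.0,
) -> TrimResult:
    """Remove implausibly fast and condition-wise slow trials.

    Drops trials with rt < ``floor_ms`` and trials with rt above the
    cross-subject mean + ``n_sd`` * SD of their condition, with the
    mean/SD computed once on the pre-trim table (single pass, not
    iterated).  Trials with missing RT are left untouched.
    """
    rt = trials["rt_ms"]
    has_rt = rt.notna()
    stats_by_cond = trials[has_rt].groupby("condition")["rt_ms"].agg(["mean", "std"])
    ceiling = trials["condition"].map(
        stats_by_cond["mean"] + n_sd * stats_by_cond["std"].fillna(0.0)
    )
    too_fast = has_rt & (rt < floor_ms)
    too_slow = has_rt & ~too_fast & (rt > ceiling)
    removed = too_fast | too_slow
    log = pd.DataFrame(
        {
            "trial_index": trials.index[removed],
            "rule": np.where(too_fast[removed], "rt_floor", "rt_ceiling"),
            "value": rt[removed].to_numpy(),
        }
    )
    return TrimResult(trials[~removed].copy(), log)
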
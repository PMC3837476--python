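"""Analysis-window selection and functional-ROI localization.

Windows of interest are 50 ms intervals centered either at a canonical
latency (e.g. 100 ms for the early visual response) or at a detected peak
of a mean time course (e.g. the letter-string response peaking ~170 ms).
The functional ROI (fROI) is localized on a source grid from an
independent localizer contrast — the facilitatory priming difference
pooled over the identity and regular conditions — and the priming effect
is then *tested* on held-out conditions (irregular, pseudo-irregular),
which keeps the selection from biasing the test.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import EpochSet, SourceEpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "FroiDefinition",
    "mean_timecourse",
    "find_peak_latency",
    "centered_window",
    "localize_froi",
    "extract_froi_timecourses",
]


@dataclasses.dataclass
class FroiDefinition:
    """A functional ROI: source set around the peak facilitatory priming
    effect, plus the provenance of its selection."""

    sources: list[int]
    peak_source: int
    peak_latency_ms: float
    conditions_used: list[str]
    window_used_ms: tuple[float, float]

    def __post_init__(self):
        if not self.sources:
            raise ValueError("fROI source set is empty")
        if self.peak_source not in self.sources:
            raise ValueError("peak source must belong to the fROI")

    def to_json(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["window_used_ms"] = list(self.window_used_ms)
        text = json.dumps(d, sort_keys=True, indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    def to_label_file(self, path) -> None:
        """One source index per line (interoperable label export)."""
        with open(path, "w") as f:
            for s in self.sources:
                f.write(f"{s}\n")


def mean_timecourse(epochs: EpochSet, selector=None) -> np.ndarray:
    """Pointwise mean over selected trials.

    ``selector`` is a boolean mask over trials, an array of trial labels,
    or None (all trials).
    """
    if selector is None:
        data = epochs.data
    else:
        selector = np.asarray(selector)
        if selector.dtype == bool:
            if selector.shape[0] != epochs.n_trials:
                raise ValueError("selector mask length mismatch")
            data = epochs.data[selector]
        else:
            data = epochs.subset(selector).data
    if data.shape[0] == 0:
        raise ValueError("selector matches no trials")
    return data.mean(axis=0)


def find_peak_latency(
    series: np.ndarray,
    time_ms: np.ndarray,
    search_window_ms: tuple[float, float],
    direction: str = "max",
) -> float:
    """Latency of the extremum of a mean series within a search window.

    Ties break toward the earliest sample.  An extremum sitting exactly on
    a window edge is flagged in the log (the window may be clipping a peak
    outside it) but still returned.
    """
    series = np.asarray(series, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    if series.shape != time_ms.shape:
        raise ValueError("series/time grid mismatch")
    start, end = search_window_ms
    mask = (time_ms >= start - 1e-9) & (time_ms <= end + 1e-9)
    if not mask.any():
        raise ValueError("search window contains no samples")
    seg = series[mask]
    seg_t = time_ms[mask]
    if np.ptp(seg) == 0.0:
        raise ValueError("series is constant in the search window; no peak")
    if direction == "max":
        k = int(np.argmax(seg))
    elif direction == "min":
        k = int(np.argmin(seg))
    elif direction == "absmax":
        k = int(np.argmax(np.abs(seg)))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if k == 0 or k == len(seg) - 1:
        logger.warning(
            "peak at %.1f ms lies on the search-window edge (%.1f, %.1f)",
            seg_t[k], start, end,
        )
    return float(seg_t[k])


def centered_window(peak_ms: float, width_ms: float = 50.0) -> tuple[float, float]:
    """Analysis window of ``width_ms`` centered at a peak latency."""
    if width_ms <= 0:
        raise ValueError("width must be > 0")
    half = width_ms / 2.0
    return (peak_ms - half, peak_ms + half)


def _facilitation_map(src: SourceEpochSet, trials: pd.DataFrame,
                      conditions, window_ms):
    """Per-source facilitatory priming difference, window averaged.

    Facilitation is defined relative to each source's local response sign:
    a reduction in |activity| for related primes.  With s = sign of the
    source's mean evoked response in the window, the localizer statistic
    is s * (mean unrelated - mean related)."""
    sel = trials["condition"].isin(conditions)
    if not sel.any():
        raise ValueError(f"conditions {sorted(conditions)} not present in trials")
    sub = trials[sel]
    data = src.subset(sub.index).data  # (n, S, T)
    sl = src.window_slice(window_ms)
    win = data[:, :, sl]
    related = (sub["prime_type"] == "related").to_numpy()
    if not related.any() or related.all():
        raise ValueError("both prime types required within the localizer conditions")
    evoked = win.mean(axis=0)  # (S, T)
    sign = np.where(evoked.mean(axis=1) >= 0, 1.0, -1.0)
    diff_t = win[~related].mean(axis=0) - win[related].mean(axis=0)  # (S, T)
    facil_t = sign[:, None] * diff_t
    return facil_t.mean(axis=1), facil_t, src.time_ms[sl]


def localize_froi(
    src: SourceEpochSet,
    trials: pd.DataFrame,
    conditions: Iterable[str] = ("identity", "regular"),
    masks: Iterable[str] = ("fusiform", "inferior_temporal"),
    window_ms: tuple[float, float] = (158.0, 208.0),
    extent_rule: float = 0.5,
) -> FroiDefinition:
    """Draw the fROI around the peak facilitatory priming effect.

    The peak source is the mask-internal source with the largest
    window-averaged facilitatory difference (localizer conditions pooled);
    the fROI extends to mask-internal sources whose facilitation is at
    least ``extent_rule`` of the peak's, restricted to the grid-connected
    component containing the peak.
    """
    conditions = sorted(set(conditions))
    masks = set(masks)
    unknown = masks - set(src.source_labels)
    if unknown:
        raise ValueError(f"masks not present in source labels: {sorted(unknown)}")
    facil, facil_t, win_t = _facilitation_map(src, trials, conditions, window_ms)
    eligible = src.sources_in_masks(masks)
    elig_facil = facil[eligible]
    if (elig_facil <= 0).all():
        raise ValueError("no facilitatory source within the requested masks")
    peak = int(eligible[np.argmax(elig_facil)])
    cut = extent_rule * facil[peak]
    qualify = set(int(s) for s in eligible[facil[eligible] >= cut])
    # connected component containing the peak, within qualifying sources
    nbrs = src.neighbors()
    froi = {peak}
    frontier = [peak]
    while frontier:
        s = frontier.pop()
        for nb in nbrs[s]:
            if nb in qualify and nb not in froi:
                froi.add(nb)
                frontier.append(nb)
    peak_latency = float(win_t[np.argmax(facil_t[peak])])
    return FroiDefinition(
        sources=sorted(froi),
        peak_source=peak,
        peak_latency_ms=peak_latency,
        conditions_used=conditions,
        window_used_ms=(float(window_ms[0]), float(window_ms[1])),
    )


def extract_froi_timecourses(src: SourceEpochSet, froi: FroiDefinition) -> EpochSet:
    """Per-trial mean over the fROI sources at each time point."""
    if max(froi.sources) >= src.n_sources or min(froi.sources) < 0:
        raise ValueError("fROI refers to sources outside the grid")
    return src.source_mean(froi.sources)
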